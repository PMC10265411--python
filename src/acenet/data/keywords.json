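{
  "adversity_phrases": [
    "abuse",
    "neglect",
    "jail",
    "prison",
    "substance use",
    "substance misuse",
    "substance abuse",
    "overdose",
    "od",
    "drug addiction",
    "parental separation",
    "divorce"
  ],
  "queries": {
    "ace": {
      "any_of": ["my mother", "my father", "my mom", "my dad", "my guardian"],
      "require_all": "$ADVERSITY",
      "negate_group": []
    },
    "nonace1": {
      "any_of": ["my mother", "my father", "my mom", "my dad"],
      "require_all": [],
      "negate_group": "$ADVERSITY"
    },
    "nonace2": {
      "any_of": ["school", "basketball", "game", "dog", "cosplay", "shopping"],
      "require_all": [],
      "negate_group": "$ADVERSITY"
    }
  }
}
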