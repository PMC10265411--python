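# acenet

Analysis pipeline for studying web-based social networks of people who
disclose adverse childhood experiences (ACEs) in short social-media texts.
The package covers three stages, end to end, with synthetic data standing in
for platform collection:

1. **Text & classification** — clean short texts into token sequences
   (lowercase, abbreviation expansion, special-character removal,
   deduplication, drop of texts with ≤ 5 words), evaluate keyword queries
   (OR-groups combined with AND / AND NOT), and train a binary
   embedding + convolutional classifier whose softmax output in [0, 1] is
   the per-text *ACE mention score* (strict > 0.5 decision rule; accuracy,
   precision, recall, F1 and rank-based AUC reported). The CNN is
   implemented directly on numpy (manual backprop), so training is
   deterministic under a fixed seed and needs no deep-learning framework.
2. **User scoring & sentiment** — aggregate a user's eligible-text scores
   (> 5 words, ≥ 30 texts) into the *ACE alignment index* (nearest-rank
   top-decile value); categorize users as ACE (index ≥ 0.5), non-ACE (all
   scores < 0.3), indeterminate, or insufficient-data. Sentiment scores in
   [−1, 1] from a pluggable scorer are classified with the ±0.05 thresholds.
3. **Egocentric networks & group statistics** — directed follow networks
   sampled up to 100 followers/followees per root; per-root reciprocity
   (r1, r2), local clustering over reciprocal-neighbor pairs (strict C1/C2
   and weak C1′/C2′ variants), homophily averages of neighbor alignment
   indexes, the reciprocal-vs-nonreciprocal follower split, and degree
   survival curves. Indexes guarded by the < 5-neighbor rule are undefined
   (`None`) and propagate as missing values into the three-group comparison
   (two-sided Mann-Whitney-Wilcoxon, Bonferroni × 3, capped at 1).

`acenet.synthetic` generates every input the pipeline consumes — separable
labeled corpora, per-user score streams, and ego networks with planted
follow-back probability, triangle density, and group-assortative attachment
— so all stages are testable offline, including parameter-recovery checks.

## CLI

All stages are exposed under a single `acenet` entry point:

```sh
acenet synth corpus --n-pos 1000 --n-neg 1000 --seed 7 --out corpus.jsonl
acenet classifier train --in corpus.jsonl --seed 7 --out model.npz
acenet classifier eval  --model model.npz --in corpus.jsonl --report metrics.json
acenet classifier score --model model.npz --in tweets.jsonl --out scored.jsonl

acenet preprocess clean --in raw.jsonl --out cleaned.jsonl --min-words 5
acenet preprocess match --query ace --in raw.jsonl

acenet users score      --in scored.jsonl --out users.csv
acenet sentiment profile --in sentiments.jsonl --out sentiment.csv

acenet synth egonet --n-per-group 50 --seed 11 --out-dir data/
acenet egonet indexes --edges data/edges.csv --roots data/roots.csv \
                      --alpha data/alpha.csv --out indexes.csv
acenet stats compare --indexes indexes.csv --groups data/groups.csv \
                     --metric r1 --out table.json
```

Corpus files are JSONL or CSV (`doc_id`, `author_id`, `text`, optional
`label`); networks are edge-list CSVs (`source_id`, `target_id`, optional
`root_id`) plus a roots file (`root_id`, `k_in`, `k_out`).

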