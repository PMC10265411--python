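"""Plain-text I/O for corpora (JSONL/CSV), networks and index tables (CSV)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from acenet.ego_network import DirectedEgoNetwork
from acenet.text_preprocess import CleanedDocument, RawDocument

__all__ = [
    "read_raw_corpus",
    "read_cleaned_corpus",
    "write_cleaned_corpus",
    "read_records",
    "write_records",
    "read_ego_networks",
    "write_indexes_csv",
]

_CORPUS_COLUMNS = ("doc_id", "author_id", "text", "label")


def read_records(path: str | Path) -> list[dict]:
    """Read a JSONL (one object per line) or CSV file into dicts."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, dtype={"doc_id": str, "author_id": str})
        return frame.where(frame.notna(), None).to_dict("records")
    with path.open() as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_records(records: Iterable[Mapping], path: str | Path) -> None:
    path = Path(path)
    records = list(records)
    if path.suffix.lower() == ".csv":
        pd.DataFrame.from_records(records).to_csv(path, index=False)
        return
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(dict(rec)) + "\n")


def read_raw_corpus(path: str | Path) -> tuple[list[RawDocument], list[int | None]]:
    """Load raw documents plus optional labels from JSONL/CSV."""
    docs, labels = [], []
    for rec in read_records(path):
        docs.append(
            RawDocument(
                doc_id=str(rec["doc_id"]),
                text=str(rec["text"]),
                author_id=rec.get("author_id"),
            )
        )
        lab = rec.get("label")
        labels.append(None if lab is None else int(lab))
    return docs, labels


def write_cleaned_corpus(
    docs: Iterable[CleanedDocument],
    path: str | Path,
    labels: Iterable[int | None] | None = None,
) -> None:
    labels = list(labels) if labels is not None else None
    records = []
    for i, doc in enumerate(docs):
        rec = {
            "doc_id": doc.doc_id,
            "author_id": doc.author_id,
            "tokens": list(doc.tokens),
            "word_count": doc.word_count,
        }
        if labels is not None:
            rec["label"] = labels[i]
        records.append(rec)
    write_records(records, path)


def read_cleaned_corpus(
    path: str | Path,
) -> tuple[list[CleanedDocument], list[int | None]]:
    docs, labels = [], []
    for rec in read_records(path):
        tokens = rec["tokens"]
        if isinstance(tokens, str):  # CSV round-trip stores a JSON string
            tokens = json.loads(tokens.replace("'", '"'))
        docs.append(
            CleanedDocument(
                doc_id=str(rec["doc_id"]),
                tokens=tuple(tokens),
                author_id=rec.get("author_id"),
            )
        )
        lab = rec.get("label")
        labels.append(None if lab is None else int(lab))
    return docs, labels


def read_ego_networks(
    edges_path: str | Path, roots_path: str | Path
) -> list[DirectedEgoNetwork]:
    """Assemble per-root networks from an edge-list CSV and a roots CSV.

    ``edges.csv`` columns: source_id, target_id (source follows target), with
    an optional ``root_id`` column assigning each edge to one root's sampled
    subgraph.  ``roots.csv`` columns: root_id, k_in, k_out.  Followers and
    followees of each root are inferred from its edges.
    """
    edges = pd.read_csv(edges_path, dtype=str)
    roots = pd.read_csv(roots_path, dtype={"root_id": str})
    has_assignment = "root_id" in edges.columns
    nets = []
    for _, row in roots.iterrows():
        root = row["root_id"]
        sub = edges[edges["root_id"] == root] if has_assignment else edges
        pairs = frozenset(zip(sub["source_id"], sub["target_id"]))
        followers = frozenset(a for a, b in pairs if b == root)
        followees = frozenset(b for a, b in pairs if a == root)
        nets.append(
            DirectedEgoNetwork(
                root=root,
                followers=followers,
                followees=followees,
                edges=pairs,
                k_in=int(row["k_in"]),
                k_out=int(row["k_out"]),
            )
        )
    return nets


def write_indexes_csv(indexes: Iterable, path: str | Path) -> None:
    pd.DataFrame.from_records([ix.to_dict() for ix in indexes]).to_csv(
        path, index=False
    )
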