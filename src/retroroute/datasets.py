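"""Reaction-dataset helpers.

The single-step models in the original setting are trained on a patent-
derived reaction corpus distributed as pre-split train/validation/test
reaction SMILES files (90 : 5 : 5).  Nothing in this package requires that
download — the toy world covers all tests — but :func:`split_counts` lets a
user verify a local copy of such a split by counting its records.
"""

from __future__ import annotations

import gzip
from pathlib import Path

__all__ = ["count_records", "split_counts"]


def count_records(path: str | Path) -> int:
    """Number of non-empty, non-comment records in a (possibly gzipped)
    reaction SMILES or SMILES file, header lines excluded for .csv/.tsv."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    stem = path.name.removesuffix(".gz")
    has_header = stem.endswith((".csv", ".tsv"))
    n = 0
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if has_header and i == 0:
                continue
            if line.strip() and not line.startswith("#"):
                n += 1
    return n


def split_counts(
    train: str | Path, valid: str | Path, test: str | Path
) -> dict[str, int]:
    """Record counts of a train/validation/test reaction split."""
    return {
        "train": count_records(train),
        "valid": count_records(valid),
        "test": count_records(test),
    }
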