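"""Reading, writing and filtering of gene x sample count matrices.

A count matrix has genes as rows and samples as columns; entries are
non-negative integers (mapped-read counts). Sample group labels and
benchmark truth sets (true-positive / true-negative gene lists from
qRT-PCR validation) are small side-car inputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "TruthSet",
    "read_counts",
    "write_table",
    "filter_genes",
    "read_truth_set",
]


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids, sample_ids
        Row / column identifiers, unique, order preserved from input.
    counts
        ``(n_genes, n_samples)`` integer array.
    groups
        Optional mapping ``sample_id -> group label`` covering every sample.
    removed_genes
        Gene ids dropped by :func:`filter_genes` (provenance only).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    groups: dict[str, str] | None = None
    removed_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9, rtol=0.0):
                bad = np.argwhere(np.abs(counts - rounded) > 1e-9)[0]
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}: {counts[tuple(bad)]}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.groups is not None:
            missing = [s for s in self.sample_ids if s not in self.groups]
            if missing:
                raise ValueError(f"samples without a group label: {missing}")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total read counts N_j."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        groups = None
        if self.groups is not None:
            groups = {s: self.groups[s] for s in sample_ids}
        return CountMatrix(
            self.gene_ids, tuple(sample_ids), self.counts[:, idx], groups=groups
        )


@dataclass(frozen=True)
class TruthSet:
    """Benchmark gene lists: validated positives and negatives (disjoint)."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"genes in both truth lists: {sorted(overlap)[:10]}")
        if not self.positives or not self.negatives:
            raise ValueError("truth sets must both be non-empty")
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


def read_counts(path, delimiter: str = "\t") -> CountMatrix:
    """Read a delimited gene x sample count file.

    First row is the sample-id header, first column the gene ids.
    Lines starting with ``#`` are skipped. Numeric cells must be within
    1e-9 of an integer.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split(delimiter)
    sample_ids = [c for c in header[1:] if c != ""]
    n_cols = len(sample_ids)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.rstrip("\n").split(delimiter)
        if len(cells) == 1 and cells[0] == "":
            continue
        if len(cells) != n_cols + 1:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {n_cols + 1}"
            )
        gene_ids.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    counts = np.asarray(rows, dtype=float).reshape(len(gene_ids), n_cols)
    return CountMatrix(tuple(gene_ids), tuple(sample_ids), counts)


def write_table(obj, path, delimiter: str = "\t") -> None:
    """Write a CountMatrix, a results/metrics DataFrame, to delimited text.

    Floats are serialized with 12 significant digits so a read/write round
    trip is lossless at working precision.
    """
    if isinstance(obj, CountMatrix):
        frame = obj.to_frame()
        frame.index.name = "gene"
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    buf = io.StringIO()
    frame.to_csv(buf, sep=delimiter, float_format="%.12g")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def filter_genes(cm: CountMatrix, max_zero_fraction: float = 0.5) -> CountMatrix:
    """Drop genes whose zero fraction exceeds ``max_zero_fraction``.

    The comparison is strict (a gene with zero fraction exactly at the
    threshold is kept); all-zero genes are always removed. Removed ids are
    recorded on the returned matrix.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError(f"max_zero_fraction must be in [0, 1], got {max_zero_fraction}")
    zero_frac = (cm.counts == 0).mean(axis=1)
    keep = (zero_frac <= max_zero_fraction) & (zero_frac < 1.0)
    removed = tuple(g for g, k in zip(cm.gene_ids, keep) if not k)
    return CountMatrix(
        tuple(g for g, k in zip(cm.gene_ids, keep) if k),
        cm.sample_ids,
        cm.counts[keep],
        groups=cm.groups,
        removed_genes=cm.removed_genes + removed,
    )


def read_truth_set(path_pos, path_neg) -> TruthSet:
    """Read one-gene-id-per-line truth lists (deduplicated)."""

    def _read(path) -> frozenset[str]:
        with open(path, "rt", encoding="utf-8") as fh:
            ids = frozenset(ln.strip() for ln in fh if ln.strip())
        if not ids:
            raise ValueError(f"{path}: empty truth list")
        return ids

    return TruthSet(_read(path_pos), _read(path_neg))
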