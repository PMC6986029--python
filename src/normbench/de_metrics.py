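"""DEG calling at conventional cutoffs and benchmark confusion metrics.

A gene is called differentially expressed when its BH-adjusted FDR is at
most the FDR cutoff *and* its absolute log2 fold change is at least the
fold-change cutoff (both boundaries inclusive). Against a validated
truth set the usual confusion metrics follow: PPV = TP/(TP+FP), actual
FDR = FP/(TP+FP) = 1 - PPV, sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import TruthSet

__all__ = ["DegCallSet", "ConfusionMetrics", "call_degs", "confusion_metrics", "fpr_from_calls"]


@dataclass(frozen=True)
class DegCallSet:
    """Per-gene DE calls with the cutoffs that produced them."""

    tested_genes: tuple[str, ...]
    is_de: tuple[bool, ...]
    fdr_cutoff: float
    lfc_cutoff: float

    def __post_init__(self) -> None:
        if len(self.tested_genes) != len(self.is_de):
            raise ValueError("is_de must cover every tested gene")

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(g for g, d in zip(self.tested_genes, self.is_de) if d)

    @property
    def n_de(self) -> int:
        return int(sum(self.is_de))


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived rates against a truth set.

    Rates with a zero denominator are NaN. ``sensitivity_raw`` /
    ``specificity_raw`` use the full truth-list sizes as denominators;
    the plain fields use only truth genes present among the tested genes
    (the effective denominator).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float
    actual_fdr: float
    sensitivity: float
    specificity: float
    sensitivity_raw: float = float("nan")
    specificity_raw: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def call_degs(
    tt: pd.DataFrame, fdr_cutoff: float = 0.05, lfc_cutoff: float = 1.0
) -> DegCallSet:
    """Call DEGs from a test table at FDR <= cutoff and |log2FC| >= cutoff."""
    if fdr_cutoff < 0 or lfc_cutoff < 0:
        raise ValueError("cutoffs must be non-negative")
    fdr = tt["fdr"].to_numpy(dtype=float)
    lfc = tt["log2fc"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        is_de = (fdr <= fdr_cutoff) & (np.abs(lfc) >= lfc_cutoff)
    is_de = np.where(np.isnan(fdr) | np.isnan(lfc), False, is_de)
    return DegCallSet(tuple(tt["gene"]), tuple(bool(d) for d in is_de), fdr_cutoff, lfc_cutoff)


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(calls: DegCallSet, truth: TruthSet) -> ConfusionMetrics:
    """Confusion counts/rates of a DEG call set against a truth set.

    Genes outside the truth lists are ignored; truth genes absent from
    the tested genes enter only the raw-denominator sensitivity and
    specificity.
    """
    tested = set(calls.tested_genes)
    pos = truth.positives & tested
    neg = truth.negatives & tested
    if not pos and not neg:
        raise ValueError("truth sets do not intersect the tested genes")
    de = calls.de_genes
    tp = len(de & pos)
    fp = len(de & neg)
    fn = len(pos - de)
    tn = len(neg - de)
    ppv = _rate(tp, tp + fp)
    metrics = ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        ppv=ppv,
        actual_fdr=_rate(fp, tp + fp),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        sensitivity_raw=_rate(tp, len(truth.positives)),
        specificity_raw=_rate(len(truth.negatives) - fp, len(truth.negatives)),
    )
    if tp + fp > 0:
        assert abs(metrics.ppv + metrics.actual_fdr - 1.0) < 1e-12
    return metrics


def fpr_from_calls(calls: DegCallSet, total_genes: int | None = None) -> float:
    """Fraction of tested genes called DE (empirical false-positive rate
    when both groups come from the same condition).

    ``total_genes`` swaps in an alternative denominator (e.g. the
    pre-filter gene count).
    """
    den = total_genes if total_genes is not None else len(calls.tested_genes)
    if den <= 0:
        raise ValueError("no tested genes")
    return calls.n_de / den
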