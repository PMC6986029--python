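"""Null-resampling benchmarks for normalization/test combinations.

Two evaluation procedures:

* **Intra-group (mock comparison)** — repeatedly draw two disjoint
  pseudo-groups from a single condition; any DEG called between them is
  a false positive by construction, so the fraction of tested genes
  called DE estimates the empirical type-I error of the whole pipeline.
* **Bootstrap two-group** — repeatedly subsample case and control
  cohorts at a target sample size and count the DEGs called, summarizing
  mean +/- SE over repeats.

Every repeat re-applies gene filtering, normalization and dispersion
estimation to the drawn samples (the filter depends on which samples are
drawn), and its RNG stream derives from (master seed, sample size,
repeat index) so grids are reproducible and extensible.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, filter_genes
from .de_metrics import call_degs, fpr_from_calls
from .nb_inference import (
    TESTS,
    estimate_dispersions,
    exact_test,
    moderated_t,
    ql_ftest,
    wald_test,
)
from .normalization import METHODS, normalize

__all__ = [
    "run_de_pipeline",
    "intra_group_fpr_experiment",
    "bootstrap_de_experiment",
    "plot_fpr_summary",
]

logger = logging.getLogger(__name__)


def run_de_pipeline(
    cm: CountMatrix,
    normalization: str,
    test: str,
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
    max_zero_fraction: float = 0.5,
    prior_weight: float = 10.0,
):
    """Filter, normalize, test and call DEGs on a labeled two-group matrix.

    Returns ``(calls, test_table)``. ``cm.groups`` must assign exactly two
    labels.
    """
    if normalization not in METHODS:
        raise ValueError(f"unknown normalization {normalization!r}; choose from {METHODS}")
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    if cm.groups is None:
        raise ValueError("count matrix has no group labels")
    filtered = filter_genes(cm, max_zero_fraction)
    nm = normalize(filtered, normalization)
    groups = [cm.groups[s] for s in filtered.sample_ids]
    if test == "tmod":
        tt = moderated_t(nm, groups)
    else:
        disp = estimate_dispersions(nm, groups, prior_weight=prior_weight)
        if test == "exact":
            tt = exact_test(nm, groups, disp)
        elif test == "wald":
            tt = wald_test(nm, groups, disp)
        else:
            tt = ql_ftest(nm, groups, disp)
    calls = call_degs(tt, fdr_cutoff, lfc_cutoff)
    return calls, tt


def intra_group_fpr_experiment(
    cm: CountMatrix,
    sample_sizes,
    normalization: str,
    test: str,
    n_repeats: int = 50,
    seed: int = 0,
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
    max_zero_fraction: float = 0.5,
    prior_weight: float = 10.0,
) -> pd.DataFrame:
    """Mock-comparison false-positive-rate experiment on one condition.

    For each sample size n and repeat, 2n distinct samples are drawn from
    ``cm`` and split into two disjoint pseudo-groups of n; the DE
    pipeline runs and the FPR (fraction of tested genes called DE) is
    recorded. Sizes needing more samples than available are skipped with
    a warning.
    """
    rows = []
    for n in sample_sizes:
        if cm.n_samples < 2 * n:
            warnings.warn(
                f"size {n} needs {2 * n} samples but only {cm.n_samples} "
                "are available; skipping",
                stacklevel=2,
            )
            continue
        fprs, n_fp, n_tested = [], [], []
        for rep in range(n_repeats):
            rng = np.random.default_rng([seed, n, rep])
            idx = rng.choice(cm.n_samples, size=2 * n, replace=False)
            sub_ids = [cm.sample_ids[i] for i in idx]
            sub = cm.subset_samples(sub_ids)
            groups = {s: ("A" if k < n else "B") for k, s in enumerate(sub_ids)}
            sub = CountMatrix(sub.gene_ids, sub.sample_ids, sub.counts, groups=groups)
            calls, _ = run_de_pipeline(
                sub, normalization, test, fdr_cutoff, lfc_cutoff,
                max_zero_fraction, prior_weight,
            )
            fpr = fpr_from_calls(calls)
            fprs.append(fpr)
            n_fp.append(calls.n_de)
            n_tested.append(len(calls.tested_genes))
            logger.info(
                "intra-group %s/%s n=%d rep=%d: tested=%d de=%d fpr=%.5f",
                normalization, test, n, rep, n_tested[-1], n_fp[-1], fpr,
            )
        fprs = np.asarray(fprs)
        rows.append(
            {
                "normalization": normalization,
                "test": test,
                "sample_size": n,
                "fpr_mean": fprs.mean(),
                "fpr_se": fprs.std(ddof=1) / np.sqrt(len(fprs)) if len(fprs) > 1 else 0.0,
                "n_repeats": len(fprs),
                "mean_n_fp": float(np.mean(n_fp)),
                "n_tested_mean": float(np.mean(n_tested)),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_de_experiment(
    case_cm: CountMatrix,
    control_cm: CountMatrix,
    sample_sizes,
    normalization: str,
    test: str,
    n_repeats: int = 50,
    seed: int = 0,
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
    max_zero_fraction: float = 0.5,
    prior_weight: float = 10.0,
) -> pd.DataFrame:
    """Bootstrap two-group DEG-count experiment (case vs control).

    Per repeat and size n, n case and n control samples are drawn without
    replacement, merged, and run through the DE pipeline; the number of
    DEGs called is summarized as mean +/- SE over repeats.
    """
    shared = [g for g in case_cm.gene_ids if g in set(control_cm.gene_ids)]
    if len(shared) != len(case_cm.gene_ids) or len(shared) != len(control_cm.gene_ids):
        warnings.warn("gene universes differ; intersecting", stacklevel=2)
    case_idx = [case_cm.gene_ids.index(g) for g in shared] if len(shared) != len(case_cm.gene_ids) else None
    ctrl_idx = [control_cm.gene_ids.index(g) for g in shared] if len(shared) != len(control_cm.gene_ids) else None
    case_counts = case_cm.counts if case_idx is None else case_cm.counts[case_idx]
    ctrl_counts = control_cm.counts if ctrl_idx is None else control_cm.counts[ctrl_idx]

    rows = []
    for n in sample_sizes:
        if case_cm.n_samples < n or control_cm.n_samples < n:
            warnings.warn(f"size {n} exceeds available samples; skipping", stacklevel=2)
            continue
        n_degs = []
        for rep in range(n_repeats):
            rng = np.random.default_rng([seed, n, rep])
            ci = rng.choice(case_cm.n_samples, size=n, replace=False)
            ki = rng.choice(control_cm.n_samples, size=n, replace=False)
            ids = [f"case_{case_cm.sample_ids[i]}" for i in ci] + [
                f"ctrl_{control_cm.sample_ids[i]}" for i in ki
            ]
            counts = np.concatenate([case_counts[:, ci], ctrl_counts[:, ki]], axis=1)
            groups = {s: ("case" if s.startswith("case_") else "control") for s in ids}
            merged = CountMatrix(tuple(shared), tuple(ids), counts, groups=groups)
            calls, _ = run_de_pipeline(
                merged, normalization, test, fdr_cutoff, lfc_cutoff,
                max_zero_fraction, prior_weight,
            )
            n_degs.append(calls.n_de)
            logger.info(
                "bootstrap %s/%s n=%d rep=%d: tested=%d de=%d",
                normalization, test, n, rep, len(calls.tested_genes), calls.n_de,
            )
        n_degs = np.asarray(n_degs, dtype=float)
        rows.append(
            {
                "normalization": normalization,
                "test": test,
                "sample_size": n,
                "mean_n_deg": n_degs.mean(),
                "se_n_deg": n_degs.std(ddof=1) / np.sqrt(len(n_degs)) if len(n_degs) > 1 else 0.0,
                "n_repeats": len(n_degs),
            }
        )
    return pd.DataFrame(rows)


def plot_fpr_summary(summary: pd.DataFrame, path=None):
    """Line plot of mean FPR vs sample size, one line per (norm, test)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (norm, test), grp in summary.groupby(["normalization", "test"]):
        grp = grp.sort_values("sample_size")
        ax.errorbar(
            grp["sample_size"], grp["fpr_mean"], yerr=grp["fpr_se"],
            marker="o", label=f"{norm}/{test}",
        )
    ax.set_xlabel("sample size per group")
    ax.set_ylabel("mean FPR")
    ax.axhline(0.05, color="grey", ls="--", lw=0.8)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
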