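"""Library-size normalization: UQ, UQ-pgQ2, RLE and TMM.

All four methods correct for between-sample differences in sequencing
depth (and, for TMM/RLE, RNA composition) so that counts are comparable
across samples:

* **UQ** — each sample is scaled by the 75th percentile (Q3) of its
  nonzero gene counts, then multiplied by the mean Q3 over samples so the
  output stays on the count scale.
* **UQ-pgQ2** — two-step: UQ first, then each gene row is divided by its
  across-sample median (Q2) and multiplied by 100, putting every gene on
  a common per-gene scale.
* **RLE** — relative log expression: size factor = median over genes of
  the ratio of a sample's count to the gene's geometric mean across
  samples (genes positive in every sample only).
* **TMM** — trimmed mean of M-values relative to a reference sample,
  with delta-method precision weights, rescaled to unit geometric mean.

Quantiles and medians use linear interpolation (numpy default, R type 7)
throughout; the convention is fixed here in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts_io import CountMatrix

__all__ = [
    "NormFactors",
    "NormalizedMatrix",
    "normalize_uq",
    "normalize_uq_pgq2",
    "rle_size_factors",
    "tmm_factors",
    "apply_size_factors",
    "normalize",
    "METHODS",
]

METHODS = ("uq", "uq-pgq2", "rle", "tmm")

#: quantile interpolation convention used by every quantile/median here
QUANTILE_METHOD = "linear"


def _quantile(x: np.ndarray, q: float, axis=None) -> np.ndarray:
    return np.quantile(x, q, axis=axis, method=QUANTILE_METHOD)


@dataclass(frozen=True)
class NormFactors:
    """Per-sample scale factors and effective library sizes.

    ``per_gene_divisor`` is present only for UQ-pgQ2 (the across-sample
    median of the UQ-normalized gene, i.e. the second-step divisor).
    """

    method: str
    per_sample_factor: dict[str, float]
    effective_library_size: dict[str, float]
    per_gene_divisor: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        for name, val in self.per_sample_factor.items():
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"non-positive factor for sample {name!r}: {val}")
        has_div = self.per_gene_divisor is not None
        if has_div != (self.method == "uq-pgq2"):
            raise ValueError("per_gene_divisor present iff method is uq-pgq2")


@dataclass(frozen=True)
class NormalizedMatrix:
    """Real-valued normalized expression matrix with provenance."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    method: str
    factors: NormFactors
    source: CountMatrix | None = None
    flagged_genes: tuple[str, ...] = ()
    #: for UQ-pgQ2, the intermediate UQ matrix (provenance; lets downstream
    #: log-scale tests cancel the per-gene divisor exactly)
    uq_matrix: "NormalizedMatrix | None" = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match ids")
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("normalized values must be finite and >= 0")
        object.__setattr__(self, "values", values)

    def rounded_counts(self) -> np.ndarray:
        """Values rounded to the nearest integer, for count-based tests."""
        return np.rint(self.values).astype(np.int64)


def _uq_factors(cm: CountMatrix, zero_removal: str = "per_sample") -> np.ndarray:
    """Per-sample Q3 of nonzero counts (the UQ scaling factor)."""
    if zero_removal not in ("per_sample", "matrix"):
        raise ValueError(f"zero_removal must be per_sample or matrix, got {zero_removal!r}")
    counts = cm.counts
    if zero_removal == "matrix":
        counts = counts[(counts > 0).any(axis=1)]
    factors = np.empty(cm.n_samples)
    for j, sample in enumerate(cm.sample_ids):
        col = counts[:, j]
        nz = col[col > 0] if zero_removal == "per_sample" else col
        if nz.size < 4:
            raise ValueError(f"sample {sample!r} has fewer than 4 nonzero genes")
        q3 = _quantile(nz, 0.75)
        if q3 <= 0:
            raise ValueError(f"sample {sample!r} has zero upper quartile")
        factors[j] = q3
    return factors


def normalize_uq(
    cm: CountMatrix, zero_removal: str = "per_sample"
) -> tuple[NormFactors, NormalizedMatrix]:
    """Upper-quartile normalization.

    X_gj = R_gj / Q3_j * mean_k(Q3_k). After scaling, all samples share a
    common effective library size (the mean raw library size is reported).
    """
    q3 = _uq_factors(cm, zero_removal)
    mean_q3 = q3.mean()
    values = cm.counts / q3[np.newaxis, :] * mean_q3
    eff = float(cm.library_sizes().mean())
    nf = NormFactors(
        "uq",
        dict(zip(cm.sample_ids, map(float, q3))),
        {s: eff for s in cm.sample_ids},
    )
    nm = NormalizedMatrix(cm.gene_ids, cm.sample_ids, values, "uq", nf, source=cm)
    return nf, nm


def normalize_uq_pgq2(
    cm: CountMatrix, zero_removal: str = "per_sample"
) -> tuple[NormFactors, NormalizedMatrix]:
    """Two-step UQ + per-gene Q2 normalization.

    Starting from the UQ matrix, each gene row is divided by its
    across-sample median and multiplied by 100, so every surviving gene
    has across-sample median 100. Genes whose UQ median is 0 keep their
    UQ values (divisor 1) and are flagged.
    """
    _, uq_nm = normalize_uq(cm, zero_removal)
    medians = np.median(uq_nm.values, axis=1)
    flagged = medians <= 0.0
    divisor = np.where(flagged, 1.0, medians)
    scale = np.where(flagged, 1.0, 100.0 / divisor)
    values = uq_nm.values * scale[:, np.newaxis]
    eff = next(iter(uq_nm.factors.effective_library_size.values()))
    nf = NormFactors(
        "uq-pgq2",
        dict(uq_nm.factors.per_sample_factor),
        {s: eff for s in cm.sample_ids},
        per_gene_divisor=dict(zip(cm.gene_ids, map(float, divisor))),
    )
    nm = NormalizedMatrix(
        cm.gene_ids,
        cm.sample_ids,
        values,
        "uq-pgq2",
        nf,
        source=cm,
        flagged_genes=tuple(g for g, f in zip(cm.gene_ids, flagged) if f),
        uq_matrix=uq_nm,
    )
    return nf, nm


def _values_of(cm) -> np.ndarray:
    """Raw counts of a CountMatrix or values of a NormalizedMatrix."""
    if isinstance(cm, NormalizedMatrix):
        return cm.values
    return cm.counts


def rle_size_factors(cm) -> NormFactors:
    """Median-of-ratios (relative log expression) size factors.

    s_j = median over genes positive in all samples of
    R_gj / geometric-mean_k(R_gk). Factors are not rescaled: the median
    of ratios is already centered. Accepts a CountMatrix or a
    NormalizedMatrix.
    """
    counts = _values_of(cm)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has positive counts in every sample")
    logc = np.log(counts[all_pos].astype(float))
    log_gm = logc.mean(axis=1)
    factors = np.exp(np.median(logc - log_gm[:, np.newaxis], axis=0))
    lib = np.asarray(counts, dtype=float).sum(axis=0)
    # effective depth on the read scale: the size factor times the mean depth
    return NormFactors(
        "rle",
        dict(zip(cm.sample_ids, map(float, factors))),
        dict(zip(cm.sample_ids, map(float, factors * lib.mean()))),
    )


def tmm_factors(cm, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors (unit geometric mean).

    The reference sample is the one whose upper quartile of count
    proportions is closest to the mean upper quartile. Per sample, M and
    A log-ratios over genes positive in both the sample and the
    reference are trimmed (``trim_m`` two-sided by M, ``trim_a`` by A)
    and averaged with delta-method inverse-variance weights.
    """
    counts = _values_of(cm).astype(float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = cm.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero library size")
    props = counts / lib[np.newaxis, :]
    q3 = _quantile(props, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q3 - q3.mean())))

    factors = np.empty(cm.n_samples)
    for j in range(cm.n_samples):
        if j == ref:
            factors[j] = 1.0
            continue
        mask = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if mask.sum() < 20:
            raise ValueError(
                f"only {int(mask.sum())} genes expressed in both sample "
                f"{cm.sample_ids[j]!r} and the reference; TMM needs >= 20"
            )
        yj, yr = counts[mask, j], counts[mask, ref]
        pj, pr = yj / lib[j], yr / lib[ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        n = m.size
        # edgeR-style rank trimming: keep ranks [floor(n*trim)+1, n-floor(n*trim)]
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = _rank(m)
        rank_a = _rank(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() < 20:
            raise ValueError(
                f"only {int(keep.sum())} genes survive TMM trimming for sample "
                f"{cm.sample_ids[j]!r}; lower trim_m/trim_a"
            )
        w = 1.0 / ((lib[j] - yj) / (lib[j] * yj) + (lib[ref] - yr) / (lib[ref] * yr))
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        "tmm",
        dict(zip(cm.sample_ids, map(float, factors))),
        dict(zip(cm.sample_ids, map(float, lib * factors))),
    )


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), matching R's rank()."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    ranks[order] = np.arange(1, x.size + 1, dtype=float)
    # average ties
    sx = x[order]
    i = 0
    while i < sx.size:
        j = i
        while j + 1 < sx.size and sx[j + 1] == sx[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    return ranks


def apply_size_factors(cm: CountMatrix, nf: NormFactors) -> NormalizedMatrix:
    """Scale counts by RLE size factors or TMM effective library sizes.

    RLE: value_gj = R_gj / s_j. TMM: value_gj = R_gj / (N_j f_j /
    mean_k(N_k f_k)), preserving the average effective depth.
    """
    missing = [s for s in cm.sample_ids if s not in nf.per_sample_factor]
    if missing:
        raise ValueError(f"factors missing for samples: {missing}")
    f = np.array([nf.per_sample_factor[s] for s in cm.sample_ids])
    if nf.method == "rle":
        scale = f
    elif nf.method == "tmm":
        eff = np.array([nf.effective_library_size[s] for s in cm.sample_ids])
        scale = eff / eff.mean()
    else:
        raise ValueError(f"apply_size_factors expects rle or tmm factors, got {nf.method!r}")
    values = cm.counts / scale[np.newaxis, :]
    return NormalizedMatrix(cm.gene_ids, cm.sample_ids, values, nf.method, nf, source=cm)


def normalize(cm: CountMatrix, method: str) -> NormalizedMatrix:
    """Run any of the four normalizations, returning the matrix."""
    method = method.lower()
    if method == "uq":
        return normalize_uq(cm)[1]
    if method in ("uq-pgq2", "uq_pgq2", "uqpgq2"):
        return normalize_uq_pgq2(cm)[1]
    if method == "rle":
        return apply_size_factors(cm, rle_size_factors(cm))
    if method == "tmm":
        return apply_size_factors(cm, tmm_factors(cm))
    raise ValueError(f"unknown normalization method {method!r}")
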