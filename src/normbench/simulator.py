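"""Monte-Carlo read-count simulator.

Real cohorts are emulated in two stages. A *reference profile* holds
per-sample gene-proportion vectors (estimated from a real or synthetic
count matrix as R_ig / N_i). Simulated samples then draw a read depth
from Normal(mean_depth, sd_depth^2) (rounded, floored) and counts from
Multinomial(depth, proportions), so each simulated column sums exactly
to its drawn depth. Because every sample re-uses an observed proportion
vector, the sample-to-sample biological variability of the source cohort
is preserved while no gene is differentially expressed between the two
simulated groups (a null by construction).

``synth_reference`` builds a stand-in source cohort when no real cohort
is available: heavy-tailed log-normal baseline abundances with NB
inter-sample variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .counts_io import CountMatrix

__all__ = [
    "ReferenceProfile",
    "SimConfig",
    "estimate_proportions",
    "synth_reference",
    "simulate_two_groups",
    "thin_counts",
]


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-sample gene-proportion vectors (columns sum to 1)."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    proportions: np.ndarray  # (n_genes, n_samples)
    source: str = "real"

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("proportions shape does not match ids")
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        sums = p.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ValueError("each sample's proportions must sum to 1 within 1e-12")
        object.__setattr__(self, "proportions", p)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    ``mean_depth``/``sd_depth`` are in reads (the study scenarios use
    30-50 million +/- 3 or 5 million); depths are rounded to the nearest
    integer and floored at ``min_depth``.
    """

    mean_depth: float
    sd_depth: float
    n_per_group: int
    n_repeats: int = 50
    seed: int = 0
    min_depth: int = 1_000_000

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.sd_depth < 0:
            raise ValueError("sd_depth must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.mean_depth <= 3.0 * self.sd_depth:
            warnings.warn(
                "mean_depth <= 3*sd_depth: Normal depth draws will often "
                "hit the truncation floor",
                stacklevel=2,
            )


def estimate_proportions(cm: CountMatrix) -> ReferenceProfile:
    """Per-sample proportions p_ig = R_ig / N_i."""
    lib = cm.library_sizes()
    if (lib <= 0).any():
        bad = cm.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero total count")
    props = cm.counts / lib[np.newaxis, :].astype(float)
    props = props / props.sum(axis=0, keepdims=True)  # exact renormalization
    return ReferenceProfile(cm.gene_ids, cm.sample_ids, props, source="real")


def synth_reference(
    n_genes: int,
    n_samples: int,
    seed: int,
    abundance_sdlog: float = 2.0,
    biological_dispersion: float = 0.1,
) -> CountMatrix:
    """Synthetic source cohort emulating a deeply sequenced cancer panel.

    Baseline expected counts are log-normal(meanlog 4, sdlog
    ``abundance_sdlog``) — a heavy-tailed abundance spectrum spanning
    several orders of magnitude — and per-sample counts are NB around the
    baseline with dispersion ``biological_dispersion``.
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if abundance_sdlog <= 0 or biological_dispersion <= 0:
        raise ValueError("abundance_sdlog and biological_dispersion must be positive")
    rng = np.random.default_rng(seed)
    lam = rng.lognormal(mean=4.0, sigma=abundance_sdlog, size=n_genes)
    r = 1.0 / biological_dispersion
    p = r / (r + lam)
    counts = rng.negative_binomial(r, p[:, None], size=(n_genes, n_samples))
    gene_ids = tuple(f"g{i:05d}" for i in range(n_genes))
    sample_ids = tuple(f"s{j:03d}" for j in range(n_samples))
    return CountMatrix(gene_ids, sample_ids, counts)


def simulate_two_groups(
    profile: ReferenceProfile, config: SimConfig, repeat_index: int = 0
) -> CountMatrix:
    """Simulate 2*n_per_group null samples (labeled A/B) from a profile.

    Source proportion vectors are drawn without replacement within a
    repeat (with replacement, with a warning, if the pool is smaller than
    2n). Each simulated sample's RNG stream is fully determined by
    (seed, repeat_index, sample_index).
    """
    n = config.n_per_group
    n_total = 2 * n
    select_rng = np.random.default_rng([config.seed, repeat_index])
    if profile.n_samples >= n_total:
        chosen = select_rng.choice(profile.n_samples, size=n_total, replace=False)
    else:
        warnings.warn(
            f"profile has {profile.n_samples} source samples < {n_total}; "
            "sampling with replacement",
            stacklevel=2,
        )
        chosen = select_rng.choice(profile.n_samples, size=n_total, replace=True)

    counts = np.empty((len(profile.gene_ids), n_total), dtype=np.int64)
    sample_ids = []
    groups = {}
    for i in range(n_total):
        rng = np.random.default_rng([config.seed, repeat_index, i])
        depth = int(round(rng.normal(config.mean_depth, config.sd_depth)))
        depth = max(depth, config.min_depth)
        counts[:, i] = rng.multinomial(depth, profile.proportions[:, chosen[i]])
        group = "A" if i < n else "B"
        sid = f"r{repeat_index}_{group}{i % n}"
        sample_ids.append(sid)
        groups[sid] = group
    return CountMatrix(profile.gene_ids, tuple(sample_ids), counts, groups=groups)


def thin_counts(cm: CountMatrix, fraction: float, seed: int) -> CountMatrix:
    """Binomially downsample every count cell to a fraction of its depth.

    Each cell is replaced by Binomial(R_gj, fraction): expected per-gene
    proportions are preserved while the effective depth shrinks.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return cm
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(cm.counts, fraction)
    return CountMatrix(cm.gene_ids, cm.sample_ids, thinned, groups=cm.groups)
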