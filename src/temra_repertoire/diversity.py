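"""Repertoire diversity: richness, normalized entropy, normalized clonality.

The diversity statistic used throughout is the normalized clonality

    clonality = 1 - H / log2(n),   H = -sum_i f_i * log2(f_i)

where ``f_i`` are the clonotype frequencies and ``n`` the richness
(number of distinct clonotypes).  Clonality is 0 for a perfectly
polyclonal (uniform) repertoire and 1 for a monoclonal one.  Samples of
different sequencing depths are made comparable by resampling each to a
fixed number of cells (1000 by default) with replacement and averaging
the clonality over bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ValidationError
from .models import Repertoire

_SUM_TOL = 1e-9


def _validated_freqs(frequencies) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or f.size < 1:
        raise ValidationError("frequencies must be a non-empty 1-D vector")
    if np.any(f <= 0):
        raise ValidationError("all frequencies must be > 0")
    if abs(f.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(
            f"frequencies must sum to 1 (got {f.sum():.12g})"
        )
    return f


def normalized_entropy(frequencies) -> float:
    """Shannon entropy of the frequency vector divided by log2(n).

    For a single clonotype (n = 1) the normalization log2(1) = 0 is
    degenerate; by convention the entropy is 0 (and clonality 1),
    matching the monoclonal limit of the statistic's interpretation.
    """
    f = _validated_freqs(frequencies)
    n = f.size
    if n == 1:
        return 0.0
    h = -float(np.dot(f, np.log2(f))) / np.log2(n)
    # guard tiny negative / >1 excursions from rounding
    return float(min(1.0, max(0.0, h)))


def normalized_clonality(frequencies) -> float:
    """1 - normalized entropy: 0 = polyclonal/uniform, 1 = monoclonal."""
    return 1.0 - normalized_entropy(frequencies)


def richness(rep: Repertoire) -> int:
    """Number of distinct clonotypes in the repertoire."""
    return rep.richness


def clonality_of_counts(counts: np.ndarray) -> float:
    """Normalized clonality of a raw count vector (zeros are dropped:
    a clonotype absent from a sample is not part of its richness)."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    return normalized_clonality(counts / counts.sum())


@dataclass
class BootstrapSummary:
    """Bootstrap distribution of clonality at fixed subsample size."""

    subsample_size: int
    n_replicates: int
    seed: int
    clonality_mean: float
    clonality_sd: float
    clonality_ci95: tuple[float, float]


@dataclass
class DiversitySummary:
    """Diversity report for one (donor, subset) repertoire."""

    donor_id: str
    subset: str
    richness: int
    normalized_entropy: float
    normalized_clonality: float
    monoclonal: bool = False
    bootstrap: BootstrapSummary | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def bootstrap_normalize(
    rep: Repertoire,
    subsample_size: int = 1000,
    n_replicates: int = 100,
    seed: int = 0,
) -> DiversitySummary:
    """Size-normalized clonality via bootstrap resampling.

    Each replicate draws ``subsample_size`` cells with replacement from
    the repertoire's clone distribution and recomputes clonality on the
    resampled counts; the replicate's richness (clonotypes actually
    drawn) is the ``n`` of the normalization.  Output is bit-identical
    for identical inputs and seed.
    """
    if subsample_size < 1:
        raise ValidationError(f"subsample_size must be >= 1, got {subsample_size}")
    if n_replicates < 1:
        raise ValidationError(f"n_replicates must be >= 1, got {n_replicates}")
    rng = np.random.default_rng(seed)
    probs = rep.frequency_array()
    draws = rng.multinomial(subsample_size, probs, size=n_replicates)
    vals = np.array([clonality_of_counts(row) for row in draws])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    boot = BootstrapSummary(
        subsample_size=subsample_size,
        n_replicates=n_replicates,
        seed=seed,
        clonality_mean=float(vals.mean()),
        clonality_sd=float(vals.std(ddof=1)) if n_replicates > 1 else 0.0,
        clonality_ci95=(float(lo), float(hi)),
    )
    return _summary(rep, bootstrap=boot)


def _summary(rep: Repertoire, bootstrap: BootstrapSummary | None = None
             ) -> DiversitySummary:
    h = normalized_entropy(rep.frequency_array())
    return DiversitySummary(
        donor_id=rep.donor_id,
        subset=rep.subset,
        richness=rep.richness,
        normalized_entropy=h,
        normalized_clonality=1.0 - h,
        monoclonal=rep.richness == 1,
        bootstrap=bootstrap,
    )


def diversity_summary(
    rep: Repertoire,
    bootstrap: bool = False,
    subsample_size: int = 1000,
    n_replicates: int = 100,
    seed: int = 0,
) -> DiversitySummary:
    """Full diversity report, optionally with bootstrap normalization."""
    if bootstrap:
        return bootstrap_normalize(rep, subsample_size=subsample_size,
                                   n_replicates=n_replicates, seed=seed)
    return _summary(rep)


def diversity_table(summaries: list[DiversitySummary]) -> pd.DataFrame:
    """Flatten summaries into one row per (donor, subset)."""
    rows = []
    for s in summaries:
        row = {
            "donor_id": s.donor_id,
            "subset": s.subset,
            "richness": s.richness,
            "normalized_entropy": s.normalized_entropy,
            "normalized_clonality": s.normalized_clonality,
        }
        if s.bootstrap is not None:
            b = s.bootstrap
            row.update(
                subsample_size=b.subsample_size,
                n_replicates=b.n_replicates,
                bootstrap_seed=b.seed,
                clonality_mean=b.clonality_mean,
                clonality_sd=b.clonality_sd,
                clonality_ci95_low=b.clonality_ci95[0],
                clonality_ci95_high=b.clonality_ci95[1],
            )
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_subset_tests(table: pd.DataFrame,
                          value_col: str = "normalized_clonality"
                          ) -> pd.DataFrame:
    """Two-tailed Mann-Whitney U between every pair of subsets.

    Convenience wrapper over scipy; unadjusted p-values, as is usual for
    small pairwise subset comparisons of repertoire clonality.
    """
    subsets = sorted(table["subset"].unique())
    rows = []
    for i, a in enumerate(subsets):
        for b in subsets[i + 1:]:
            xa = table.loc[table["subset"] == a, value_col]
            xb = table.loc[table["subset"] == b, value_col]
            if len(xa) == 0 or len(xb) == 0:
                continue
            res = mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append({"subset_a": a, "subset_b": b,
                         "n_a": len(xa), "n_b": len(xb),
                         "U": float(res.statistic),
                         "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)
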