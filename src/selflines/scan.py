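"""Per-locus F_ST distribution analysis and migration arithmetic.

Between diverged lineages exchanging some genes, the distribution of
per-locus F_ST is characteristically U-shaped: most loci introgress freely
(F_ST near 0) while "divergence islands" resist gene flow (F_ST near 1).
Among sites within a lineage, drift alone produces a unimodal distribution
instead.  This module summarizes per-locus F_ST vectors into histograms,
counts of high-F_ST loci, overlaps of outlier sets across comparisons, and
a scalar U-shape index, and converts mutation-scaled coalescent estimates
(theta = 4 N_e mu, M = m/mu) into migrants per generation N_e m = theta*M/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FstHistogram",
    "LocusFstTable",
    "MigrationEstimate",
    "fst_distribution",
    "shared_outliers",
    "u_shape_index",
    "migrants_per_generation",
]


@dataclass
class FstHistogram:
    counts: np.ndarray
    edges: np.ndarray
    n_above_threshold: int
    threshold: float
    n_negative: int  # negative estimates, clipped into the lowest bin


def fst_distribution(
    per_locus_fst: np.ndarray, bins: int = 20, threshold: float = 0.9
) -> FstHistogram:
    """Histogram of per-locus F_ST on [0, 1] plus the high-F_ST count.

    NaN entries (loci skipped by the estimator) are dropped.  Negative
    estimates are clipped into the lowest bin and their count flagged.
    """
    v = np.asarray(per_locus_fst, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty F_ST vector")
    n_negative = int((v < 0).sum())
    clipped = np.clip(v, 0.0, 1.0)
    counts, edges = np.histogram(clipped, bins=bins, range=(0.0, 1.0))
    return FstHistogram(
        counts=counts,
        edges=edges,
        n_above_threshold=int((v > threshold).sum()),
        threshold=threshold,
        n_negative=n_negative,
    )


@dataclass
class LocusFstTable:
    """Aligned per-locus F_ST vectors for several pairwise comparisons."""

    loci: list
    comparisons: dict  # name -> per-locus F_ST vector
    threshold: float = 0.9

    def counts_above(self) -> dict:
        return {
            name: int(np.nansum(np.asarray(v) > self.threshold))
            for name, v in self.comparisons.items()
        }

    def overlaps(self) -> dict:
        names = list(self.comparisons)
        out = {}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ids, n = shared_outliers(
                    self.comparisons[a], self.comparisons[b], self.loci, self.threshold
                )
                out[(a, b)] = n
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"locus": self.loci, **self.comparisons})


def shared_outliers(
    fstA: np.ndarray, fstB: np.ndarray, loci=None, threshold: float = 0.9
) -> tuple[list, int]:
    """Loci exceeding ``threshold`` in both comparisons (set intersection)."""
    a = np.asarray(fstA, dtype=float)
    b = np.asarray(fstB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("F_ST vectors must be aligned on the same loci")
    with np.errstate(invalid="ignore"):
        both = (a > threshold) & (b > threshold)
    idx = np.flatnonzero(both)
    ids = [loci[i] for i in idx] if loci is not None else idx.tolist()
    return ids, int(both.sum())


def u_shape_index(counts: np.ndarray, edges: np.ndarray) -> float:
    """Scalar in [-1, 1] contrasting bimodal-extreme vs. central mass.

    With m_low / m_high the mass below 0.1 and above 0.9 and m_mid the
    mass in the central four deciles [0.3, 0.7), the index is

        (2 * min(m_low, m_high) - m_mid) / (2 * min(m_low, m_high) + m_mid).

    Requiring mass at *both* extremes distinguishes a genuine U (positive)
    from a drift-style unimodal-low distribution, which also piles mass in
    the lowest decile but has an empty top decile (negative).  Mass is
    apportioned to deciles by fractional bin overlap, so the sign is stable
    across bin counts whose edges need not align with decile boundaries.
    """
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 bins")
    total = counts.sum()
    if total == 0:
        return 0.0

    def mass(lo, hi):
        left = np.clip(edges[:-1], lo, hi)
        right = np.clip(edges[1:], lo, hi)
        widths = edges[1:] - edges[:-1]
        frac = np.where(widths > 0, (right - left) / np.where(widths > 0, widths, 1), 0)
        return float((counts * frac).sum() / total)

    m_low = mass(0.0, 0.1)
    m_high = mass(0.9, 1.0 + 1e-12)
    m_mid = mass(0.3, 0.7)
    num = 2 * min(m_low, m_high) - m_mid
    den = 2 * min(m_low, m_high) + m_mid
    return float(num / den) if den > 0 else 0.0


@dataclass
class MigrationEstimate:
    """Container for mutation-scaled coalescent estimates.

    theta = 4 N_e mu (mutation-scaled population size), M = m/mu
    (mutation-scaled immigration rate); the implied migrants per
    generation is N_e m = theta * M / 4.
    """

    theta: float
    M: float

    def __post_init__(self):
        if self.theta < 0 or self.M < 0:
            raise ValueError("theta and M must be non-negative")

    @property
    def Nem(self) -> float:
        return migrants_per_generation(self.theta, self.M)


def migrants_per_generation(theta: float, M: float) -> float:
    """Migrants per generation N_e m = (1/4) * theta * M."""
    if theta < 0 or M < 0:
        raise ValueError("theta and M must be non-negative")
    return theta * M / 4.0
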