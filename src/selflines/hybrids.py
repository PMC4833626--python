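"""Hybrid simulation, hybrid-index estimation, and hybrid classification.

A putative hybrid between two inbred lineages is characterized by two
statistics: its individual observed heterozygosity and its hybrid index h
(the maximum-likelihood proportion of its alleles drawn from the second
parental population).  Reference distributions for first-generation
hybrids and their selfed descendants are built by forward simulation:
F1 = cross of individuals randomly sampled from each parental population,
F2 = one generation of selfing each F1, F3 = one further selfing.  Each
selfing generation halves heterozygosity in expectation and widens the
hybrid-index distribution.  Observed individuals are then classified
against the simulated classes.

Genotypes are alt-allele dosages (0/1/2, -1 missing) on shared loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING

__all__ = [
    "cross",
    "self_",
    "observed_heterozygosity",
    "simulate_hybrid_generations",
    "hybrid_index",
    "classify_hybrid",
    "HybridSimResult",
    "HybridCall",
]


# ---------------------------------------------------------------------------
# Mendelian operations
# ---------------------------------------------------------------------------


def _gametes(calls: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete (0/1 alt count, -1 missing) per locus per row."""
    calls = np.atleast_2d(calls)
    g = np.where(calls == 2, 1, 0).astype(np.int8)
    het = calls == 1
    if het.any():
        g[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    g[calls == MISSING] = MISSING
    return g


def cross(parentA: np.ndarray, parentB: np.ndarray, seed=None) -> np.ndarray:
    """Offspring of two individuals: one uniform gamete from each parent.

    A missing parental call makes the offspring call missing at that locus.
    """
    parentA = np.asarray(parentA, dtype=np.int8)
    parentB = np.asarray(parentB, dtype=np.int8)
    if parentA.shape != parentB.shape:
        raise ValueError("parents must be genotyped on the same loci")
    rng = np.random.default_rng(seed)
    gA = _gametes(parentA, rng)
    gB = _gametes(parentB, rng)
    off = gA + gB
    off[(gA == MISSING) | (gB == MISSING)] = MISSING
    return off.reshape(parentA.shape)


def self_(individual: np.ndarray, seed=None) -> np.ndarray:
    """One generation of self-fertilization (two independent gametes)."""
    individual = np.asarray(individual, dtype=np.int8)
    rng = np.random.default_rng(seed)
    g1 = _gametes(individual, rng)
    g2 = _gametes(individual, rng)
    off = g1 + g2
    off[(g1 == MISSING) | (g2 == MISSING)] = MISSING
    return off.reshape(individual.shape)


def observed_heterozygosity(calls: np.ndarray) -> float | np.ndarray:
    """Fraction of heterozygous calls among non-missing loci.

    Accepts one individual (1-D) or a matrix (2-D, one row per individual).
    """
    calls = np.asarray(calls)
    if calls.ndim == 1:
        valid = calls != MISSING
        return float((calls[valid] == 1).mean()) if valid.any() else float("nan")
    valid = calls != MISSING
    nval = valid.sum(axis=1)
    het = ((calls == 1) & valid).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nval > 0, het / np.maximum(nval, 1), np.nan)


# ---------------------------------------------------------------------------
# hybrid index (Buerkle-style ML estimator)
# ---------------------------------------------------------------------------


def _loglik_grid(
    calls: np.ndarray, freqsA: np.ndarray, freqsB: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Log-likelihood of h over ``grid`` for each row of ``calls``.

    Model: each of the individual's two gene copies at a locus derives from
    population B with probability h, so the alt-allele probability is
    q(h) = h*pB + (1-h)*pA and genotypes are binomial in q(h).
    Returns an array (n_grid, n_individuals).
    """
    calls = np.atleast_2d(calls)
    pA = np.asarray(freqsA, dtype=float)
    pB = np.asarray(freqsB, dtype=float)
    ok = ~(np.isnan(pA) | np.isnan(pB))
    calls = calls[:, ok]
    pA, pB = pA[ok], pB[ok]
    eps = 1e-12
    q = np.clip(grid[:, None] * pB[None, :] + (1 - grid[:, None]) * pA[None, :], eps, 1 - eps)
    logp = {
        0: 2 * np.log1p(-q),
        1: np.log(2) + np.log(q) + np.log1p(-q),
        2: 2 * np.log(q),
    }
    ll = np.zeros((len(grid), calls.shape[0]))
    for g, lp in logp.items():
        ind = (calls == g).astype(float)  # (n_ind, L)
        ll += lp @ ind.T
    return ll


@dataclass
class HybridIndexEstimate:
    h: float
    interval: tuple[float, float]  # 2-log-likelihood-unit support region
    h_counting: float  # diagnostic-allele fraction at fixed differences
    n_informative: int


def hybrid_index(
    calls: np.ndarray,
    freqsA: np.ndarray,
    freqsB: np.ndarray,
    grid_size: int = 1001,
) -> HybridIndexEstimate:
    """ML hybrid index of one individual with a 2-unit support interval.

    h = 0 means pure population A ancestry, h = 1 pure population B.  The
    counting estimator (fraction of B-diagnostic alleles among loci fixed
    for alternate alleles in the two populations) is reported alongside as
    a cross-check; the two coincide when every locus is a fixed difference
    and nothing is missing.
    """
    calls = np.asarray(calls, dtype=np.int8)
    pA = np.asarray(freqsA, dtype=float)
    pB = np.asarray(freqsB, dtype=float)
    valid = (calls != MISSING) & ~(np.isnan(pA) | np.isnan(pB))
    if not (np.abs(pA[valid] - pB[valid]) > 0).any():
        raise ValueError("no informative loci: parental frequencies identical")

    grid = np.linspace(0.0, 1.0, grid_size)
    masked = np.where(valid, calls, MISSING)[None, :]
    ll = _loglik_grid(masked, pA, pB, grid)[:, 0]
    # _loglik_grid ignores missing codes because they match no genotype class
    best = int(np.argmax(ll))
    h = float(grid[best])
    # refine an interior maximum by solving the score equation dLL/dh = 0
    if 0 < best < grid_size - 1:
        from scipy.optimize import brentq

        sub = valid & (np.abs(pA - pB) > 0)
        g = calls[sub].astype(float)
        pa, delta = pA[sub], (pB - pA)[sub]
        eps = 1e-12

        def score(hh):
            q = np.clip(pa + hh * delta, eps, 1 - eps)
            return float(
                (delta * (np.where(g == 2, 2 / q, 0.0)
                          + np.where(g == 1, 1 / q - 1 / (1 - q), 0.0)
                          + np.where(g == 0, -2 / (1 - q), 0.0))).sum()
            )

        lo, hi = float(grid[best - 1]), float(grid[best + 1])
        s_lo, s_hi = score(lo), score(hi)
        if s_lo > 0 > s_hi:
            h = float(brentq(score, lo, hi, xtol=1e-14))
    support = grid[ll >= ll[best] - 2.0]
    interval = (float(support.min()), float(support.max()))

    fixed = valid & (np.abs(pA - pB) == 1.0)
    if fixed.any():
        b_allele_is_alt = pB[fixed] == 1.0
        dosage = calls[fixed].astype(float)
        b_count = np.where(b_allele_is_alt, dosage, 2 - dosage)
        h_count = float(b_count.sum() / (2 * fixed.sum()))
    else:
        h_count = float("nan")
    return HybridIndexEstimate(
        h=float(np.clip(h, 0.0, 1.0)),
        interval=interval,
        h_counting=h_count,
        n_informative=int(valid.sum()),
    )


def _hybrid_index_batch(
    calls: np.ndarray, freqsA, freqsB, grid_size: int = 401
) -> np.ndarray:
    """Vectorized ML hybrid index for many individuals (grid + parabola)."""
    grid = np.linspace(0.0, 1.0, grid_size)
    ll = _loglik_grid(calls, np.asarray(freqsA), np.asarray(freqsB), grid)
    best = np.argmax(ll, axis=0)
    h = grid[best]
    inner = (best > 0) & (best < grid_size - 1)
    i = best[inner]
    cols = np.flatnonzero(inner)
    y0 = ll[i - 1, cols]
    y1 = ll[i, cols]
    y2 = ll[i + 1, cols]
    denom = y0 - 2 * y1 + y2
    adj = np.where(denom < 0, 0.5 * (y0 - y2) / np.where(denom < 0, denom, 1.0), 0.0)
    h[inner] = grid[i] + adj * (grid[1] - grid[0])
    return np.clip(h, 0.0, 1.0)


# ---------------------------------------------------------------------------
# generation simulation
# ---------------------------------------------------------------------------


@dataclass
class HybridSimResult:
    """Reference distributions for simulated F1/F2/F3 hybrid classes."""

    het: dict  # class -> (n_sim,) heterozygosity
    h: dict  # class -> (n_sim,) hybrid index
    seed: int | None
    parents: tuple
    n_sim: int

    @property
    def classes(self) -> list[str]:
        return list(self.het)

    def class_means(self) -> dict:
        return {c: (float(np.mean(self.het[c])), float(np.mean(self.h[c]))) for c in self.het}

    def class_sds(self) -> dict:
        return {
            c: (float(np.std(self.het[c], ddof=1)), float(np.std(self.h[c], ddof=1)))
            for c in self.het
        }


def simulate_hybrid_generations(
    popA: np.ndarray,
    popB: np.ndarray,
    n_sim: int = 1000,
    seed=None,
    freqsA=None,
    freqsB=None,
    parent_ids: tuple = ("A", "B"),
) -> HybridSimResult:
    """Simulate n_sim F1 hybrids, then F2 and F3 by one selfing each.

    ``popA``/``popB`` are (n_individuals, n_loci) dosage matrices; each F1
    crosses one uniformly sampled individual from each.  Hybrid indices are
    computed against ``freqsA``/``freqsB`` (defaults: the sample allele
    frequencies of the parental matrices).
    """
    popA = np.atleast_2d(np.asarray(popA, dtype=np.int8))
    popB = np.atleast_2d(np.asarray(popB, dtype=np.int8))
    if popA.shape[1] != popB.shape[1]:
        raise ValueError("parental populations must share loci")
    if popA.shape[0] == 0 or popB.shape[0] == 0:
        raise ValueError("parental populations must be non-empty")
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2 (standard deviations undefined)")
    rng = np.random.default_rng(seed)

    def freq(pop):
        valid = pop != MISSING
        return np.where(valid, pop, 0).sum(axis=0) / np.maximum(2 * valid.sum(axis=0), 1)

    fA = freq(popA) if freqsA is None else np.asarray(freqsA, dtype=float)
    fB = freq(popB) if freqsB is None else np.asarray(freqsB, dtype=float)

    ia = rng.integers(0, popA.shape[0], size=n_sim)
    ib = rng.integers(0, popB.shape[0], size=n_sim)
    A = popA[ia]
    B = popB[ib]
    gA = _gametes(A, rng)
    gB = _gametes(B, rng)
    F1 = (gA + gB).astype(np.int8)
    F1[(gA == MISSING) | (gB == MISSING)] = MISSING

    def self_matrix(M):
        g1 = _gametes(M, rng)
        g2 = _gametes(M, rng)
        out = (g1 + g2).astype(np.int8)
        out[(g1 == MISSING) | (g2 == MISSING)] = MISSING
        return out

    F2 = self_matrix(F1)
    F3 = self_matrix(F2)

    het = {c: observed_heterozygosity(M) for c, M in (("F1", F1), ("F2", F2), ("F3", F3))}
    h = {
        c: _hybrid_index_batch(M, fA, fB)
        for c, M in (("F1", F1), ("F2", F2), ("F3", F3))
    }
    return HybridSimResult(het=het, h=h, seed=seed, parents=parent_ids, n_sim=n_sim)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class HybridCall:
    individual_id: object
    het: float
    h: float
    label: str  # F1 | F2 | F3 | backcross-like | parental | uncertain
    percentiles: dict  # class -> (het percentile, h percentile)


def _percentile_of(values: np.ndarray, x: float) -> float:
    values = np.sort(np.asarray(values))
    return float(np.searchsorted(values, x, side="right") / len(values))


def classify_hybrid(
    obs: tuple[float, float],
    sim: HybridSimResult,
    alpha: float = 0.05,
    individual_id=None,
) -> HybridCall:
    """Assign an observed (heterozygosity, hybrid index) pair to a class.

    The acceptance region of each simulated class is a per-margin
    percentile box; to give the box joint coverage of about 1 - alpha the
    margins use Bonferroni-split levels (each margin keeps its central
    1 - alpha/2 interval).  An observation inside at least one box is
    labelled with the deepest such class.  Outside all boxes: near-zero
    heterozygosity with an extreme index is "parental"; elevated
    heterozygosity with an index outside every class's box is
    "backcross-like"; anything else is "uncertain".
    """
    if not sim.het:
        raise ValueError("simulation result has no classes")
    het_obs, h_obs = float(obs[0]), float(obs[1])
    a = alpha / 2.0  # per-margin level (Bonferroni over the two margins)

    depth = {}
    in_box = {}
    percentiles = {}
    h_box_union = []
    for c in sim.classes:
        p_het = _percentile_of(sim.het[c], het_obs)
        p_h = _percentile_of(sim.h[c], h_obs)
        percentiles[c] = (p_het, p_h)
        d_het = 2 * min(p_het, 1 - p_het)
        d_h = 2 * min(p_h, 1 - p_h)
        depth[c] = min(d_het, d_h)
        lo_het, hi_het = np.quantile(sim.het[c], [a / 2, 1 - a / 2])
        lo_h, hi_h = np.quantile(sim.h[c], [a / 2, 1 - a / 2])
        in_box[c] = (lo_het <= het_obs <= hi_het) and (lo_h <= h_obs <= hi_h)
        h_box_union.append((lo_h, hi_h))

    label = None
    members = [c for c in sim.classes if in_box[c]]
    if members:
        label = max(members, key=lambda c: depth[c])
    else:
        min_class_het = min(float(np.mean(sim.het[c])) for c in sim.classes)
        het_floor = max(0.25 * min_class_het, 1e-9)
        h_outside_all = not any(lo <= h_obs <= hi for lo, hi in h_box_union)
        if het_obs < het_floor and (h_obs <= 0.1 or h_obs >= 0.9):
            label = "parental"
        elif het_obs >= het_floor and h_outside_all:
            label = "backcross-like"
        else:
            label = "uncertain"
    return HybridCall(
        individual_id=individual_id,
        het=het_obs,
        h=h_obs,
        label=label,
        percentiles=percentiles,
    )
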