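"""Independent brute-force reference implementations used only by tests.

Each oracle is written as plain loops over individuals, loci and alleles,
following the defining formulas directly, and shares no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def brute_unbiased_he(group_calls: np.ndarray) -> float:
    """Mean over loci of Nei's unbiased gene diversity for one group.

    Per locus with n >= 2 non-missing diploids:
    He = n/(n-1) * (1 - sum_a p_a^2 - Ho/(2n)).
    """
    he_values = []
    for j in range(group_calls.shape[1]):
        col = [c for c in group_calls[:, j] if c != -1]
        n = len(col)
        if n < 2:
            continue
        alt = sum(col)
        p = alt / (2 * n)
        ho = sum(1 for c in col if c == 1) / n
        he = n / (n - 1) * (1 - (p**2 + (1 - p) ** 2) - ho / (2 * n))
        he_values.append(he)
    return float(np.mean(he_values))


def brute_neis_d(freqA, freqB) -> float:
    """Nei (1972) standard distance by direct evaluation of the J sums."""
    jx = jy = jxy = 0.0
    L = 0
    for pa, pb in zip(freqA, freqB):
        if math.isnan(pa) or math.isnan(pb):
            continue
        L += 1
        for x, y in ((pa, pb), (1 - pa, 1 - pb)):
            jx += x * x
            jy += y * y
            jxy += x * y
    jx, jy, jxy = jx / L, jy / L, jxy / L
    return -math.log(jxy / math.sqrt(jx * jy))


def _wc_components(calls: np.ndarray, pops: np.ndarray, j: int):
    """Summed-over-alleles (a, b, c) variance components at locus j.

    Follows the original multi-allele formulation: components are computed
    separately for each allele from genotype counts and summed.  Returns
    None when the locus is unusable (fewer than 2 populations with data,
    mean sample size <= 1).
    """
    labels = sorted(set(pops), key=str)
    pop_data = []
    for g in labels:
        col = [c for c, p in zip(calls[:, j], pops) if p == g and c != -1]
        if col:
            pop_data.append(col)
    r = len(pop_data)
    if r < 2:
        return None
    ns = [len(col) for col in pop_data]
    nbar = sum(ns) / r
    if nbar <= 1:
        return None
    nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
    if nc <= 0:
        return None
    a_sum = b_sum = c_sum = 0.0
    for allele in (0, 1):  # 0 = ref, 1 = alt
        ps, hs = [], []
        for col in pop_data:
            n = len(col)
            count = sum(col) if allele == 1 else sum(2 - c for c in col)
            het = sum(1 for c in col if c == 1)
            ps.append(count / (2 * n))
            hs.append(het / n)
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = nbar / nc * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def brute_wc_theta_per_locus(calls: np.ndarray, pops: np.ndarray) -> np.ndarray:
    """Weir & Cockerham (1984) per-locus theta by per-allele summation."""
    out = np.full(calls.shape[1], np.nan)
    for j in range(calls.shape[1]):
        comps = _wc_components(calls, pops, j)
        if comps is None:
            continue
        a, b, c = comps
        if a + b + c != 0:
            out[j] = a / (a + b + c)
    return out


def brute_wc_multilocus(calls: np.ndarray, pops: np.ndarray) -> float:
    """Ratio-of-sums multilocus theta: sum(a) / sum(a + b + c)."""
    num = den = 0.0
    for j in range(calls.shape[1]):
        comps = _wc_components(calls, pops, j)
        if comps is None:
            continue
        a, b, c = comps
        if a + b + c == 0:
            continue
        num += a
        den += a + b + c
    return num / den


def arc_length_fourier_first_harmonic(pts: np.ndarray) -> tuple[float, float]:
    """First-harmonic cosine amplitudes of x(s), y(s) over arc length s.

    Direct midpoint-rule evaluation of a1 = (2/S) * integral x cos(2 pi s/S) ds
    and d1 = (2/S) * integral y sin(2 pi s/S) ds for an axis-aligned outline
    starting on the positive x axis; independent of the chain-summation code.
    """
    pts = np.asarray(pts, dtype=float)
    d = np.diff(pts, axis=0, append=pts[:1])
    dt = np.hypot(d[:, 0], d[:, 1])
    s = np.concatenate([[0.0], np.cumsum(dt)])
    S = s[-1]
    mid = (s[:-1] + s[1:]) / 2
    phi = 2 * np.pi * mid / S
    xm = (pts[:, 0] + np.roll(pts[:, 0], -1)) / 2
    ym = (pts[:, 1] + np.roll(pts[:, 1], -1)) / 2
    a1 = 2 / S * float((xm * np.cos(phi) * dt).sum())
    d1 = 2 / S * float((ym * np.sin(phi) * dt).sum())
    return a1, d1


def brute_ml_hybrid_index(calls, freqsA, freqsB) -> float:
    """ML hybrid index by solving the score equation with plain loops."""
    data = [
        (int(g), float(pa), float(pb))
        for g, pa, pb in zip(calls, freqsA, freqsB)
        if g != -1 and not (math.isnan(pa) or math.isnan(pb))
    ]
    eps = 1e-12

    def loglik(h):
        ll = 0.0
        for g, pa, pb in data:
            q = min(max(h * pb + (1 - h) * pa, eps), 1 - eps)
            if g == 0:
                ll += 2 * math.log(1 - q)
            elif g == 1:
                ll += math.log(2 * q * (1 - q))
            else:
                ll += 2 * math.log(q)
        return ll

    def score(h):
        s = 0.0
        for g, pa, pb in data:
            d = pb - pa
            if d == 0:
                continue
            q = min(max(h * pb + (1 - h) * pa, eps), 1 - eps)
            if g == 0:
                s += -2 * d / (1 - q)
            elif g == 1:
                s += d * (1 / q - 1 / (1 - q))
            else:
                s += 2 * d / q
        return s

    grid = [i / 1000 for i in range(1001)]
    vals = [loglik(h) for h in grid]
    best = max(range(1001), key=lambda i: vals[i])
    if best in (0, 1000):
        return grid[best]
    lo, hi = grid[best - 1], grid[best + 1]
    if score(lo) > 0 > score(hi):
        return float(brentq(score, lo, hi, xtol=1e-14))
    return grid[best]
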