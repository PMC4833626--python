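"""Leaf-shape and trait analysis.

Closed leaflet outlines are decomposed by elliptic Fourier analysis
(Kuhl & Giardina chain formulation over the closed polygon with arc-length
parameterization).  Harmonic n contributes four coefficients
(a_n, b_n, c_n, d_n); normalization removes translation, scale, rotation
and starting point, after which coefficients from different leaves are
comparable and can be summarized by PCA.  Measured traits (leaflet
length:width ratios, petiolule ratio, hair density) are compared across
lineages by one-way ANOVA with Tukey HSD contrasts, and lineage membership
is predicted from traits plus the first lateral-shape PC by linear
discriminant analysis with leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "Outline",
    "EFACoefficients",
    "LdaReport",
    "elliptic_fourier",
    "normalize_efa",
    "inverse_efa",
    "efa_pca",
    "harmonic_power",
    "trait_anova",
    "lda_loocv",
]


# ---------------------------------------------------------------------------
# outlines
# ---------------------------------------------------------------------------


@dataclass
class Outline:
    """Closed 2-D contour: ordered (x, y) points, last implicitly joined
    to the first."""

    points: np.ndarray
    individual_id: object = None
    role: str = "terminal"  # terminal | lateral

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        # drop an explicitly repeated closing point
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 32:
            raise ValueError("outline needs at least 32 points")
        self.points = pts
        if self._self_intersects():
            warnings.warn("outline appears to self-intersect")

    def _self_intersects(self) -> bool:
        try:
            from shapely.geometry import LinearRing

            return not LinearRing(self.points).is_simple
        except Exception:
            return False

    def aspect_ratio(self) -> float:
        """Bounding-box long-axis : short-axis ratio."""
        ext = self.points.max(axis=0) - self.points.min(axis=0)
        lo, hi = sorted(ext)
        return float(hi / lo) if lo > 0 else float("inf")


# ---------------------------------------------------------------------------
# elliptic Fourier analysis
# ---------------------------------------------------------------------------


@dataclass
class EFACoefficients:
    """Harmonic coefficients: ``coeffs[n-1] = (a_n, b_n, c_n, d_n)``."""

    coeffs: np.ndarray  # (n_harmonics, 4)
    A0: float
    C0: float
    normalized: bool = False

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    def flat(self) -> np.ndarray:
        return self.coeffs.ravel()


def elliptic_fourier(outline: Outline | np.ndarray, n_harmonics: int) -> EFACoefficients:
    """Elliptic Fourier decomposition of a closed polygonal outline.

    The number of harmonics is capped at floor(n_points / 2) (the Nyquist
    limit of the polygon), with a warning when the request exceeds it.
    """
    if not isinstance(outline, Outline):
        outline = Outline(np.asarray(outline, dtype=float))
    pts = outline.points
    K = len(pts)
    max_h = K // 2
    if n_harmonics > max_h:
        warnings.warn(
            f"{n_harmonics} harmonics exceeds the outline's support; using {max_h}"
        )
        n_harmonics = max_h
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")

    d = np.diff(pts, axis=0, append=pts[:1])  # chain vectors, closed
    dt = np.hypot(d[:, 0], d[:, 1])
    if (dt == 0).any():
        keep = dt > 0
        if keep.sum() < 3:
            raise ValueError("degenerate outline (zero total length)")
        pts = pts[keep]
        d = np.diff(pts, axis=0, append=pts[:1])
        dt = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2 * np.pi * t / T  # (K+1,)

    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (N, K)
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    coef = T / (2 * (n.ravel() ** 2) * np.pi**2)
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = coef * (dx_dt * dcos).sum(axis=1)
    b = coef * (dx_dt * dsin).sum(axis=1)
    c = coef * (dy_dt * dcos).sum(axis=1)
    dd = coef * (dy_dt * dsin).sum(axis=1)

    # offsets (A0, C0): mean position over arc length
    xi = np.cumsum(d[:, 0]) - d[:, 0] - dx_dt * t[:-1]
    delta = np.cumsum(d[:, 1]) - d[:, 1] - dy_dt * t[:-1]
    A0 = pts[0, 0] + (
        (dx_dt / 2 * (t[1:] ** 2 - t[:-1] ** 2) + xi * dt).sum() / T
    )
    C0 = pts[0, 1] + (
        (dy_dt / 2 * (t[1:] ** 2 - t[:-1] ** 2) + delta * dt).sum() / T
    )
    coeffs = np.column_stack([a, b, c, dd])
    return EFACoefficients(coeffs=coeffs, A0=float(A0), C0=float(C0))


def _rotate_start(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point by angle theta along the outline."""
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        n = i + 1
        a, b, c, d = coeffs[i]
        ct, st = np.cos(n * theta), np.sin(n * theta)
        out[i] = (
            a * ct + b * st,
            -a * st + b * ct,
            c * ct + d * st,
            -c * st + d * ct,
        )
    return out


def _rotate_space(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the coordinate frame by angle psi."""
    ct, st = np.cos(psi), np.sin(psi)
    R = np.array([[ct, st], [-st, ct]])
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        M = coeffs[i].reshape(2, 2)
        out[i] = (R @ M).ravel()
    return out


def _reverse_direction(coeffs: np.ndarray) -> np.ndarray:
    """Coefficients of the same outline traversed in the other direction."""
    out = coeffs.copy()
    out[:, 1] *= -1
    out[:, 3] *= -1
    return out


def normalize_efa(
    efa: EFACoefficients,
    scale: bool = True,
    allow_reflection: bool = True,
) -> EFACoefficients:
    """Normalize coefficients to a standard position.

    Removes translation (offsets dropped), rotates the starting point and
    the coordinate frame so the first harmonic is an axis-aligned ellipse
    traced from its semi-major axis (a1 > 0, b1 = c1 = 0), and optionally
    scales by the semi-major axis length.  With ``allow_reflection`` the
    traversal direction is canonicalized (d1 >= 0), making the result
    invariant to outline reversal.  Residual two-fold ambiguities are
    resolved by choosing the lexicographically largest coefficient vector,
    which makes the normalization deterministic and transform-invariant.
    """
    C = efa.coeffs.astype(float)
    a1, b1, c1, d1 = C[0]
    denom = a1**2 + c1**2 - b1**2 - d1**2
    theta = 0.5 * np.arctan2(2 * (a1 * b1 + c1 * d1), denom)
    mag1 = np.hypot(a1, c1)
    if mag1 == 0 and np.hypot(b1, d1) == 0:
        raise ValueError("zero first harmonic; cannot normalize")

    candidates = []
    directions = (False, True) if allow_reflection else (False,)
    for reverse in directions:
        base = _reverse_direction(C) if reverse else C
        a1, b1, c1, d1 = base[0]
        theta = 0.5 * np.arctan2(
            2 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
        )
        for extra in (0.0, np.pi):
            S = _rotate_start(base, theta + extra)
            psi = np.arctan2(S[0, 2], S[0, 0])
            R = _rotate_space(S, psi)
            if scale:
                R = R / abs(R[0, 0])
            if allow_reflection and R[0, 3] < 0:
                continue
            candidates.append(R)
    if not candidates:  # all candidates reflected away; keep raw ones
        for extra in (0.0, np.pi):
            S = _rotate_start(C, theta + extra)
            psi = np.arctan2(S[0, 2], S[0, 0])
            R = _rotate_space(S, psi)
            if scale:
                R = R / abs(R[0, 0])
            candidates.append(R)
    key = [tuple(np.round(c.ravel(), 9)) for c in candidates]
    best = candidates[max(range(len(candidates)), key=lambda i: key[i])]
    return EFACoefficients(coeffs=best, A0=0.0, C0=0.0, normalized=True)


def inverse_efa(efa: EFACoefficients, n_points: int = 256) -> Outline:
    """Reconstruct a closed outline from (possibly truncated) harmonics."""
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    x = np.full(n_points, efa.A0)
    y = np.full(n_points, efa.C0)
    for i in range(efa.n_harmonics):
        n = i + 1
        a, b, c, d = efa.coeffs[i]
        x += a * np.cos(n * t) + b * np.sin(n * t)
        y += c * np.cos(n * t) + d * np.sin(n * t)
    return Outline(np.column_stack([x, y]))


def harmonic_power(efa: EFACoefficients) -> np.ndarray:
    """Per-harmonic power (a^2+b^2+c^2+d^2)/2; cumulative sums approach
    the total shape power as harmonics increase."""
    return (efa.coeffs**2).sum(axis=1) / 2.0


def efa_pca(coefficient_sets: list[EFACoefficients], n_components: int = 2):
    """PCA on stacked normalized coefficient vectors.

    Returns (scores, variance_fraction).  Requires at least 3 outlines.
    """
    if len(coefficient_sets) < 3:
        raise ValueError("need at least 3 outlines")
    X = np.vstack([e.flat() for e in coefficient_sets])
    if n_components > min(X.shape):
        raise ValueError("fewer outlines than requested components")
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S**2).sum())
    scores = U[:, :n_components] * S[:n_components]
    var_frac = (S[:n_components] ** 2 / total) if total > 0 else S[:n_components] * 0.0
    return scores, var_frac


# ---------------------------------------------------------------------------
# trait ANOVA + Tukey
# ---------------------------------------------------------------------------


def _tukey_letters(groups: list, reject: dict) -> dict:
    """Compact letter display from pairwise rejection results.

    Groups that share a letter are not significantly different.  Greedy
    insertion: each group joins every letter-set it is compatible with,
    opening a new letter when none fits.
    """
    letter_sets: list[set] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(not reject.get(frozenset((g, other)), False) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # assign letters in order
    out = {g: "" for g in groups}
    for li, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                out[g] += chr(ord("a") + li)
    return out


def trait_anova(traits: pd.DataFrame, labels, trait_cols=None, alpha: float = 0.05):
    """One-way fixed-effects ANOVA per trait with Tukey HSD letters.

    Returns a DataFrame with one row per trait: between-group mean square,
    F, p, per-group means/SEs and Tukey letters (Tukey-Kramer adjustment
    for unbalanced groups, via statsmodels).  A trait with zero
    within-group variance has an undefined F, reported as NaN and flagged.
    """
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if trait_cols is None:
        trait_cols = [
            c for c in traits.columns if c not in ("id", "lineage", "label", "group")
        ]
    rows = []
    for trait in trait_cols:
        y = traits[trait].to_numpy(dtype=float)
        by_group = [y[labels == g] for g in groups]
        if any(len(v) < 2 for v in by_group):
            raise ValueError("need >= 2 individuals per group")
        grand = y.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group)
        df_between = len(groups) - 1
        ms_between = ss_between / df_between
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group)
        df_within = len(y) - len(groups)
        rec = {
            "trait": trait,
            "MS": ms_between,
            "df_between": df_between,
            "df_within": df_within,
        }
        if ss_within == 0:
            rec.update(F=np.nan, p=np.nan, flag="zero within-group variance")
            letters = {g: "" for g in groups}
        else:
            F, p = stats.f_oneway(*by_group)
            rec.update(F=float(F), p=float(p), flag="")
            tk = pairwise_tukeyhsd(y, labels, alpha=alpha)
            reject = {}
            res = pd.DataFrame(
                data=tk._results_table.data[1:], columns=tk._results_table.data[0]
            )
            for _, r in res.iterrows():
                reject[frozenset((r["group1"], r["group2"]))] = bool(r["reject"])
            letters = _tukey_letters(groups, reject)
        for g in groups:
            v = y[labels == g]
            rec[f"mean_{g}"] = float(v.mean())
            rec[f"se_{g}"] = float(v.std(ddof=1) / np.sqrt(len(v)))
            rec[f"letter_{g}"] = letters[g]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# LDA with leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class LdaReport:
    confusion: pd.DataFrame  # truth (rows) x predicted (columns)
    success_rate: float  # percent
    per_class_rate: dict


def lda_loocv(
    features: pd.DataFrame | np.ndarray,
    labels,
    standardize: bool = True,
) -> LdaReport:
    """Linear discriminant analysis with leave-one-out cross-validation.

    The classifier is refit n times, each time predicting the single
    held-out sample; priors are proportional to class frequencies.
    Features are standardized to unit variance by default (recorded
    choice).  Classes with a single member cannot be held out and refit;
    they raise.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("every class needs >= 2 members for LOOCV")
    if np.isnan(X).any():
        raise ValueError("features must be complete-case")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    n = len(X)
    preds = np.empty(n, dtype=object)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = LinearDiscriminantAnalysis()
        clf.fit(X[train], labels[train])
        preds[i] = clf.predict(X[i : i + 1])[0]

    confusion = pd.crosstab(
        pd.Series(labels, name="truth"), pd.Series(preds, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    correct = sum(confusion.loc[c, c] for c in classes if c in confusion.columns)
    success = 100.0 * correct / n
    per_class = {
        c: float(100.0 * confusion.loc[c, c] / counts[c]) for c in classes
    }
    return LdaReport(confusion=confusion, success_rate=float(success), per_class_rate=per_class)
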