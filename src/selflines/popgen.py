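"""Descriptive diversity and divergence statistics for lineage discovery.

Implements, for biallelic SNP matrices with missing data:

* per-group summaries: observed heterozygosity H_o, Nei's unbiased gene
  diversity H_e (with the n/(n-1) small-sample factor), inbreeding
  coefficient F_IS = 1 - H_o/H_e, rarefied allelic richness, and private
  alleles;
* Nei's (1972) standard genetic distance D between allele-frequency
  vectors;
* the Weir & Cockerham (1984) variance-components F_ST estimator theta,
  per locus and multilocus as a ratio of sums;
* genotype PCA on centered alt-allele dosages with per-locus mean
  imputation of missing calls, plus a rule for flagging PCA-intermediate
  individuals as candidate hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "GroupSummary",
    "PairwiseDivergence",
    "PcaResult",
    "group_summary",
    "group_allele_frequencies",
    "neis_distance",
    "wc_fst",
    "genotype_pca",
    "flag_pca_intermediates",
]


# ---------------------------------------------------------------------------
# per-group summaries
# ---------------------------------------------------------------------------


@dataclass
class GroupSummary:
    group: object
    n: int
    Ho: float
    He: float
    Fis: float  # NaN when He == 0 (flagged undefined)
    AR: float
    PA: int
    pctPA: float


def _group_counts(matrix: GenotypeMatrix, grouping) -> tuple[list, dict]:
    grouping = np.asarray(grouping)
    if len(grouping) != matrix.n_individuals:
        raise ValueError("grouping length must match individuals")
    labels = pd.unique(grouping)
    idx = {g: np.flatnonzero(grouping == g) for g in labels}
    return list(labels), idx


def group_allele_frequencies(matrix: GenotypeMatrix, grouping) -> pd.DataFrame:
    """Alt-allele frequency per locus per group (NaN where no data)."""
    labels, idx = _group_counts(matrix, grouping)
    return pd.DataFrame(
        {g: matrix.allele_frequencies(idx[g]) for g in labels},
    )


def _per_group_locus_stats(calls: np.ndarray):
    """n (diploids), alt-allele count, het count per locus for one group."""
    valid = calls != MISSING
    n = valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    het = ((calls == 1) & valid).sum(axis=0)
    return n, alt, het


def _rarefied_richness(n_genes: np.ndarray, alt: np.ndarray, g: int) -> float:
    """Mean over loci of expected allele count in samples of g genes.

    Hurlbert rarefaction for a biallelic locus: each allele contributes
    1 - C(N - c, g)/C(N, g) where N is the number of sampled genes and c
    the allele's count.
    """

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    ok = n_genes >= g
    if not ok.any():
        return float("nan")
    N = n_genes[ok].astype(float)
    c_alt = alt[ok].astype(float)
    c_ref = N - c_alt
    contrib = np.zeros(len(N))
    for c in (c_alt, c_ref):
        present = c > 0
        keep_all = (N - c) < g  # cannot draw g genes avoiding the allele
        p_absent = np.zeros(len(N))
        calc = present & ~keep_all
        p_absent[calc] = np.exp(log_comb(N[calc] - c[calc], g) - log_comb(N[calc], g))
        contrib += np.where(present, 1.0 - p_absent, 0.0)
    return float(contrib.mean())


def group_summary(
    matrix: GenotypeMatrix,
    grouping,
    rarefaction_genes: int | None = None,
) -> pd.DataFrame:
    """Per-group diversity summary (one row per group).

    H_o is the mean over loci of the heterozygote fraction among
    non-missing calls.  H_e is Nei's unbiased gene diversity per locus,
    n/(n-1) * (1 - sum p^2 - H_o/(2n)), averaged over loci with n >= 2.
    F_IS = 1 - H_o/H_e, NaN (flagged) where H_e is 0.  Allelic richness is
    rarefied to ``rarefaction_genes`` sampled genes (default: the smallest
    per-locus non-missing gene count over groups, at least 2).  Private
    alleles are alleles observed in exactly one group of the partition.
    Hybrid or unassigned individuals should be excluded by the caller.
    """
    labels, idx = _group_counts(matrix, grouping)
    if len(labels) < 1:
        raise ValueError("no groups")

    stats = {g: _per_group_locus_stats(matrix.calls[idx[g]]) for g in labels}

    if rarefaction_genes is None:
        g_min = min(int(2 * stats[g][0][stats[g][0] > 0].min()) for g in labels)
        rarefaction_genes = max(2, g_min)

    # allele presence per group for private-allele counts
    presence = {}
    for g in labels:
        n, alt, _het = stats[g]
        ref_count = 2 * n - alt
        presence[g] = np.stack([ref_count > 0, alt > 0])  # (2, L)
    n_groups_with_allele = sum(presence[g] for g in labels)

    rows = []
    for g in labels:
        n, alt, het = stats[g]
        informative = n > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            ho_l = np.where(informative, het / np.maximum(n, 1), np.nan)
            p = np.where(informative, alt / np.maximum(2 * n, 1), np.nan)
        Ho = float(np.nanmean(ho_l))
        n2 = n >= 2
        if not n2.any():
            He = float("nan")
        else:
            nn = n[n2].astype(float)
            ssq = p[n2] ** 2 + (1 - p[n2]) ** 2
            he_l = nn / (nn - 1) * (1.0 - ssq - ho_l[n2] / (2 * nn))
            He = float(he_l.mean())
        Fis = float(1.0 - Ho / He) if He and He > 0 else float("nan")
        AR = _rarefied_richness(2 * n, alt, rarefaction_genes)
        private = (presence[g] & (n_groups_with_allele == 1)).sum()
        total_alleles = presence[g].sum()
        rows.append(
            GroupSummary(
                group=g,
                n=len(idx[g]),
                Ho=Ho,
                He=He,
                Fis=Fis,
                AR=AR,
                PA=int(private),
                pctPA=float(100.0 * private / total_alleles) if total_alleles else 0.0,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------


def neis_distance(freqsA: np.ndarray, freqsB: np.ndarray) -> float:
    """Nei (1972) standard distance between two alt-allele frequency vectors.

    D = -ln( Jxy / sqrt(Jx * Jy) ) with Jx = mean over loci of sum p_x^2,
    Jxy = mean over loci of sum p_x p_y; loci with a missing frequency in
    either population are dropped pairwise.  Returns ``inf`` when the
    populations share no allelic identity (Jxy = 0).
    """
    pA = np.asarray(freqsA, dtype=float)
    pB = np.asarray(freqsB, dtype=float)
    if pA.shape != pB.shape:
        raise ValueError("frequency vectors must be aligned on the same loci")
    ok = ~(np.isnan(pA) | np.isnan(pB))
    if not ok.any():
        raise ValueError("no loci with frequencies in both populations")
    pA, pB = pA[ok], pB[ok]
    qA, qB = 1 - pA, 1 - pB
    Jx = float(np.mean(pA**2 + qA**2))
    Jy = float(np.mean(pB**2 + qB**2))
    Jxy = float(np.mean(pA * pB + qA * qB))
    if Jxy <= 0:
        return float("inf")
    return float(-np.log(Jxy / np.sqrt(Jx * Jy)))


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


@dataclass
class PairwiseDivergence:
    """Divergence between two (or more) subpopulations."""

    neis_D: float
    fst_multilocus: float
    per_locus_fst: np.ndarray
    n_loci_used: int
    n_loci_skipped: int


def wc_fst(
    matrix: GenotypeMatrix,
    partition,
    mode: str = "both",
):
    """Weir-Cockerham theta over the subpopulations given by ``partition``.

    Per-locus theta is a/(a+b+c) from the variance components; the
    multilocus estimate is the ratio of sums sum(a)/sum(a+b+c).  A locus
    contributes only if at least two subpopulations have a non-missing call
    there and the components are defined (mean sample size > 1); loci whose
    total variance a+b+c is zero (monomorphic) are skipped and counted.
    Negative per-locus estimates are retained.

    Returns ``(per_locus, multilocus, n_skipped)`` for ``mode='both'``, or
    just the requested piece for ``mode='per_locus'``/``'multilocus'``.
    """
    labels, idx = _group_counts(matrix, partition)
    if len(labels) < 2:
        raise ValueError("partition must define at least two subpopulations")

    L = matrix.n_loci
    n = np.zeros((len(labels), L))
    p = np.zeros((len(labels), L))
    h = np.zeros((len(labels), L))
    for k, g in enumerate(labels):
        ng, alt, het = _per_group_locus_stats(matrix.calls[idx[g]])
        n[k] = ng
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(ng > 0, alt / np.maximum(2 * ng, 1), 0.0)
            h[k] = np.where(ng > 0, het / np.maximum(ng, 1), 0.0)

    has_data = n > 0
    r = has_data.sum(axis=0).astype(float)  # populations with data per locus
    n_tot = n.sum(axis=0)
    usable = r >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = np.where(usable, n_tot / np.maximum(r, 1), np.nan)
        sum_n2 = (n**2).sum(axis=0)
        nc = np.where(
            usable & (r > 1),
            (n_tot - sum_n2 / np.maximum(n_tot, 1)) / np.maximum(r - 1, 1),
            np.nan,
        )
        pbar = np.where(n_tot > 0, (n * p).sum(axis=0) / np.maximum(n_tot, 1), np.nan)
        s2 = np.where(
            usable,
            (n * (p - pbar) ** 2).sum(axis=0)
            / np.maximum((r - 1) * nbar, 1e-300),
            np.nan,
        )
        hbar = np.where(n_tot > 0, (n * h).sum(axis=0) / np.maximum(n_tot, 1), np.nan)

        pq = pbar * (1 - pbar)
        inner = pq - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0

    denom = a + b + c
    valid = usable & (nbar > 1) & (nc > 0) & np.isfinite(denom) & (denom != 0)
    per_locus = np.full(L, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus[valid] = a[valid] / denom[valid]
    n_skipped = int(L - valid.sum())
    multilocus = (
        float(a[valid].sum() / denom[valid].sum()) if valid.any() else float("nan")
    )

    if mode == "per_locus":
        return per_locus
    if mode == "multilocus":
        return multilocus
    if mode == "both":
        return per_locus, multilocus, n_skipped
    raise ValueError(f"unknown mode {mode!r}")


def pairwise_divergence(
    matrix: GenotypeMatrix, grouping, groupA, groupB
) -> PairwiseDivergence:
    """Nei's D plus Weir-Cockerham theta between two named groups."""
    grouping = np.asarray(grouping)
    sel = np.flatnonzero((grouping == groupA) | (grouping == groupB))
    sub = matrix.subset(individual_idx=sel)
    sub_groups = grouping[sel]
    freqs = group_allele_frequencies(sub, sub_groups)
    per_locus, multi, skipped = wc_fst(sub, sub_groups, mode="both")
    return PairwiseDivergence(
        neis_D=neis_distance(freqs[groupA].to_numpy(), freqs[groupB].to_numpy()),
        fst_multilocus=multi,
        per_locus_fst=per_locus,
        n_loci_used=matrix.n_loci - skipped,
        n_loci_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_individuals, n_components)
    variance_fraction: np.ndarray


def dosage_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with per-locus mean imputation of missing calls."""
    X = matrix.calls.astype(float)
    miss = matrix.missing_mask
    if miss.all(axis=0).any():
        raise ValueError("locus with all calls missing (should not survive QC)")
    if miss.any():
        col_mean = np.where(miss, 0.0, X).sum(axis=0) / (~miss).sum(axis=0)
        X = np.where(miss, col_mean[None, :], X)
    return X


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of centered (not variance-scaled) alt-allele dosages."""
    X = dosage_matrix(matrix)
    X = X - X.mean(axis=0)
    n_components = min(n_components, min(X.shape) - 1)
    if n_components < 1:
        raise ValueError("too few individuals/loci for PCA")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((S**2).sum())
    scores = U[:, :n_components] * S[:n_components]
    var_frac = (S[:n_components] ** 2) / total_var if total_var > 0 else S[:n_components] * 0
    return PcaResult(scores=scores, variance_fraction=var_frac)


def flag_pca_intermediates(
    scores: np.ndarray,
    grouping,
    n_axes: int = 2,
    spread_factor: float = 3.0,
) -> np.ndarray:
    """Flag individuals lying between group clouds on the leading PC axes.

    Convention (candidate-hybrid rule): an individual is flagged when its
    distance to its nearest group centroid exceeds ``spread_factor`` times
    that group's root-mean-square within-group radius, computed on the
    first ``n_axes`` axes with the individual itself excluded from the
    centroid.  Returns a boolean mask.
    """
    grouping = np.asarray(grouping)
    X = np.asarray(scores)[:, :n_axes]
    labels = pd.unique(grouping)
    flagged = np.zeros(len(X), dtype=bool)
    for i in range(len(X)):
        best = None
        for g in labels:
            members = np.flatnonzero((grouping == g) & (np.arange(len(X)) != i))
            if len(members) < 2:
                continue
            centroid = X[members].mean(axis=0)
            radius = np.sqrt(((X[members] - centroid) ** 2).sum(axis=1).mean())
            d = np.linalg.norm(X[i] - centroid)
            if best is None or d < best[0]:
                best = (d, radius)
        if best is not None:
            d, radius = best
            flagged[i] = d > spread_factor * max(radius, 1e-12)
    return flagged
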