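"""Synthetic genotype, sequence, outline, and trait generator.

The generator emulates the statistical structure of a small set of highly
selfing, strongly diverged plant lineages sampled at a handful of sites:

* a two-level allele-frequency model: each lineage has ancestral
  frequencies; site frequencies drift around them following a
  Balding-Nichols beta distribution parameterized by a target among-site
  F_ST; individuals are drawn with an inbreeding coefficient set by a
  number of selfing generations from a randomly mating base
  (F_IS = 1 - 2^-t);
* between-lineage divergence planted as lineage-specific fixed
  differences: a fraction of loci is fixed for the alternate allele in
  exactly one lineage ("star" patterns), so pairwise fixed-difference
  fractions d_ij = f_i + f_j;
* remaining loci carry shared ancestral polymorphism with minor-allele
  frequencies drawn from a scaled beta distribution;
* optional hybrid individuals (F1, selfed F2/F3, backcross) injected by
  running the Mendelian cross/self operators on sampled parents;
* 93-bp RAD consensus sequences per locus whose two allelic variants
  differ exactly at the recorded SNP offsets; a configurable fraction of
  RAD loci carries a second, fully linked SNP (making those loci
  unsuitable for a one-variable-site melt assay);
* closed leaf outlines from a noisy-ellipse family with controlled
  length:width aspect ratio, and a trait table drawn from per-group
  means/SDs.

Calibration helpers compute, in closed form, the expected value of the
downstream diversity estimators under this model (including the
among-site-drift and finite-sample corrections), so that a configuration
built from target H_e / Nei's D values is recovered by estimation up to
sampling error rather than up to an unmodelled bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genotypes import MISSING, RAD_LOCUS_LENGTH, GenotypeMatrix
from .hybrids import cross, self_

__all__ = [
    "LineageConfig",
    "SyntheticDataset",
    "LeafShapeParams",
    "TABLE_TRAITS",
    "simulate_lineage_dataset",
    "simulate_site_structure",
    "simulate_leaf_outlines",
    "simulate_trait_table",
    "solve_pattern_fractions",
    "beta_params_for_diversity",
    "expected_group_he",
    "calibrate_lineage_pair",
]

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class LineageConfig:
    """Generator configuration.

    Parameters
    ----------
    n_lineages
        Number of pure lineages.
    loci
        Number of RAD loci (one primary biallelic SNP each).
    site_plan
        Mapping ``lineage label -> {site label: n individuals}``.
    fixed_diff_fraction
        Either a scalar (two lineages) or a symmetric ``(K, K)`` array of
        per-pair fractions of loci fixed for alternate alleles.
    within_group_maf_dist
        ``(a, b)`` beta parameters; minor allele frequencies at shared
        polymorphic loci are drawn as ``0.5 * Beta(a, b)``.  ``None``
        leaves non-fixed-difference loci monomorphic.
    selfing_generations
        Generations of selfing from a randomly mating base;
        F_IS = 1 - 2**-t (``inf`` allowed, giving complete homozygosity).
    site_drift_fst
        Target Weir-Cockerham F_ST among sites within a lineage.
    missing_rate_individual, missing_rate_locus
        Independent per-call dropout probabilities applied per individual
        and per locus.
    hybrid_spec
        List of ``(lineageA, lineageB, kind, count)`` with kind in
        {"F1", "F2", "F3", "BC"} (BC = F1 x lineageB backcross).
    multi_snp_fraction
        Fraction of RAD loci carrying a second, fully linked SNP.
    seed
        Root seed for all randomness.
    """

    n_lineages: int
    loci: int
    site_plan: dict
    fixed_diff_fraction: object = 0.0
    within_group_maf_dist: tuple | None = None
    selfing_generations: float = float("inf")
    site_drift_fst: float = 0.0
    missing_rate_individual: float = 0.0
    missing_rate_locus: float = 0.0
    hybrid_spec: list = field(default_factory=list)
    multi_snp_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lineages < 1 or self.loci < 1:
            raise ValueError("counts must be positive")
        if sorted(self.site_plan) != sorted(self.lineage_labels()):
            raise ValueError("site_plan must cover every lineage")
        for frac in (
            self.site_drift_fst,
            self.missing_rate_individual,
            self.missing_rate_locus,
            self.multi_snp_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.site_drift_fst >= 1.0:
            raise ValueError("site_drift_fst must be in [0, 1)")
        D = self.pairwise_fixed_fractions()
        if not np.allclose(D, D.T):
            raise ValueError("fixed_diff_fraction must be symmetric")
        if (D < 0).any() or (D > 1).any():
            raise ValueError("fixed_diff_fraction entries must be in [0, 1]")
        solve_pattern_fractions(D)  # raises if infeasible

    def lineage_labels(self) -> list:
        return list(self.site_plan)

    def pairwise_fixed_fractions(self) -> np.ndarray:
        K = self.n_lineages
        D = np.zeros((K, K))
        if np.isscalar(self.fixed_diff_fraction):
            D[~np.eye(K, dtype=bool)] = float(self.fixed_diff_fraction)
        else:
            D = np.asarray(self.fixed_diff_fraction, dtype=float)
            if D.shape != (K, K):
                raise ValueError("fixed_diff_fraction matrix has wrong shape")
        return D

    @property
    def fis(self) -> float:
        t = self.selfing_generations
        return 1.0 if math.isinf(t) else 1.0 - 0.5**t


def solve_pattern_fractions(pairwise: np.ndarray) -> np.ndarray:
    """Lineage-specific pattern fractions f with f_i + f_j = d_ij.

    Pattern i fixes the alternate allele in lineage i only.  For two
    lineages the single off-diagonal entry is returned as one pattern.
    Raises if the pairwise targets are inconsistent with such patterns or
    sum beyond one.
    """
    D = np.asarray(pairwise, dtype=float)
    K = D.shape[0]
    if K == 1:
        return np.zeros(1)
    if K == 2:
        f = np.array([D[0, 1], 0.0])
    else:
        pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
        A = np.zeros((len(pairs), K))
        y = np.zeros(len(pairs))
        for row, (i, j) in enumerate(pairs):
            A[row, i] = A[row, j] = 1.0
            y[row] = D[i, j]
        f, *_ = np.linalg.lstsq(A, y, rcond=None)
        if not np.allclose(A @ f, y, atol=1e-9):
            raise ValueError(
                "pairwise fixed-difference fractions are not representable "
                "by lineage-specific fixed-allele patterns"
            )
    if (f < -1e-12).any() or f.sum() > 1.0 + 1e-12:
        raise ValueError("infeasible fixed-difference configuration")
    return np.clip(f, 0.0, 1.0)


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------


def beta_diversity(a: float, b: float) -> float:
    """E[2 p q] when the minor allele frequency is 0.5 * Beta(a, b)."""
    m1 = a / (a + b)
    m2 = a * (a + 1) / ((a + b) * (a + b + 1))
    return m1 - 0.5 * m2


def beta_params_for_diversity(hp: float, a: float = 1.2) -> tuple[float, float]:
    """Beta b parameter (given a) so that E[2pq] at polymorphic loci = hp."""
    if not 0 < hp < 0.5:
        raise ValueError("per-locus diversity target must be in (0, 0.5)")
    return a, float(brentq(lambda b: beta_diversity(a, b) - hp, 1e-3, 1e4))


def _he_correction(n_ind: int, n_sites: int, fst: float, fis: float) -> float:
    """E[unbiased-He estimator] / (2pq) under the generative model.

    Accounts for the reduction of pooled-sample diversity caused by
    among-site drift (factor 1 - F_ST/S) and for finite-sample gene
    correlation under inbreeding, combined with the estimator's own
    n/(n-1) and H_o/(2n) corrections.
    """
    N, S = float(n_ind), float(n_sites)
    bracket = (
        1.0
        - fst / S
        - (1.0 + fis) / (2 * N)
        - (1.0 - fst) * (1.0 - fis) / (2 * N)
    )
    return N / (N - 1.0) * bracket


def expected_group_he(
    hp: float, poly_fraction: float, n_ind: int, n_sites: int, fst: float, fis: float
) -> float:
    """Expected estimated group H_e given per-locus diversity hp."""
    return poly_fraction * hp * _he_correction(n_ind, n_sites, fst, fis)


def _expected_neis_d(
    d_xy: float,
    d_total: float,
    hp: float,
    corr_x: float,
    corr_y: float,
) -> float:
    """Expected plug-in Nei's D between two lineages under the model."""
    P = 1.0 - d_total
    jxy = (d_total - d_xy) + P * (1.0 - hp)
    jx = d_total + P * (1.0 - hp * corr_x)
    jy = d_total + P * (1.0 - hp * corr_y)
    if jxy <= 0:
        return float("inf")
    return -math.log(jxy / math.sqrt(jx * jy))


def _j_correction(n_ind: int, n_sites: int, fst: float, fis: float) -> float:
    """E[2 p_hat q_hat] / (2pq) for the plug-in homozygosity sums."""
    N, S = float(n_ind), float(n_sites)
    return 1.0 - fst / S - (1.0 + fis) / (2 * N)


def calibrate_lineage_pair(
    he_target: float,
    neis_d_target: float,
    n_ind: int,
    n_sites: int,
    site_fst: float,
    selfing_generations: float = float("inf"),
    beta_a: float = 1.2,
) -> dict:
    """Solve the two-lineage configuration hitting target H_e and Nei's D.

    Returns the fixed-difference fraction, the per-polymorphic-locus
    diversity, and the beta parameters of the minor-allele-frequency
    distribution, such that the expected values of the group-level
    unbiased H_e estimator and of the plug-in Nei's D equal the targets
    under the generative model (equal-sized lineages assumed).
    """
    fis = 1.0 if math.isinf(selfing_generations) else 1.0 - 0.5**selfing_generations
    kappa = _he_correction(n_ind, n_sites, site_fst, fis)
    c1 = _j_correction(n_ind, n_sites, site_fst, fis)

    def d_mismatch(d):
        hp = he_target / ((1.0 - d) * kappa)
        if hp >= 0.5:
            return 1e9  # infeasible diversity at this d; D already too large
        return _expected_neis_d(d, d, hp, c1, c1) - neis_d_target

    d = float(brentq(d_mismatch, 1e-6, 0.98))
    hp = he_target / ((1.0 - d) * kappa)
    a, b = beta_params_for_diversity(hp, a=beta_a)
    return {
        "fixed_diff_fraction": d,
        "per_locus_diversity": hp,
        "maf_beta": (a, b),
        "fis": fis,
    }


# ---------------------------------------------------------------------------
# site structure
# ---------------------------------------------------------------------------


def simulate_site_structure(
    lineage_freqs: np.ndarray, n_sites: int, target_fst: float, seed=None
) -> np.ndarray:
    """Per-site allele frequencies drifted around lineage frequencies.

    Draws follow the Balding-Nichols model: site frequency at a locus with
    lineage frequency p is Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target
    among-site F_ST, so E = p and Var = F p (1-p).  Loci fixed in the
    lineage (p in {0, 1}) stay fixed.  F = 0 copies the lineage vector.
    Returns an ``(n_sites, n_loci)`` array.
    """
    p = np.asarray(lineage_freqs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if not 0.0 <= target_fst < 1.0:
        raise ValueError("target_fst must be in [0, 1)")
    if n_sites < 2:
        raise ValueError("among-site structure undefined for fewer than 2 sites")
    if target_fst == 0.0:
        return np.tile(p, (n_sites, 1))
    rng = np.random.default_rng(seed)
    F = target_fst
    out = np.tile(p, (n_sites, 1))
    seg = (p > 0) & (p < 1)
    if seg.any():
        a = p[seg] * (1 - F) / F
        b = (1 - p[seg]) * (1 - F) / F
        out[:, seg] = rng.beta(a, b, size=(n_sites, int(seg.sum())))
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    truth_labels: pd.DataFrame  # id, lineage, hybrid_class, parents
    rad_sequences: dict  # rad_locus_id -> (allele0 seq, allele1 seq)
    locus_truth: pd.DataFrame  # rad_locus_id, pattern, n_snps, assay_suitable
    outlines: list | None
    traits: pd.DataFrame | None
    config: LineageConfig


def _draw_genotypes(p_site: np.ndarray, n_ind: int, fis: float, rng) -> np.ndarray:
    """Genotypes for one site under inbreeding coefficient ``fis``."""
    p = p_site[None, :]
    q = 1 - p
    p_het = 2 * p * q * (1 - fis)
    p_alt2 = p**2 + fis * p * q
    u = rng.random((n_ind, p_site.size))
    calls = np.full((n_ind, p_site.size), 0, dtype=np.int8)
    calls[u < p_alt2] = 2
    both = (u >= p_alt2) & (u < p_alt2 + p_het)
    calls[both] = 1
    return calls


def _random_sequences(rad_ids, offsets_by_rad, rng) -> dict:
    """93-bp allele sequences differing exactly at the recorded offsets."""
    seqs = {}
    for rad in rad_ids:
        base = rng.integers(0, 4, size=RAD_LOCUS_LENGTH)
        ref_seq = BASES[base].copy()
        alt_seq = ref_seq.copy()
        for off in offsets_by_rad[rad]:  # 1-based
            alt = (base[off - 1] + rng.integers(1, 4)) % 4
            alt_seq[off - 1] = BASES[alt]
        seqs[rad] = ("".join(ref_seq), "".join(alt_seq))
    return seqs


def simulate_lineage_dataset(
    config: LineageConfig,
    include_phenotypes: bool = False,
    shape_params: dict | None = None,
    trait_params: pd.DataFrame | None = None,
) -> SyntheticDataset:
    """Generate a full labelled dataset from the two-level lineage model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, L = config.n_lineages, config.loci
    labels = config.lineage_labels()
    fis = config.fis

    # --- allocate loci to fixed-difference patterns --------------------
    f = solve_pattern_fractions(config.pairwise_fixed_fractions())
    counts = np.round(f * L).astype(int)
    pattern = np.full(L, -1, dtype=int)  # -1 = shared polymorphic
    perm = rng.permutation(L)
    start = 0
    for i, c in enumerate(counts):
        pattern[perm[start : start + c]] = i
        start += c

    # --- ancestral lineage frequencies ---------------------------------
    anc = np.zeros((K, L))
    for i in range(K):
        anc[i, pattern == i] = 1.0
    poly = pattern == -1
    if config.within_group_maf_dist is not None and poly.any():
        a, b = config.within_group_maf_dist
        maf = 0.5 * rng.beta(a, b, size=int(poly.sum()))
        flip = rng.random(int(poly.sum())) < 0.5
        p_poly = np.where(flip, 1.0 - maf, maf)
        anc[:, poly] = p_poly[None, :]

    # --- individuals ----------------------------------------------------
    call_blocks, ind_rows = [], []
    lineage_rows: dict = {}
    row = 0
    for k, lab in enumerate(labels):
        plan = config.site_plan[lab]
        sites = list(plan)
        if len(sites) >= 2 and config.site_drift_fst > 0:
            site_freqs = simulate_site_structure(
                anc[k], len(sites), config.site_drift_fst, seed=rng.integers(2**31)
            )
        else:
            site_freqs = np.tile(anc[k], (len(sites), 1))
        for s, site in enumerate(sites):
            n = int(plan[site])
            calls = _draw_genotypes(site_freqs[s], n, fis, rng)
            call_blocks.append(calls)
            for j in range(n):
                ind_rows.append(
                    {"id": f"{lab}_{site}_{j:03d}", "site": site, "group": lab}
                )
                lineage_rows.setdefault(lab, []).append(row)
                row += 1
    calls = np.vstack(call_blocks) if call_blocks else np.zeros((0, L), np.int8)

    truth = [
        {"id": r["id"], "lineage": r["group"], "hybrid_class": "pure", "parents": ""}
        for r in ind_rows
    ]

    # --- hybrids --------------------------------------------------------
    for entry in config.hybrid_spec:
        linA, linB, kind, count = entry
        if kind not in ("F1", "F2", "F3", "BC"):
            raise ValueError(f"unknown hybrid kind {kind!r}")
        for c in range(count):
            pa = calls[rng.choice(lineage_rows[linA])]
            pb = calls[rng.choice(lineage_rows[linB])]
            child = cross(pa, pb, seed=rng.integers(2**31))
            if kind == "BC":
                child = cross(child, calls[rng.choice(lineage_rows[linB])],
                              seed=rng.integers(2**31))
            elif kind in ("F2", "F3"):
                child = self_(child, seed=rng.integers(2**31))
                if kind == "F3":
                    child = self_(child, seed=rng.integers(2**31))
            hid = f"HYB_{kind}_{linA}x{linB}_{c:02d}"
            site = ind_rows[lineage_rows[linA][0]]["site"]
            calls = np.vstack([calls, child[None, :]])
            ind_rows.append({"id": hid, "site": site, "group": "hybrid"})
            truth.append(
                {
                    "id": hid,
                    "lineage": "hybrid",
                    "hybrid_class": kind,
                    "parents": f"{linA}x{linB}",
                }
            )

    # --- missing data ---------------------------------------------------
    n_total = calls.shape[0]
    if config.missing_rate_individual > 0:
        mask = rng.random(calls.shape) < config.missing_rate_individual
        calls = np.where(mask, MISSING, calls).astype(np.int8)
    if config.missing_rate_locus > 0:
        mask = rng.random(calls.shape) < config.missing_rate_locus
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    # --- locus metadata and sequences -----------------------------------
    rad_ids = [f"RAD{j:06d}" for j in range(L)]
    primary_off = rng.integers(1, RAD_LOCUS_LENGTH + 1, size=L)
    offsets_by_rad = {rad: [int(primary_off[j])] for j, rad in enumerate(rad_ids)}
    loci_rows = [
        {
            "rad_locus_id": rad_ids[j],
            "snp_offset": int(primary_off[j]),
            "ref": "A",
            "alt": "T",
        }
        for j in range(L)
    ]
    multi = rng.random(L) < config.multi_snp_fraction
    extra_cols = []
    for j in np.flatnonzero(multi):
        off = int(primary_off[j])
        choices = [o for o in range(1, RAD_LOCUS_LENGTH + 1) if o != off]
        second = int(rng.choice(choices))
        offsets_by_rad[rad_ids[j]].append(second)
        loci_rows.append(
            {
                "rad_locus_id": rad_ids[j],
                "snp_offset": second,
                "ref": "A",
                "alt": "T",
            }
        )
        extra_cols.append(j)
    if extra_cols:
        # second SNPs are in complete linkage with the primary SNP
        calls = np.hstack([calls, calls[:, extra_cols]])
    loci = pd.DataFrame(loci_rows)
    seqs = _random_sequences(rad_ids, offsets_by_rad, rng)
    # set ref/alt bases from the sequences
    ref_bases, alt_bases = [], []
    for r in loci.itertuples():
        s0, s1 = seqs[r.rad_locus_id]
        ref_bases.append(s0[r.snp_offset - 1])
        alt_bases.append(s1[r.snp_offset - 1])
    loci["ref"] = ref_bases
    loci["alt"] = alt_bases

    flank_ok = (primary_off - 1 >= 18) & (RAD_LOCUS_LENGTH - primary_off >= 18)
    locus_truth = pd.DataFrame(
        {
            "rad_locus_id": rad_ids,
            "pattern": [
                labels[pattern[j]] if pattern[j] >= 0 else "poly" for j in range(L)
            ],
            "n_snps": [len(offsets_by_rad[r]) for r in rad_ids],
            "assay_suitable": (~multi) & flank_ok,
        }
    )

    genotypes = GenotypeMatrix(
        calls=calls,
        individuals=pd.DataFrame(ind_rows),
        loci=loci,
    )
    truth_df = pd.DataFrame(truth)

    outlines = traits = None
    if include_phenotypes:
        if trait_params is None:
            trait_params = TABLE_TRAITS
        n_per_group = {lab: sum(config.site_plan[lab].values()) for lab in labels}
        traits = simulate_trait_table(
            trait_params, n_per_group, seed=int(rng.integers(2**31)),
            group_order=labels,
        )
        if shape_params is None:
            shape_params = {}
            for gi, lab in enumerate(labels):
                mcol = f"mean_{gi + 1}"
                ar = (
                    float(trait_params.loc["lat_dim", mcol])
                    if mcol in trait_params.columns
                    else 1.3
                )
                shape_params[lab] = LeafShapeParams(
                    ar_mean=ar, ar_sd=0.08, n=n_per_group[lab]
                )
        outlines = simulate_leaf_outlines(
            shape_params, n_points=256, seed=int(rng.integers(2**31))
        )

    return SyntheticDataset(
        genotypes=genotypes,
        truth_labels=truth_df,
        rad_sequences=seqs,
        locus_truth=locus_truth,
        outlines=outlines,
        traits=traits,
        config=config,
    )


# ---------------------------------------------------------------------------
# leaf outlines and traits
# ---------------------------------------------------------------------------


@dataclass
class LeafShapeParams:
    """Per-group leaf outline parameters (length:width aspect ratio)."""

    ar_mean: float
    ar_sd: float
    n: int
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.ar_mean <= 0 or self.ar_sd < 0 or self.n < 0:
            raise ValueError("degenerate leaf shape parameters")


def _noisy_closed_outline(
    aspect: float, n_points: int, noise_sd: float, rng
) -> np.ndarray:
    """Closed, star-shaped (hence non-self-intersecting) leaflet outline.

    A unit circle is perturbed by a smooth low-order random radial field,
    stretched, then rescaled so the bounding-box length:width ratio equals
    ``aspect`` exactly.
    """
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    r = np.ones(n_points)
    for k in range(2, 6):
        amp = rng.normal(0.0, noise_sd / k)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.2, None)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    width = y.max() - y.min()
    length = x.max() - x.min()
    x = x * (aspect * width / length)
    return np.column_stack([x, y])


def simulate_leaf_outlines(
    group_shape_params: dict, n_points: int = 256, seed=None
) -> list:
    """Labelled closed outlines drawn from per-group aspect-ratio models.

    Returns a list of ``(label, outline)`` pairs where each outline is an
    ``(n_points, 2)`` array tracing a closed contour.
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    rng = np.random.default_rng(seed)
    out = []
    for label, params in group_shape_params.items():
        for _ in range(params.n):
            ar = rng.normal(params.ar_mean, params.ar_sd)
            ar = max(ar, 0.2)
            out.append((label, _noisy_closed_outline(ar, n_points, params.noise_sd, rng)))
    return out


#: Default per-group trait parameterization: means (SE) for three lineage
#: groups of a selfing annual legume; length:width ratios of terminal and
#: lateral leaflets, terminal:lateral petiolule length ratio, and hair
#: count per 9 mm^2.  SEs are converted to SDs with assumed group sizes
#: (25, 26, 25).
TABLE_TRAITS = pd.DataFrame(
    {
        "trait": ["term_dim", "lat_dim", "pet_dim", "hairs"],
        "mean_1": [1.67, 1.61, 3.83, 47.5],
        "se_1": [0.03, 0.02, 0.07, 3.3],
        "mean_2": [1.23, 1.38, 5.66, 84.5],
        "se_2": [0.01, 0.01, 0.13, 4.4],
        "mean_3": [1.15, 1.26, 4.66, 56.9],
        "se_3": [0.01, 0.01, 0.09, 2.3],
    }
).set_index("trait")

TABLE_TRAIT_GROUP_N = (25, 26, 25)


def simulate_trait_table(
    group_trait_params: pd.DataFrame,
    n_per_group: dict,
    seed=None,
    hair_model: str = "truncnorm",
    group_order: list | None = None,
    se_group_n: tuple = TABLE_TRAIT_GROUP_N,
) -> pd.DataFrame:
    """Draw a per-individual trait table from group means and SEs.

    ``group_trait_params`` has one row per trait and columns ``mean_k`` /
    ``se_k`` for the k-th group (printed standard errors; SD = SE*sqrt(n)
    with the assumed group sizes ``se_group_n``).  Ratio traits are normal
    draws; hair counts are truncated at zero by default (``hair_model=
    'truncnorm'``) or Poisson with the group mean (``'poisson'``).
    """
    rng = np.random.default_rng(seed)
    groups = group_order if group_order is not None else list(n_per_group)
    rows = []
    for gi, g in enumerate(groups):
        n = int(n_per_group[g])
        mcol, scol = f"mean_{gi + 1}", f"se_{gi + 1}"
        for j in range(n):
            rec = {"id": f"{g}_{j:03d}", "lineage": g}
            for trait in group_trait_params.index:
                mu = float(group_trait_params.loc[trait, mcol])
                sd = float(group_trait_params.loc[trait, scol]) * math.sqrt(
                    se_group_n[min(gi, len(se_group_n) - 1)]
                )
                if trait == "hairs":
                    if hair_model == "poisson":
                        val = float(rng.poisson(mu))
                    else:
                        val = max(0.0, float(rng.normal(mu, sd)))
                else:
                    val = max(1e-3, float(rng.normal(mu, sd)))
                rec[trait] = val
            rows.append(rec)
    return pd.DataFrame(rows)
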