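import numpy as np
import pandas as pd
import pytest

from selflines import popgen
from selflines.synthetic import (
    TABLE_TRAITS,
    LeafShapeParams,
    LineageConfig,
    beta_diversity,
    beta_params_for_diversity,
    calibrate_lineage_pair,
    expected_group_he,
    simulate_leaf_outlines,
    simulate_lineage_dataset,
    simulate_site_structure,
    simulate_trait_table,
    solve_pattern_fractions,
)


def two_lineage_config(**kw):
    base = dict(
        n_lineages=2,
        loci=500,
        site_plan={"A": {"s1": 15, "s2": 15}, "B": {"s1": 15, "s2": 15}},
        fixed_diff_fraction=0.3,
        within_group_maf_dist=None,
        selfing_generations=float("inf"),
        seed=5,
    )
    base.update(kw)
    return LineageConfig(**base)


class TestPatternSolver:
    def test_three_lineage_star_solution(self):
        # d_12 = 0.5, d_13 = 0.5, d_23 = 0.2 -> f = (0.4, 0.1, 0.1)
        D = np.array([[0, 0.5, 0.5], [0.5, 0, 0.2], [0.5, 0.2, 0]])
        f = solve_pattern_fractions(D)
        np.testing.assert_allclose(f, [0.4, 0.1, 0.1], atol=1e-12)

    def test_infeasible_rejected(self):
        # triangle inequality violated: d_23 > d_12 + d_13
        D = np.array([[0, 0.1, 0.1], [0.1, 0, 0.9], [0.1, 0.9, 0]])
        with pytest.raises(ValueError):
            solve_pattern_fractions(D)

    def test_oversubscribed_rejected(self):
        D = np.array([[0, 0.9], [0.9, 0]])
        cfg = two_lineage_config(fixed_diff_fraction=1.2)
        with pytest.raises(ValueError):
            cfg.validate()


class TestGenotypeGeneration:
    def test_complete_selfing_forces_homozygosity(self):
        ds = simulate_lineage_dataset(
            two_lineage_config(within_group_maf_dist=(1.2, 10.0))
        )
        assert (ds.genotypes.calls != 1).all()
        summary = popgen.group_summary(
            ds.genotypes, ds.genotypes.individuals["group"]
        )
        assert (summary["Ho"] == 0).all()

    def test_injected_f1_heterozygosity_equals_fixed_fraction(self):
        cfg = two_lineage_config(hybrid_spec=[("A", "B", "F1", 1)])
        ds = simulate_lineage_dataset(cfg)
        f1_row = ds.truth_labels["hybrid_class"] == "F1"
        idx = np.flatnonzero(f1_row.to_numpy())
        het = (ds.genotypes.calls[idx[0]] == 1).mean()
        assert het == pytest.approx(0.3, abs=1e-12)
        # counting hybrid index of an F1 between fully inbred lineages = 0.5
        from selflines.hybrids import hybrid_index

        groups = ds.genotypes.individuals["group"].to_numpy()
        fA = ds.genotypes.allele_frequencies(np.flatnonzero(groups == "A"))
        fB = ds.genotypes.allele_frequencies(np.flatnonzero(groups == "B"))
        est = hybrid_index(ds.genotypes.calls[idx[0]], fA, fB)
        assert est.h_counting == pytest.approx(0.5, abs=1e-12)

    def test_realized_he_within_3se_of_analytic_target(self):
        he_target = 0.065
        cal = calibrate_lineage_pair(
            he_target, 0.22, n_ind=30, n_sites=2, site_fst=0.0,
        )
        cfg = two_lineage_config(
            loci=10000,
            fixed_diff_fraction=cal["fixed_diff_fraction"],
            within_group_maf_dist=cal["maf_beta"],
            site_drift_fst=0.0,
            seed=21,
        )
        ds = simulate_lineage_dataset(cfg)
        groups = ds.genotypes.individuals["group"].to_numpy()
        summary = popgen.group_summary(ds.genotypes, groups).set_index("group")
        # bootstrap-over-loci standard error of the mean-over-loci He
        rng = np.random.default_rng(0)
        idxA = np.flatnonzero(groups == "A")
        calls = ds.genotypes.calls[idxA]
        n = calls.shape[0]
        p = calls.mean(axis=0) / 2
        ho = (calls == 1).mean(axis=0)
        he_l = n / (n - 1) * (1 - (p**2 + (1 - p) ** 2) - ho / (2 * n))
        boots = [
            he_l[rng.integers(0, len(he_l), len(he_l))].mean() for _ in range(200)
        ]
        se = np.std(boots, ddof=1)
        assert abs(summary.loc["A", "He"] - he_target) < 3 * se

    def test_deterministic_under_seed(self):
        a = simulate_lineage_dataset(two_lineage_config(seed=9))
        b = simulate_lineage_dataset(two_lineage_config(seed=9))
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
        assert a.rad_sequences == b.rad_sequences

    def test_every_individual_has_truth_label(self):
        cfg = two_lineage_config(hybrid_spec=[("A", "B", "F2", 2)])
        ds = simulate_lineage_dataset(cfg)
        assert set(ds.truth_labels["id"]) == set(ds.genotypes.individuals["id"])

    def test_sequences_differ_exactly_at_recorded_offsets(self):
        cfg = two_lineage_config(multi_snp_fraction=0.4, seed=3)
        ds = simulate_lineage_dataset(cfg)
        loci = ds.genotypes.loci
        for rad, (s0, s1) in ds.rad_sequences.items():
            recorded = set(
                loci.loc[loci["rad_locus_id"] == rad, "snp_offset"].astype(int)
            )
            observed = {
                i + 1 for i, (a, b) in enumerate(zip(s0, s1)) if a != b
            }
            assert observed == recorded


class TestSiteStructure:
    def test_zero_fst_copies_lineage_vector(self):
        p = np.array([0.1, 0.5, 0.9])
        out = simulate_site_structure(p, 4, 0.0, seed=1)
        assert (out == p).all()

    def test_target_fst_recovered(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.9, size=5000)
        sites = simulate_site_structure(p, 7, 0.10, seed=8)
        # draw fully inbred individuals at each site and estimate theta
        from conftest import make_matrix

        n_per_site = 12
        calls = []
        labels = []
        for s in range(7):
            hom = (rng.random((n_per_site, 5000)) < sites[s]).astype(np.int8) * 2
            calls.append(hom)
            labels += [f"site{s}"] * n_per_site
        m = make_matrix(np.vstack(calls))
        theta = popgen.wc_fst(m, np.array(labels), mode="multilocus")
        assert abs(theta - 0.10) < 0.02

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            simulate_site_structure(np.array([0.5]), 1, 0.1)

    def test_bad_fst_rejected(self):
        with pytest.raises(ValueError):
            simulate_site_structure(np.array([0.5]), 3, 1.0)


class TestCalibration:
    def test_beta_diversity_solver_roundtrip(self):
        a, b = beta_params_for_diversity(0.08)
        assert beta_diversity(a, b) == pytest.approx(0.08, rel=1e-9)

    def test_calibration_reproduces_expected_he(self):
        cal = calibrate_lineage_pair(0.065, 0.22, n_ind=60, n_sites=7, site_fst=0.1)
        he = expected_group_he(
            cal["per_locus_diversity"],
            1 - cal["fixed_diff_fraction"],
            n_ind=60,
            n_sites=7,
            fst=0.1,
            fis=1.0,
        )
        assert he == pytest.approx(0.065, rel=1e-9)


class TestLeafOutlines:
    def test_circle_aspect_ratio(self):
        out = simulate_leaf_outlines(
            {"g": LeafShapeParams(ar_mean=1.0, ar_sd=0.0, n=3, noise_sd=0.0)},
            n_points=256,
            seed=1,
        )
        for _, pts in out:
            ext = pts.max(axis=0) - pts.min(axis=0)
            assert ext[0] / ext[1] == pytest.approx(1.0, abs=1 / 256)

    def test_group_mean_ratios_match_inputs(self):
        params = {
            "G1": LeafShapeParams(1.67, 0.15, 40),
            "G2": LeafShapeParams(1.23, 0.05, 40),
            "G3": LeafShapeParams(1.15, 0.05, 40),
        }
        out = simulate_leaf_outlines(params, n_points=128, seed=2)
        df = {}
        for label, pts in out:
            ext = pts.max(axis=0) - pts.min(axis=0)
            df.setdefault(label, []).append(ext[0] / ext[1])
        for g, p in params.items():
            ratios = np.array(df[g])
            se = ratios.std(ddof=1) / np.sqrt(len(ratios))
            assert abs(ratios.mean() - p.ar_mean) < 2 * se + 0.02

    def test_zero_noise_ellipse_first_harmonic_ratio(self):
        # The first-harmonic semi-axis ratio of an arc-length EFA of an
        # ellipse is compared against a direct Fourier-integral oracle
        # (it is close to, but not identical with, the bounding-box ratio).
        from oracles import arc_length_fourier_first_harmonic
        from selflines.morpho import elliptic_fourier, normalize_efa

        out = simulate_leaf_outlines(
            {"g": LeafShapeParams(2.0, 0.0, 1, noise_sd=0.0)}, n_points=512, seed=3
        )
        _, pts = out[0]
        efa = normalize_efa(elliptic_fourier(pts, 8), scale=False)
        a1, _, _, d1 = efa.coeffs[0]
        oa1, od1 = arc_length_fourier_first_harmonic(pts)
        # the two quadratures differ at O(1/n_points^2)
        assert a1 / abs(d1) == pytest.approx(oa1 / od1, rel=1e-4)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            LeafShapeParams(0.0, 0.1, 5)
        with pytest.raises(ValueError):
            simulate_leaf_outlines(
                {"g": LeafShapeParams(1.0, 0.0, 1)}, n_points=8, seed=1
            )


class TestTraitTable:
    def test_zero_variance_equals_group_means(self):
        params = TABLE_TRAITS.copy()
        for c in params.columns:
            if c.startswith("se_"):
                params[c] = 0.0
        tt = simulate_trait_table(params, {"G1": 5, "G2": 5, "G3": 5}, seed=1)
        for gi, g in enumerate(("G1", "G2", "G3")):
            sub = tt[tt["lineage"] == g]
            for trait in TABLE_TRAITS.index:
                assert sub[trait].to_numpy() == pytest.approx(
                    TABLE_TRAITS.loc[trait, f"mean_{gi+1}"]
                ), trait

    def test_sample_means_near_inputs_large_n(self):
        tt = simulate_trait_table(
            TABLE_TRAITS, {"G1": 400, "G2": 400, "G3": 400}, seed=2
        )
        for gi, g in enumerate(("G1", "G2", "G3")):
            sub = tt[tt["lineage"] == g]
            for trait in TABLE_TRAITS.index:
                mu = TABLE_TRAITS.loc[trait, f"mean_{gi+1}"]
                se = sub[trait].std(ddof=1) / np.sqrt(len(sub))
                assert abs(sub[trait].mean() - mu) < 3 * se + 1e-9, (g, trait)

    def test_hairs_nonnegative_poisson_mode(self):
        tt = simulate_trait_table(
            TABLE_TRAITS, {"G1": 50, "G2": 50, "G3": 50}, seed=3, hair_model="poisson"
        )
        assert (tt["hairs"] >= 0).all()

    def test_perfect_separation_gives_full_loocv_success(self):
        from selflines.morpho import lda_loocv

        params = TABLE_TRAITS.copy()
        # means 5 SD apart: blow up the separation by shrinking SEs
        for c in params.columns:
            if c.startswith("se_"):
                params[c] = params[c] / 50
        tt = simulate_trait_table(params, {"G1": 15, "G2": 15, "G3": 15}, seed=4)
        rep = lda_loocv(tt[["term_dim", "lat_dim", "pet_dim", "hairs"]], tt["lineage"])
        assert rep.success_rate == 100.0
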