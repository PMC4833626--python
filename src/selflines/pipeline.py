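"""Pipeline orchestration: qc -> popgen -> pca -> hybrids -> scan -> panel
-> morphometrics, with artifacts passed between stages and all randomness
derived from a single root seed.

The pipeline consumes either a synthetic-generator configuration or paths
to genotype/grouping (and optionally outline/trait) files, executes the
enabled stages in fixed order, writes per-stage TSV/JSON outputs into the
output directory, and returns a run report.  Outputs embed the seed and a
hash of the configuration so that runs are attributable; a fixed seed
reproduces numerically identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import assay, hybrids, io, morpho, popgen, qc, scan
from .synthetic import LineageConfig, SyntheticDataset, simulate_lineage_dataset

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

STAGE_ORDER = ("qc", "popgen", "pca", "hybrids", "scan", "panel", "morpho")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    # inputs: either a generator config or file paths
    synthetic: LineageConfig | None = None
    genotypes_path: str | None = None
    genotypes_format: str | None = None
    grouping_path: str | None = None
    stages: tuple = STAGE_ORDER
    # stage parameters
    max_missing_individual: float = 0.25
    max_missing_locus: float = 0.10
    n_sim: int = 1000
    fst_threshold: float = 0.9
    alpha: float = 0.05
    n_harmonics: int = 20
    panel_size: int = 4
    max_clusters: int = 6

    def validate(self, require_inputs: bool = True) -> None:
        if require_inputs and self.synthetic is None and self.genotypes_path is None:
            raise ValueError("need either a synthetic config or a genotypes path")
        if self.genotypes_path is not None and not Path(self.genotypes_path).exists():
            raise ValueError(f"missing input: {self.genotypes_path}")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        skip = {"synthetic", "outdir"}  # hash covers analysis parameters only
        payload = {k: v for k, v in self.__dict__.items() if k not in skip}
        if self.synthetic is not None:
            payload["synthetic"] = {
                k: (v if np.isscalar(v) or isinstance(v, (dict, list, tuple)) else str(v))
                for k, v in self.synthetic.__dict__.items()
            }
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    seed: int
    config_hash: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _detect_clusters(scores: np.ndarray, max_k: int, seed: int):
    """Choose a cluster count on the leading PC axes by silhouette."""
    X = scores[:, :3] if scores.shape[1] >= 3 else scores
    best = None
    for k in range(2, min(max_k, len(X) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if best is None or s > best[0]:
            best = (s, k, labels)
    if best is None:
        raise ValueError("could not cluster PCA scores")
    return best[1], best[2], best[0]


def run_pipeline(config: PipelineConfig, dataset: SyntheticDataset | None = None) -> RunReport:
    """Execute the enabled stages in fixed order; see module docstring."""
    config.validate(require_inputs=dataset is None)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report = RunReport(seed=config.seed, config_hash=chash)
    rng_root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGE_ORDER, rng_root.spawn(len(STAGE_ORDER)))
    }
    tag = f"seed{config.seed}_{chash}"

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            report.stages[name] = fn()
        except Exception as err:
            report.stages[name] = {"error": str(err)}
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    # --- inputs ---------------------------------------------------------
    if dataset is None and config.synthetic is not None:
        dataset = simulate_lineage_dataset(
            config.synthetic, include_phenotypes="morpho" in config.stages
        )
    if dataset is not None:
        matrix = dataset.genotypes
    else:
        meta = (
            io.read_grouping(config.grouping_path)
            if config.grouping_path
            else None
        )
        matrix = io.read_genotypes(
            config.genotypes_path, config.genotypes_format,
            **({"individuals_meta": meta} if meta is not None else {}),
        )

    state: dict = {"matrix": matrix}

    # --- qc -------------------------------------------------------------
    def stage_qc():
        filtered, reports = qc.standard_qc(
            state["matrix"],
            config.max_missing_individual,
            config.max_missing_locus,
        )
        state["matrix"] = filtered
        io.write_qc_report(reports, outdir / f"qc_report_{tag}.json", seed=config.seed)
        io.write_genotypes_tsv(
            filtered, outdir / f"genotypes_filtered_{tag}.tsv", seed=config.seed
        )
        return {
            "n_individuals": filtered.n_individuals,
            "n_loci": filtered.n_loci,
            "removed": {r.step: len(r.removed) for r in reports},
        }

    run_stage("qc", stage_qc)
    matrix = state["matrix"]
    has_groups = (
        "group" in matrix.individuals.columns
        and matrix.individuals["group"].notna().all()
    )
    grouping = matrix.individuals["group"].to_numpy() if has_groups else None
    pure_mask = (
        np.array([g != "hybrid" for g in grouping])
        if grouping is not None
        else np.ones(matrix.n_individuals, bool)
    )

    # --- pca (also used for lineage discovery) ---------------------------
    def stage_pca():
        pca = popgen.genotype_pca(matrix, n_components=10)
        k, labels, sil = _detect_clusters(
            pca.scores, config.max_clusters, stage_seeds["pca"]
        )
        state["pca"] = pca
        state["clusters"] = labels
        pd.DataFrame(
            {
                "id": matrix.individuals["id"],
                "cluster": labels,
                **{f"PC{i+1}": pca.scores[:, i] for i in range(min(4, pca.scores.shape[1]))},
            }
        ).to_csv(outdir / f"pca_scores_{tag}.tsv", sep="\t", index=False)
        return {
            "n_clusters": int(k),
            "silhouette": float(sil),
            "variance_fraction_pc1_pc2": [
                float(v) for v in pca.variance_fraction[:2]
            ],
        }

    run_stage("pca", stage_pca)

    if grouping is None and "clusters" in state:
        grouping = np.array([f"cluster{c}" for c in state["clusters"]])
        pure_mask = np.ones(matrix.n_individuals, bool)

    # --- popgen -----------------------------------------------------------
    def stage_popgen():
        sub = matrix.subset(individual_idx=np.flatnonzero(pure_mask))
        summary = popgen.group_summary(sub, sub.individuals["group"].to_numpy()
                                       if has_groups else grouping[pure_mask])
        summary.to_csv(outdir / f"group_summary_{tag}.tsv", sep="\t", index=False)
        groups = list(summary["group"])
        div = {}
        per_locus = {}
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                d = popgen.pairwise_divergence(
                    sub, sub.individuals["group"].to_numpy() if has_groups
                    else grouping[pure_mask], a, b
                )
                div[f"{a}|{b}"] = {
                    "neis_D": d.neis_D,
                    "fst_multilocus": d.fst_multilocus,
                }
                per_locus[f"{a}|{b}"] = d.per_locus_fst
        state["per_locus_fst"] = per_locus
        state["groups"] = groups
        pd.DataFrame({"locus": matrix.loci["rad_locus_id"], **per_locus}).to_csv(
            outdir / f"per_locus_fst_{tag}.tsv", sep="\t", index=False
        )
        return {"groups": {str(r["group"]): r["n"] for _, r in summary.iterrows()},
                "divergence": div}

    run_stage("popgen", stage_popgen)

    # --- hybrids ----------------------------------------------------------
    def stage_hybrids():
        if "pca" not in state:
            raise ValueError("hybrid stage needs the pca stage")
        flags = popgen.flag_pca_intermediates(
            state["pca"].scores, np.where(pure_mask, grouping, "hybrid")
        )
        candidates = np.flatnonzero(flags | ~pure_mask)
        calls_by_group = {
            g: matrix.calls[(grouping == g) & pure_mask]
            for g in pd.unique(grouping[pure_mask])
        }
        out = {}
        sims = {}
        for i in candidates:
            # classify against the two nearest group centroids in PC space
            X = state["pca"].scores[:, :2]
            cents = {
                g: X[(grouping == g) & pure_mask].mean(axis=0)
                for g in calls_by_group
            }
            nearest = sorted(cents, key=lambda g: np.linalg.norm(X[i] - cents[g]))[:2]
            pair = tuple(sorted(map(str, nearest)))
            if pair not in sims:
                sims[pair] = hybrids.simulate_hybrid_generations(
                    calls_by_group[nearest[0]],
                    calls_by_group[nearest[1]],
                    n_sim=config.n_sim,
                    seed=stage_seeds["hybrids"],
                    parent_ids=pair,
                )
            sim = sims[pair]
            freqA = matrix.allele_frequencies(
                np.flatnonzero((grouping == nearest[0]) & pure_mask)
            )
            freqB = matrix.allele_frequencies(
                np.flatnonzero((grouping == nearest[1]) & pure_mask)
            )
            est = hybrids.hybrid_index(matrix.calls[i], freqA, freqB)
            het = hybrids.observed_heterozygosity(matrix.calls[i])
            call = hybrids.classify_hybrid(
                (het, est.h), sim, alpha=config.alpha,
                individual_id=matrix.individuals.loc[i, "id"],
            )
            out[str(call.individual_id)] = {
                "parents": pair,
                "het": call.het,
                "h": call.h,
                "h_interval": est.interval,
                "label": call.label,
            }
        (outdir / f"hybrid_calls_{tag}.json").write_text(
            json.dumps(out, indent=2, default=str)
        )
        return {"n_candidates": len(candidates), "calls": out}

    run_stage("hybrids", stage_hybrids)

    # --- divergence scan --------------------------------------------------
    def stage_scan():
        if "per_locus_fst" not in state:
            raise ValueError("scan stage needs the popgen stage")
        out = {}
        for name, v in state["per_locus_fst"].items():
            hist = scan.fst_distribution(v, bins=20, threshold=config.fst_threshold)
            out[name] = {
                "n_above_threshold": hist.n_above_threshold,
                "u_shape_index": scan.u_shape_index(hist.counts, hist.edges),
                "n_negative": hist.n_negative,
            }
        names = list(state["per_locus_fst"])
        overlaps = {}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                _, n = scan.shared_outliers(
                    state["per_locus_fst"][a],
                    state["per_locus_fst"][b],
                    threshold=config.fst_threshold,
                )
                overlaps[f"{a} & {b}"] = n
        return {"comparisons": out, "outlier_overlaps": overlaps}

    run_stage("scan", stage_scan)

    # --- diagnostic panel -------------------------------------------------
    def stage_panel():
        if dataset is None or dataset.rad_sequences is None:
            return {"skipped": "no RAD sequences available"}
        sub_idx = np.flatnonzero(pure_mask)
        sub = matrix.subset(individual_idx=sub_idx)
        sub_groups = grouping[sub_idx]
        groups = list(pd.unique(sub_groups))
        panels = []
        info = {}
        for g in groups:
            partition = ([g], [x for x in groups if x != g])
            cands = assay.find_diagnostic_loci(sub, sub_groups, partition)
            suitable = assay.filter_assay_suitable(cands, dataset.rad_sequences)
            if len(suitable) == 0:
                continue
            panel = assay.build_panel(partition, suitable, config.panel_size)
            panels.append(panel)
            info[str(g)] = {
                "n_candidates": len(cands),
                "n_suitable": len(suitable),
                "panel": [l.rad_locus_id for l in panel.loci],
            }
        state["panels"] = panels
        return info

    run_stage("panel", stage_panel)

    # --- morphometrics ----------------------------------------------------
    def stage_morpho():
        if dataset is None or dataset.traits is None or dataset.outlines is None:
            return {"skipped": "no phenotype data available"}
        traits = dataset.traits
        labels = traits["lineage"].to_numpy()
        anova = morpho.trait_anova(traits, labels)
        anova.to_csv(outdir / f"trait_anova_{tag}.tsv", sep="\t")
        efas = [
            morpho.normalize_efa(
                morpho.elliptic_fourier(pts, n_harmonics=config.n_harmonics)
            )
            for _, pts in dataset.outlines
        ]
        scores, var_frac = morpho.efa_pca(efas)
        feats = traits[["term_dim", "lat_dim", "pet_dim", "hairs"]].copy()
        if len(scores) == len(traits):
            feats["lat_PC1"] = scores[:, 0]
        lda = morpho.lda_loocv(feats, labels)
        lda.confusion.to_csv(outdir / f"lda_confusion_{tag}.tsv", sep="\t")
        return {
            "anova_p": {t: float(anova.loc[t, "p"]) for t in anova.index},
            "lda_success_rate": lda.success_rate,
            "shape_pc_variance": [float(v) for v in var_frac],
        }

    run_stage("morpho", stage_morpho)

    (outdir / f"run_report_{tag}.json").write_text(report.to_json())
    return report
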