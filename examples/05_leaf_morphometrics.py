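"""Discriminate lineages from leaf shape and measured traits.

Simulates leaflet outlines and a trait table from per-lineage parameters
(leaflet length:width ratios, petiolule ratio, hair density), decomposes
outlines by elliptic Fourier analysis, tests trait differences by one-way
ANOVA with Tukey letters, and predicts lineage by LDA with leave-one-out
cross-validation.
"""

from selflines import morpho
from selflines.synthetic import (
    TABLE_TRAITS,
    LeafShapeParams,
    simulate_leaf_outlines,
    simulate_trait_table,
)

n_per_group = {"G1": 25, "G2": 26, "G3": 25}
traits = simulate_trait_table(TABLE_TRAITS, n_per_group, seed=5)
shapes = {
    g: LeafShapeParams(
        ar_mean=float(TABLE_TRAITS.loc["lat_dim", f"mean_{i+1}"]),
        ar_sd=0.08,
        n=n_per_group[g],
    )
    for i, g in enumerate(n_per_group)
}
outlines = simulate_leaf_outlines(shapes, n_points=256, seed=6)

anova = morpho.trait_anova(traits, traits["lineage"])
print("trait     MS        F        p       Tukey letters (G1, G2, G3)")
for t in anova.index:
    r = anova.loc[t]
    print(
        f"{t:9s} {r['MS']:<9.3f} {r['F']:<8.1f} {r['p']:.2e}  "
        f"{r['letter_G1']}, {r['letter_G2']}, {r['letter_G3']}"
    )
print("-> groups sharing a letter are not significantly different\n")

efas = [
    morpho.normalize_efa(morpho.elliptic_fourier(pts, n_harmonics=20))
    for _, pts in outlines
]
scores, var_frac = morpho.efa_pca(efas)
feats = traits[["term_dim", "lat_dim", "pet_dim", "hairs"]].copy()
feats["lat_PC1"] = scores[:, 0]

report = morpho.lda_loocv(feats, traits["lineage"])
print(f"LDA leave-one-out success rate: {report.success_rate:.1f}%")
print("confusion matrix (rows = truth):")
print(report.confusion.to_string())
print("-> the two similar lineages are confused more than the divergent one")
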