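"""Design a diagnostic SNP panel and assign samples to lineages.

Finds loci that are monomorphic within every lineage and fixed for
different alleles across a bipartition, keeps those suitable for a
melt-curve assay (one variable site, >= 18 invariant flanking bases),
builds two 4-locus panels, and assigns samples — flagging chimeric
mixed-signal samples as conflicts.
"""

import numpy as np

from selflines import assay
from selflines.synthetic import LineageConfig, simulate_lineage_dataset

cfg = LineageConfig(
    n_lineages=3,
    loci=800,
    site_plan={g: {"s1": 10, "s2": 10} for g in ("G1", "G2", "G3")},
    fixed_diff_fraction=np.array([[0, 0.3, 0.3], [0.3, 0, 0.14], [0.3, 0.14, 0]]),
    within_group_maf_dist=(1.2, 12.0),
    selfing_generations=float("inf"),
    multi_snp_fraction=0.3,  # some RAD loci carry a linked second SNP
    seed=61,
)
ds = simulate_lineage_dataset(cfg)
m = ds.genotypes
groups = m.individuals["group"].to_numpy()

panels, columns = [], {}
for pi, partition in enumerate(((["G1"], ["G2", "G3"]), (["G1", "G2"], ["G3"]))):
    cands = assay.find_diagnostic_loci(m, groups, partition)
    suitable = assay.filter_assay_suitable(cands, ds.rad_sequences)
    panel = assay.build_panel(partition, suitable, k_per_partition=4)
    panels.append(panel)
    for locus in panel.loci:
        columns[(pi, locus.rad_locus_id)] = locus.locus_index
    print(
        f"partition {partition}: {len(cands)} diagnostic, "
        f"{len(suitable)} assay-suitable, panel = "
        f"{[l.rad_locus_id for l in panel.loci]}"
    )

results = assay.assign_samples(m.calls[:6], m.individuals["id"][:6], panels, columns)
print("\nsample assignments (truth = prefix of the id):")
for r in results:
    print(f"  {r.sample_id}: {r.label}")
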