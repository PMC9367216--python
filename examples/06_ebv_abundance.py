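"""Annotate CDR3s against a specificity database and score EBV abundance.

Clusters containing at least one database-annotated EBV-specific CDR3
are EBV-specific clusters; a sample's EBV-specific abundance is the
summed fraction of all CDR3s in those clusters.
"""

import numpy as np

from tcrshare import (
    AntigenRecord, ClusterParams, SimConfig, annotate, build_clusters,
    ebv_abundance, ebv_cluster_members, label_ebv_clusters, simulate_cohort,
)
from tcrshare.simulate import EBV_FAMILY_SCORE_FLOOR

reps, meta, gt = simulate_cohort(
    SimConfig(n_control=6, n_tumor=6, clones_per_sample=800,
              n_ebv_families=2, ebv_family_size=8,
              stage_probs=(0.2, 0.2, 0.2, 0.4), seed=6)
)
# a miniature database listing only the family seeds as EBV-specific
db = [AntigenRecord(f["seed"], "RAKFKQLL", "EBV", "demo") for f in gt.ebv_families]

universe = sorted({aa for r in reps for aa in r.df["cdr3_aa"]})
clusters = build_clusters(universe, ClusterParams(score_threshold=EBV_FAMILY_SCORE_FLOOR))
annotations = annotate(universe, db)
labeled = label_ebv_clusters(clusters, annotations)
members = ebv_cluster_members(labeled, annotations)
planted = {m for f in gt.ebv_families for m in f["members"]}
print(f"EBV-cluster CDR3 universe: {len(members)} "
      f"(matches planted families: {members == planted})")

print("\nper-sample EBV-specific abundance:")
info = {m.sample_id: m for m in meta}
for rep in reps:
    res = ebv_abundance(rep, members)
    m = info[rep.sample_id]
    tag = f"{m.group}/{m.stage}"
    print(f"  {rep.sample_id} ({tag:10s}): {res.abundance:.4f} "
          f"({res.n_ebv_cluster_cdr3_present} CDR3 present)")
# Stage-IV samples carry the planted families at elevated rates, so their
# abundance exceeds the control baseline.
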