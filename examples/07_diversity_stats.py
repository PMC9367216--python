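"""Repertoire diversity indices and the cohort statistical tests."""

from tcrshare import (
    SimConfig, diversity, fisher_exact_2x2, simulate_cohort, wilcoxon_rank_sum,
)

reps, meta, _ = simulate_cohort(
    SimConfig(n_control=5, n_tumor=5, clones_per_sample=2000, seed=7)
)
print("sample_id  n_unique  shannon  clonality   d50")
for rep in reps[:4]:
    d = diversity(rep)
    print(f"{d.sample_id:9s}  {d.n_unique:8d}  {d.shannon:7.3f}  "
          f"{d.clonality:9.3f}  {d.d50:4d}")
# Shannon near ln(n_unique) and clonality near 0 mean an even repertoire;
# a small D50 means a few clones dominate half the reads.

groups = {m.sample_id: m.group for m in meta}
shannon = {r.sample_id: diversity(r).shannon for r in reps}
x = [v for k, v in shannon.items() if groups[k] == "tumor"]
y = [v for k, v in shannon.items() if groups[k] == "control"]
res = wilcoxon_rank_sum(x, y)
print(f"\nShannon tumor vs control: U={res.statistic:.1f}, p={res.p_value:.3f}")
# Tumor samples carry the planted hyper-expanded tumor-specific clones,
# which concentrate read mass and depress entropy; the rank-sum test
# detects exactly that planted difference.

res = fisher_exact_2x2([[8, 2], [1, 9]])
print(f"HLA-style carrier table [[8,2],[1,9]]: Fisher p={res.p_value:.5f}")
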