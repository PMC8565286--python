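"""Group-level aging analysis with permutation cluster inference.

Simulates a 40-subject cohort in which one network's coupling declines
linearly with age, computes per-subject CSI_P maps, regresses them on
age (gender covaried), and corrects cluster extents by permutation
FWE.  Also runs the young-vs-elderly two-sample verification.
"""

import numpy as np

from qda.experiments import aging_cohort_spec, cohort_metric_maps
from qda.group_stats import (
    cluster_table,
    critical_t,
    permutation_cluster_fwe,
    select_subgroups,
    two_sample_ttest,
)
from qda.synthetic import jaccard, network_voxel_ids

spec = aging_cohort_spec(seed=1)
truth = network_voxel_ids(spec, spec.networks[0])
pheno, mask, maps = cohort_metric_maps(spec, metric="csi_p")

t_crit = critical_t(0.001, len(pheno) - 3)
print(f"cluster-forming threshold: |t| >= {t_crit:.3f} "
      f"(two-sided p < 0.001, df = {len(pheno) - 3})")

clusters = permutation_cluster_fwe(maps, pheno, mask, t_crit, n_perm=500, seed=1)
print(cluster_table(clusters).to_string(index=False))
for c in clusters:
    if c.fwe_p <= 0.05:
        print(f"significant cluster: {c.size} voxels, "
              f"Jaccard with planted network = {jaccard(c.voxel_ids, truth):.2f}, "
              f"mean age slope = {c.mean_beta:+.5f} per year")

young, old, excluded = select_subgroups(pheno, (18, 30), (64, 76))
iy = pheno["subject_id"].isin(young).to_numpy()
io = pheno["subject_id"].isin(old).to_numpy()
t2, df2 = two_sample_ttest(maps[iy], maps[io])
print(f"young (n={iy.sum()}) vs elderly (n={io.sum()}), {len(excluded)} excluded: "
      f"mean t inside planted network {np.nanmean(t2[truth]):+.2f} (df={df2})")
print("A negative mean slope and a positive young-minus-elderly t inside "
      "the planted voxels both say the same thing: coupling falls with age.")
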