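"""Simulate and analyse a ten-subject paired-position cohort.

Draws per-subject deformity parameters around the neutral-supine cohort
means (Cobb 45° ± 7.8, kyphosis 23° ± 2.6, apical rotation 16° ± 6.6)
with coupled extension-induced changes, voxelises twenty phantoms
(1.5 mm), measures every one, and runs the paired statistics: per-outcome
means, percentage changes, paired t tests with Bonferroni control (alpha
0.05 / 4 outcomes = 0.0125), and Pearson correlations between the
plane-wise changes.  The correlation block quantifies the coupling: the
coronal Cobb reduction tracks the kyphosis reduction and the axial
derotation tracks the Cobb reduction.
"""

from spinemorph import cohort_report, simulate_cohort

cohort, truth = simulate_cohort(n_subjects=10, seed=1, voxel_mm=1.5)
rep = cohort_report(cohort)

print("paired outcomes (mean, SD, Δ%, paired t):")
print(rep["angles"].to_string(index=False))
print("\ndisc metrics (mean, SD, 95% CI):")
print(rep["discs"].to_string(index=False))
print("\ncorrelations between plane-wise reductions:")
print(rep["correlations"].round(3).to_string(index=False))
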