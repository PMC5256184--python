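"""Clean one subject's signals and build its binary graph stack.

Shows the standard cleaning order (discard 10 volumes, regress the
24-parameter motion expansion plus WM/CSF, band-pass 0.01-0.08 Hz), the
head-motion QC summaries, and the 31-density adjacency stack built from the
Pearson connectivity matrix.
"""

from hubcentral import graphs, preprocess, synthetic_cohort

design = synthetic_cohort.CohortDesign(n_per_group=1, groups=("HC",),
                                       affected_groups=(), n_timepoints=185,
                                       seed=11)
subject = synthetic_cohort.build_cohort(design)[0]

qc = preprocess.motion_qc(subject.nuisance.motion6)
print(f"motion QC: sum translation {qc.sum_translation_mm:.2f} mm, "
      f"sum rotation {qc.sum_rotation_deg:.3f} deg, "
      f"mean FD {qc.mean_fd_mm:.4f} mm")

clean = preprocess.clean_subject(subject.timeseries, subject.nuisance,
                                 n_discard=10)
print(f"volumes: {subject.timeseries.n_timepoints} acquired -> "
      f"{clean.n_timepoints} retained after discarding 10")

cm = graphs.correlation_matrix(clean)
stack = graphs.threshold_by_density(cm)
print(f"connectivity matrix: {cm.r.shape[0]} x {cm.r.shape[1]}")
print(f"densities: {len(stack.densities)} "
      f"({stack.densities[0]:.2f} to {stack.densities[-1]:.2f})")
print(f"edges at density 0.30: {stack[0.30].sum() // 2} "
      f"(= round(0.30 * 92 * 91 / 2))")
# Each density keeps the strongest correlations as edges; the edge sets are
# nested, so a sparse graph is always a subgraph of a denser one.
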