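"""Group comparison and clinical correlation on a small cohort.

Runs the repeated-measures group analysis (densities as the within-subject
factor, group between subjects, age/sex covariates) for the hub node, with
post hoc pairwise contrasts, and then correlates the hub's density-averaged
participation with the simulated tremor scores inside the affected group.
"""

from hubcentral import centrality, graphs, preprocess, stats, synthetic_cohort

design = synthetic_cohort.CohortDesign(
    n_per_group=12, groups=("TP", "HC"), n_nodes=40, n_timepoints=185,
    module_sizes=[10, 10, 10, 10], hub_boost=0.25, seed=33,
)
subjects = synthetic_cohort.build_cohort(design)
cohort = stats.score_definitions(synthetic_cohort.cohort_table(subjects))
hub = design.node_labels[design.hub_node]

grid = graphs.DensityGrid(0.10, 0.40, 0.05)
profiles = []
for s in subjects:
    clean = preprocess.clean_subject(s.timeseries, s.nuisance, n_discard=10)
    stack = graphs.threshold_by_density(graphs.correlation_matrix(clean), grid)
    profiles.append(centrality.profile_subject(stack, n_restarts=10, seed=2))
frame = stats.profiles_to_frame(profiles)

res = stats.rm_ancova(frame, cohort, hub, "participation")
print(f"group main effect on hub participation: "
      f"F({res.df_group[0]},{res.df_group[1]}) = {res.f_group:.2f}, "
      f"p = {res.p_group:.4f}")
print(res.posthoc[["group_a", "group_b", "t", "p"]].to_string(index=False))

report = stats.specificity_screen(
    frame, cohort, [hub], ("degree", "participation"),
    ["resting_tremor", "total_tremor", "bradykinesia"], groups=["TP"],
)
print("\npartial correlations (TP, age/sex adjusted):")
print(report.correlations[["metric", "score", "r", "p"]].to_string(index=False))
# Expected pattern: a significant group effect with TP > HC, tremor scores
# correlating with hub centrality, and bradykinesia (hub-independent by
# construction) staying null.
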