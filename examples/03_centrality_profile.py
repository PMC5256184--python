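"""Profile nodal centrality and compare the planted hub to its peers.

Computes degree, betweenness, within-module degree and participation
coefficient at every density for one affected (TP) and one control (HC)
subject, and prints the hub's density-averaged values.  The TP hub should
show clearly higher participation: its boosted cross-module correlations
turn it into a connector between modules.
"""

from hubcentral import centrality, graphs, preprocess, synthetic_cohort

design = synthetic_cohort.CohortDesign(
    n_per_group=1, groups=("TP", "HC"), n_nodes=40, n_timepoints=185,
    module_sizes=[10, 10, 10, 10], hub_boost=0.3, seed=21,
)
tp, hc = synthetic_cohort.build_cohort(design)
hub = design.node_labels[design.hub_node]

for subject in (tp, hc):
    clean = preprocess.clean_subject(subject.timeseries, subject.nuisance,
                                     n_discard=10)
    stack = graphs.threshold_by_density(graphs.correlation_matrix(clean))
    profile = centrality.profile_subject(stack, n_restarts=20, seed=1)
    avg = profile.density_averaged()
    row = avg.loc[hub]
    print(f"{subject.group}: hub {hub} density-averaged "
          f"K={row['degree']:.1f}  B={row['betweenness']:.0f}  "
          f"Z={row['within_module_degree']:.2f}  "
          f"P={row['participation']:.3f}  "
          f"(median P over nodes: {avg['participation'].median():.3f})")
# The TP subject's hub participation sits far above the node median; the HC
# hub is an ordinary provincial node.
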