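import numpy as np
import pytest

from hubcentral import centrality, graphs, preprocess, stats, synthetic_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_binary_graph(rng, n, p):
    """Random symmetric binary adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, k=1)
    return a + a.T


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with a planted hub effect, processed through
    the full profile path once and shared across statistics tests."""
    design = synthetic_cohort.CohortDesign(
        n_per_group=10,
        groups=("TP", "HC"),
        n_nodes=24,
        n_timepoints=150,
        module_sizes=[6, 6, 6, 6],
        hub_boost=0.3,
        seed=424242,
    )
    subjects = synthetic_cohort.build_cohort(design)
    cohort = stats.score_definitions(synthetic_cohort.cohort_table(subjects))
    grid = graphs.DensityGrid(0.10, 0.40, 0.06)
    profiles = []
    for s in subjects:
        clean = preprocess.clean_subject(s.timeseries, s.nuisance, n_discard=10)
        stack = graphs.threshold_by_density(graphs.correlation_matrix(clean), grid)
        profiles.append(centrality.profile_subject(stack, n_restarts=3, seed=7))
    frame = stats.profiles_to_frame(profiles)
    return design, subjects, cohort, frame
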