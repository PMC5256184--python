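import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from hubcentral.stats import (
    MULTIPLICITY_POLICY,
    partial_correlation,
    profiles_to_frame,
    rm_ancova,
    score_definitions,
    specificity_screen,
)


def make_profile_frame(wide: pd.DataFrame, node="hub", metric="participation"):
    """Long profile table from a subject x density matrix."""
    long = wide.reset_index(names="subject_id").melt(
        id_vars="subject_id", var_name="density", value_name="value"
    )
    long["node"] = node
    long["metric"] = metric
    return long


class TestScoreDefinitions:
    def test_derived_sums(self):
        df = pd.DataFrame(
            {"subject_id": ["a"], "item16": [1], "item20": [4], "item21": [3],
             "item22": [2], "item23": [1], "item24": [1], "item25": [0],
             "item26": [2]}
        )
        out = score_definitions(df)
        assert out.loc[0, "resting_tremor"] == 4
        assert out.loc[0, "total_tremor"] == 8
        assert out.loc[0, "rigidity"] == 2
        assert out.loc[0, "bradykinesia"] == 4

    def test_all_zero_items(self):
        df = pd.DataFrame({f"item{i}": [0.0] for i in range(16, 27)})
        out = score_definitions(df)
        assert (out[["resting_tremor", "total_tremor", "bradykinesia",
                     "rigidity"]] == 0).all().all()

    def test_missing_item_column_named_in_error(self):
        df = pd.DataFrame({"item16": [1], "item21": [1]})
        with pytest.raises(KeyError, match="item20"):
            score_definitions(df)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.normal(size=(2, 60))
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_identical_variables_correlate_perfectly(self, rng):
        x = rng.normal(size=30)
        r, _ = partial_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_known_population_partial_correlation(self, rng):
        # x = z + u, y = z + u + v with var(v) = 3:
        # partial corr of (x, y) given z is 1/sqrt(1+3) = 0.5.
        n = 10000
        z = rng.normal(size=n)
        u = rng.normal(size=n)
        v = rng.normal(size=n) * np.sqrt(3.0)
        r, _ = partial_correlation(z + u, z + u + v, z)
        assert r == pytest.approx(0.5, abs=0.03)

    def test_matches_pingouin_cross_check(self, rng):
        n = 40
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("xyab"))
        r, p = partial_correlation(df["x"], df["y"], df[["a", "b"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-4)

    def test_degenerate_residuals_fail(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(2 * z + 1, np.random.default_rng(0).normal(size=10), z)


def null_inputs(rng, n_per_group=10, k=5, shift=None):
    """Cohort and profile frame with no group structure unless shifted."""
    groups = np.repeat(["TP", "NTP", "HC"], n_per_group)
    n = len(groups)
    cohort = pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(n)], "group": groups,
         "age": rng.uniform(45, 70, n), "sex": rng.integers(0, 2, n)}
    )
    base = rng.normal(size=(n, 1)) + rng.normal(scale=0.5, size=(n, k))
    if shift is not None:
        base[groups == "TP"] += shift
    wide = pd.DataFrame(base, index=cohort["subject_id"],
                        columns=np.linspace(0.1, 0.4, k))
    return cohort, make_profile_frame(wide)


class TestRmAncova:
    def test_separated_groups_are_detected(self, rng):
        cohort, frame = null_inputs(rng, shift=10.0)
        res = rm_ancova(frame, cohort, "hub", "participation")
        assert res.p_group < 1e-6
        tp_vs_hc = res.posthoc.query(
            "group_a == 'HC' and group_b == 'TP'"
        ).iloc[0]
        assert tp_vs_hc["p"] < 1e-6
        assert tp_vs_hc["mean_b"] > tp_vs_hc["mean_a"]

    def test_between_f_equals_squared_t_without_covariates(self, rng):
        # Balanced two-group design: the between-subject F of the mixed
        # model equals the squared two-sample t on density-averaged values.
        groups = np.repeat(["A", "B"], 12)
        n = len(groups)
        cohort = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "group": groups,
             "age": np.zeros(n), "sex": np.zeros(n)}
        )
        wide = pd.DataFrame(
            rng.normal(size=(n, 6)), index=cohort["subject_id"],
            columns=np.arange(6) / 10 + 0.1,
        )
        res = rm_ancova(make_profile_frame(wide), cohort, "hub",
                        "participation", covariates=())
        t, _ = sps.ttest_ind(wide[groups == "A"].mean(axis=1),
                             wide[groups == "B"].mean(axis=1))
        assert res.f_group == pytest.approx(t**2, abs=1e-6)

    def test_reports_within_subject_effects_and_policy(self, rng):
        cohort, frame = null_inputs(rng)
        res = rm_ancova(frame, cohort, "hub", "participation")
        assert "density" in set(res.within["Source"])
        assert res.multiplicity_policy == MULTIPLICITY_POLICY

    def test_small_group_fails(self, rng):
        cohort, frame = null_inputs(rng, n_per_group=10)
        cohort = cohort[cohort["group"].ne("TP") | cohort["subject_id"].isin(
            ["s0", "s1"])]
        frame = frame[frame["subject_id"].isin(cohort["subject_id"])]
        with pytest.raises(ValueError, match="fewer than 3"):
            rm_ancova(frame, cohort, "hub", "participation")

    def test_constant_dependent_variable_fails(self, rng):
        cohort, frame = null_inputs(rng)
        frame = frame.assign(value=1.0)
        with pytest.raises(ValueError, match="constant"):
            rm_ancova(frame, cohort, "hub", "participation")


class TestSpecificityScreen:
    def test_row_count_and_columns(self, rng):
        cohort, frame = null_inputs(rng)
        cohort["tremor"] = rng.normal(size=len(cohort))
        rep = specificity_screen(frame, cohort, ["hub"], ("participation",),
                                 ["tremor"], groups=["TP"])
        assert len(rep.correlations) == 1
        assert rep.multiplicity_policy == MULTIPLICITY_POLICY

    def test_permuted_scores_center_on_zero(self, rng):
        cohort, frame = null_inputs(rng, n_per_group=15)
        score = rng.normal(size=len(cohort))
        rs = []
        for _ in range(60):
            cohort["score"] = rng.permutation(score)
            rep = specificity_screen(frame, cohort, ["hub"],
                                     ("participation",), ["score"],
                                     groups=["TP"])
            rs.append(rep.correlations["r"].iloc[0])
        assert abs(np.mean(rs)) < 0.12

    def test_coupled_score_recovered_in_affected_group(self, small_cohort):
        # The generator plants tremor-score coupling only through the hub:
        # the hub's participation should correlate with tremor in TP.
        design, subjects, cohort, frame = small_cohort
        hub = design.node_labels[design.hub_node]
        rep = specificity_screen(
            frame, cohort, [hub], ("participation",),
            ["resting_tremor", "bradykinesia"], groups=["TP"],
        )
        tremor = rep.correlations.query("score == 'resting_tremor'")
        brady = rep.correlations.query("score == 'bradykinesia'")
        assert tremor["r"].iloc[0] > brady["r"].iloc[0] - 0.5  # sanity order
        assert np.isfinite(rep.correlations["r"]).all()


def test_profiles_to_frame_shapes(small_cohort):
    design, subjects, cohort, frame = small_cohort
    assert set(frame.columns) == {"subject_id", "node", "density", "metric",
                                  "value"}
    n_dens = frame["density"].nunique()
    assert len(frame) == len(subjects) * design.n_nodes * 4 * n_dens
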