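"""Group statistics over centrality profiles.

The group analysis treats each node-metric pair as a repeated-measures
design: the 31 network densities are the within-subject factor, clinical
group (TP / NTP / HC) the between-subject factor, and age and sex enter as
covariates.  The reported group effect is the between-subject main effect,
which for a mixed design is exactly the ANCOVA on subject-level
density-averaged values (the between-subject stratum of a mixed ANOVA is an
ANOVA on subject means).  Within-subject effects are reported from a mixed
ANOVA on covariate-residualized values with Greenhouse-Geisser correction.

Post hoc pairwise group contrasts and the clinical partial correlations both
operate on the density-averaged, covariate-adjusted values.  No multiple-
testing correction is applied across nodes, metrics or scores — the metrics
are strongly interdependent and the node set is an a priori hypothesis — and
every report records that policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .centrality import METRICS, CentralityProfile

MULTIPLICITY_POLICY = (
    "no multiple-testing correction across nodes/metrics/scores "
    "(interdependent metrics, a priori node set); alpha = .05 per test"
)

#: Derived clinical scores as sums of UPDRS item columns.
SCORE_ITEMS = {
    "resting_tremor": ["item20"],
    "total_tremor": ["item16", "item20", "item21"],
    "rigidity": ["item22"],
    "bradykinesia": ["item23", "item24", "item25", "item26"],
}


def profiles_to_frame(profiles: list[CentralityProfile]) -> pd.DataFrame:
    """Stack per-subject centrality profiles into one long table
    (subject, node, density, metric, value)."""
    frames = []
    for p in profiles:
        df = p.values.copy()
        df.insert(0, "subject_id", p.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def score_definitions(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append derived clinical-score columns to a cohort table.

    resting_tremor = item 20; total_tremor = items 16+20+21;
    bradykinesia = items 23+24+25+26; rigidity = item 22.
    """
    out = cohort.copy()
    for score, items in SCORE_ITEMS.items():
        missing = [i for i in items if i not in out.columns]
        if missing:
            raise KeyError(
                f"cannot derive {score!r}: missing item column(s) {missing}"
            )
        out[score] = out[items].sum(axis=1)
    return out


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson partial correlation of x and y given covariates.

    Both variables are OLS-residualized on the covariates (plus intercept);
    the correlation of the residuals is tested against a t distribution with
    n - 2 - k degrees of freedom.  With no covariates this reduces to the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or np.size(covariates) == 0:
        z = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        z = np.column_stack([np.ones(n), c])
        k = c.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations, got {n}")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx <= 1e-10 * max(1.0, np.abs(x).max()) or \
            sy <= 1e-10 * max(1.0, np.abs(y).max()):
        raise ValueError("degenerate residual variance in partial correlation")
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if r**2 >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def _adjusted_means(
    means: pd.Series, cohort: pd.DataFrame, covariates: tuple[str, ...]
) -> pd.Series:
    """Residualize subject-level means on the covariates (plus intercept),
    adding back the grand mean.  Age is mean-centered; sex enters as 0/1."""
    if not covariates:
        return means
    sub = cohort.set_index("subject_id").loc[means.index]
    z = np.column_stack(
        [np.ones(len(means))]
        + [sub[c].to_numpy(float) - sub[c].to_numpy(float).mean()
           for c in covariates]
    )
    y = means.to_numpy(float)
    resid = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    return pd.Series(resid + y.mean(), index=means.index)


@dataclass
class RmAncovaResult:
    """Mixed-design group analysis of one node-metric pair."""

    node: str
    metric: str
    f_group: float
    p_group: float
    df_group: tuple[int, int]
    within: pd.DataFrame  # density and interaction effects (GG-corrected)
    posthoc: pd.DataFrame  # pairwise group contrasts on adjusted means
    n_per_group: dict[str, int]
    multiplicity_policy: str = MULTIPLICITY_POLICY


def rm_ancova(
    profile_frame: pd.DataFrame,
    cohort: pd.DataFrame,
    node: str,
    metric: str,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> RmAncovaResult:
    """Repeated-measures group analysis for one node and metric.

    ``profile_frame`` is the long table from :func:`profiles_to_frame`;
    every subject must contribute a value at every density.
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}")
    sub = profile_frame[
        (profile_frame["node"] == node) & (profile_frame["metric"] == metric)
    ]
    if sub.empty:
        raise ValueError(f"no profile values for node={node!r} metric={metric!r}")
    wide = sub.pivot(index="subject_id", columns="density", values="value")
    if wide.isna().any().any():
        raise ValueError("every subject needs a value at every density")
    info = cohort.set_index("subject_id").loc[wide.index]
    counts = info["group"].value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"group(s) with fewer than 3 subjects: {small}")
    if np.ptp(wide.to_numpy()) == 0:
        raise ValueError(
            f"dependent variable is constant for node={node!r} "
            f"metric={metric!r}; group model is undefined"
        )

    # Between-subject main effect: ANCOVA on density-averaged values.
    model_df = pd.DataFrame(
        {
            "dv": wide.mean(axis=1),
            "group": info["group"].astype(str),
        }
    )
    terms = ["C(group)"]
    for c in covariates:
        vals = info[c].to_numpy(float)
        model_df[c] = vals - vals.mean()
        terms.append(c)
    fit = ols("dv ~ " + " + ".join(terms), data=model_df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    f_group = float(table.loc["C(group)", "F"])
    p_group = float(table.loc["C(group)", "PR(>F)"])
    df_group = (int(table.loc["C(group)", "df"]),
                int(table.loc["Residual", "df"]))

    # Within-subject effects: mixed ANOVA on covariate-residualized values.
    resid_wide = wide.copy()
    if covariates:
        z = np.column_stack(
            [np.ones(len(wide))]
            + [model_df[c].to_numpy(float) for c in covariates]
        )
        y = wide.to_numpy(float)
        resid_wide.loc[:, :] = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    long = resid_wide.reset_index().melt(
        id_vars="subject_id", var_name="density", value_name="value"
    )
    long["group"] = info["group"].reindex(long["subject_id"]).to_numpy()
    aov = pg.mixed_anova(
        data=long, dv="value", within="density", subject="subject_id",
        between="group", correction=True,
    )
    within = aov[aov["Source"] != "group"].reset_index(drop=True)

    # Post hoc pairwise contrasts on covariate-adjusted density averages.
    adj = _adjusted_means(wide.mean(axis=1), cohort, covariates)
    rows = []
    for ga, gb in combinations(sorted(counts.index), 2):
        va = adj[info["group"] == ga].to_numpy()
        vb = adj[info["group"] == gb].to_numpy()
        t, p = sps.ttest_ind(va, vb)
        rows.append({"group_a": ga, "group_b": gb, "t": float(t),
                     "p": float(p),
                     "mean_a": float(va.mean()), "mean_b": float(vb.mean())})
    posthoc = pd.DataFrame(rows)
    return RmAncovaResult(
        node, metric, f_group, p_group, df_group, within, posthoc,
        counts.to_dict(),
    )


def group_effects(
    profile_frame: pd.DataFrame,
    cohort: pd.DataFrame,
    nodes: list[str],
    metrics: tuple[str, ...] = METRICS,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Group main effect for every node x metric pair, one row each."""
    rows = []
    for node in nodes:
        for metric in metrics:
            res = rm_ancova(profile_frame, cohort, node, metric, covariates)
            rows.append(
                {"node": node, "metric": metric, "F": res.f_group,
                 "p": res.p_group}
            )
    return pd.DataFrame(rows)


@dataclass
class StatReport:
    """Assembled partial-correlation grid with the multiplicity policy."""

    correlations: pd.DataFrame  # group, node, metric, score, n, r, p
    multiplicity_policy: str = MULTIPLICITY_POLICY
    ancova: pd.DataFrame | None = None


def specificity_screen(
    profile_frame: pd.DataFrame,
    cohort: pd.DataFrame,
    nodes: list[str],
    metrics: tuple[str, ...],
    scores: list[str],
    groups: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> StatReport:
    """Partial correlations of density-averaged metrics with clinical scores.

    Runs the full grid nodes x metrics x scores separately within each
    requested group (default: every group in the cohort), adjusting for the
    covariates.  Intended use: tremor scores should correlate in the
    affected group while bradykinesia/rigidity/global scores stay null.
    """
    if groups is None:
        groups = sorted(cohort["group"].unique())
    missing = [s for s in scores if s not in cohort.columns]
    if missing:
        raise KeyError(f"score column(s) not in cohort table: {missing}")
    avg = (
        profile_frame.groupby(["subject_id", "node", "metric"])["value"]
        .mean()
        .rename("value")
        .reset_index()
    )
    rows = []
    for grp in groups:
        members = cohort[cohort["group"] == grp]
        cov = (
            members[list(covariates)].to_numpy(float) if covariates else None
        )
        for node in nodes:
            for metric in metrics:
                sel = avg[(avg["node"] == node) & (avg["metric"] == metric)]
                sel = sel.set_index("subject_id")["value"]
                x = sel.reindex(members["subject_id"]).to_numpy(float)
                if np.isnan(x).any():
                    raise ValueError(
                        f"missing profile values for some {grp} subjects"
                    )
                for score in scores:
                    y = members[score].to_numpy(float)
                    r, p = partial_correlation(x, y, cov)
                    rows.append(
                        {"group": grp, "node": node, "metric": metric,
                         "score": score, "n": len(members), "r": r, "p": p}
                    )
    return StatReport(pd.DataFrame(rows))
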