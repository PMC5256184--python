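"""Region-level seed connectivity with permutation family-wise error control.

For each subject, the mean signal of a bilateral seed (e.g. putamen or
pallidum, averaging the left and right regions) enters a per-subject general
linear model as the regressor of interest alongside the nuisance design
(intercept, 24-parameter motion expansion, WM, CSF); the seed's OLS beta per
target region is the subject's connectivity estimate.

Group contrasts of the betas are evaluated inside an a priori region mask
(e.g. the bilateral thalami) with age/sex adjustment.  Family-wise error
over the mask is controlled exactly by the permutation distribution of the
maximum |t|: group labels are permuted with covariates held fixed, and each
region's corrected p is the tail probability of its observed |t| under the
max-statistic null.  The peak region is the largest observed |t|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NuisanceTable, RoiTimeSeries, expand_motion24
from .stats import partial_correlation

MAX_CONDITION_NUMBER = 1e8
DEFAULT_N_PERM = 5000


def seed_series(ts: RoiTimeSeries, seed_nodes: list[str]) -> np.ndarray:
    """Unweighted mean of the (typically left+right) seed region signals."""
    idx = [ts.node_labels.index(n) for n in seed_nodes if n in ts.node_labels]
    if len(idx) != len(seed_nodes):
        missing = [n for n in seed_nodes if n not in ts.node_labels]
        raise KeyError(f"seed node(s) not in series: {missing}")
    return ts.values[:, idx].mean(axis=1)


def first_level_betas(
    ts: RoiTimeSeries,
    nuisance: NuisanceTable,
    seed_nodes: list[str],
) -> pd.Series:
    """Per-target-region OLS beta of the seed regressor.

    The design is [intercept | seed | 24 motion regressors | WM | CSF]; the
    returned Series covers every node that is not part of the seed.  A seed
    that is (numerically) collinear with the nuisance design is rejected.
    """
    if nuisance.n_timepoints != ts.n_timepoints:
        raise ValueError("nuisance table and series cover different volumes")
    seed = seed_series(ts, seed_nodes)
    design = np.column_stack(
        [
            np.ones(ts.n_timepoints),
            seed,
            expand_motion24(nuisance.motion6),
            nuisance.wm,
            nuisance.csf,
        ]
    )
    scale = design.std(axis=0)
    scale[scale == 0] = 1.0
    cond = np.linalg.cond(design / scale)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        raise ValueError(
            "seed regressor is collinear with the nuisance design "
            f"(condition number {cond:.3g})"
        )
    targets = [n for n in ts.node_labels if n not in seed_nodes]
    cols = [ts.node_labels.index(n) for n in targets]
    beta = np.linalg.lstsq(design, ts.values[:, cols], rcond=None)[0]
    return pd.Series(beta[1], index=targets, name=ts.subject_id)


def collect_betas(
    subjects: list[tuple[RoiTimeSeries, NuisanceTable]],
    seed_nodes: list[str],
) -> pd.DataFrame:
    """Stack first-level betas into a subject x target-region table."""
    rows = [first_level_betas(ts, nu, seed_nodes) for ts, nu in subjects]
    return pd.DataFrame(rows)


@dataclass
class MaskContrastResult:
    """Group contrast within an a priori mask, max-statistic FWE corrected."""

    mask_nodes: list[str]
    group_a: str
    group_b: str
    t: pd.Series  # observed covariate-adjusted t per mask node (a minus b)
    p_uncorrected: pd.Series
    p_fwe: pd.Series
    peak_node: str
    n_perm: int


def _contrast_t(y: np.ndarray, g: np.ndarray, z: np.ndarray) -> np.ndarray:
    """t statistic of the group indicator in y ~ 1 + g + covariates,
    vectorized over the columns of y."""
    x = np.column_stack([np.ones(len(g)), g, z]) if z.size else np.column_stack(
        [np.ones(len(g)), g]
    )
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    return beta[1] / se


def group_contrast_fwe(
    betas: pd.DataFrame,
    cohort: pd.DataFrame,
    mask_nodes: list[str],
    group_a: str,
    group_b: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> MaskContrastResult:
    """Two-group contrast of seed betas over a mask with permutation FWE.

    Corrected p per node is (1 + #{max_perm |t| >= |t_obs|}) / (n_perm + 1),
    which is never smaller than the analogous per-node uncorrected p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    missing = [n for n in mask_nodes if n not in betas.columns]
    if missing:
        raise KeyError(f"mask node(s) without betas: {missing}")
    info = cohort.set_index("subject_id").loc[betas.index]
    in_pair = info["group"].isin([group_a, group_b])
    if info.loc[in_pair, "group"].nunique() < 2:
        raise ValueError(
            f"both groups {group_a!r} and {group_b!r} must be represented"
        )
    y = betas.loc[in_pair.to_numpy(), mask_nodes].to_numpy(float)
    sub = info[in_pair]
    g = (sub["group"] == group_a).to_numpy(float)
    z = (
        np.column_stack(
            [sub[c].to_numpy(float) - sub[c].to_numpy(float).mean()
             for c in covariates]
        )
        if covariates
        else np.empty((len(sub), 0))
    )
    t_obs = _contrast_t(y, g, z)

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(t_obs)
    max_null = np.empty(n_perm)
    exceed_node = np.zeros(len(mask_nodes))
    for b in range(n_perm):
        t_perm = _contrast_t(y, rng.permutation(g), z)
        a = np.abs(t_perm)
        max_null[b] = a.max()
        exceed_node += a >= abs_obs
    p_fwe = (1.0 + (max_null[:, None] >= abs_obs[None, :]).sum(axis=0)) / (
        n_perm + 1.0
    )
    p_unc = (1.0 + exceed_node) / (n_perm + 1.0)
    peak = mask_nodes[int(np.argmax(abs_obs))]
    return MaskContrastResult(
        list(mask_nodes), group_a, group_b,
        pd.Series(t_obs, index=mask_nodes, name="t"),
        pd.Series(p_unc, index=mask_nodes, name="p_uncorrected"),
        pd.Series(p_fwe, index=mask_nodes, name="p_fwe"),
        peak, n_perm,
    )


def beta_clinical_correlation(
    peak_betas: pd.Series,
    cohort: pd.DataFrame,
    scores: list[str],
    group: str,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Age/sex-adjusted partial correlations of peak-region betas with
    clinical scores within one group."""
    info = cohort.set_index("subject_id")
    members = info[info["group"] == group].index.intersection(peak_betas.index)
    if len(members) == 0:
        raise ValueError(f"no subjects with betas in group {group!r}")
    x = peak_betas.loc[members].to_numpy(float)
    sub = info.loc[members]
    cov = sub[list(covariates)].to_numpy(float) if covariates else None
    rows = []
    for score in scores:
        if score not in sub.columns:
            raise KeyError(f"score column {score!r} not in cohort table")
        r, p = partial_correlation(x, sub[score].to_numpy(float), cov)
        rows.append({"group": group, "score": score, "n": len(members),
                     "r": r, "p": p})
    return pd.DataFrame(rows)
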