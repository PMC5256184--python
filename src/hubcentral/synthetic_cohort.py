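"""Synthetic multi-subject cohorts with planted modular covariance.

Each subject's region-by-time matrix is drawn from a zero-mean multivariate
Gaussian whose correlation matrix has block structure: ``within_module_corr``
inside each planted module, ``between_module_corr`` across modules.  One
designated hub node has its cross-module correlations raised by
``hub_boost`` plus a per-subject jitter in the designated affected group(s),
emulating a region that becomes a connector hub in one clinical group.  A
simulated resting-tremor score is a noisy linear readout of each affected
subject's realized hub increment, so the clinical-correlation stages have a
recoverable planted target.

Motion-like nuisance series (slow random walks) and WM/CSF-like signals are
generated per subject and partially mixed into the region signals, so the
cleaning stage has real work to do.  The generator emulates the second-order
statistics the downstream graph analysis consumes — it makes no attempt at
hemodynamics, voxel geometry, or realistic fMRI noise spectra.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DEFAULT_LABELS
from .preprocess import NUISANCE_COLUMNS, NuisanceTable, RoiTimeSeries

#: Calibration of the simulated tremor score: score = baseline +
#: SCORE_SCALE * increment + N(0, score_noise_sd).  With the default jitter
#: sd of 0.08 and noise sd of 2.8, the population correlation between the
#: realized hub increment and the score is
#: SCORE_SCALE*0.08 / sqrt((SCORE_SCALE*0.08)^2 + 2.8^2) = 0.50.  The
#: baseline keeps the nonnegativity clip from truncating the distribution
#: (affected subjects have tremor regardless of their hub jitter).
SCORE_SCALE = 20.0
TREMOR_BASELINE = 4.0
DEFAULT_HUB_JITTER_SD = 0.08
DEFAULT_SCORE_NOISE_SD = 2.8

PSD_EIGEN_FLOOR = 1e-6


def _default_module_sizes(n_nodes: int, n_modules: int = 6) -> list[int]:
    if n_nodes == len(DEFAULT_LABELS):
        # Boundary placed between the putamen (striatal module, indices
        # 62-73) and the pallido-thalamic module (74-91), so the planted
        # thalamic hub gains cross-module coupling toward the putamen --
        # the configuration the seed-connectivity stage is meant to detect.
        return [16, 16, 15, 15, 12, 18]
    base, extra = divmod(n_nodes, n_modules)
    return [base + (1 if m < extra else 0) for m in range(n_modules)]


@dataclass
class CohortDesign:
    """Parameters of a synthetic cohort.

    Defaults mirror a three-group resting-state study: 92 regions sampled at
    TR = 2 s for 175 retained volumes, groups TP (tremor-dominant patients),
    NTP (non-tremor patients) and HC (healthy controls), with the hub effect
    planted in TP only.
    """

    n_per_group: int = 20
    groups: tuple[str, ...] = ("TP", "NTP", "HC")
    affected_groups: tuple[str, ...] = ("TP",)
    n_nodes: int = 92
    n_timepoints: int = 175
    tr_seconds: float = 2.0
    module_sizes: list[int] | None = None
    within_module_corr: float = 0.5
    between_module_corr: float = 0.1
    hub_node: int | None = None
    hub_boost: float = 0.25
    hub_jitter_sd: float = DEFAULT_HUB_JITTER_SD
    score_noise_sd: float = DEFAULT_SCORE_NOISE_SD
    nuisance_mix: float = 0.1
    confound_age: bool = False
    seed: int = 0
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = _default_module_sizes(self.n_nodes)
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError("module_sizes must sum to n_nodes")
        if min(self.module_sizes) < 2:
            raise ValueError("all module sizes must be >= 2")
        if not 0.0 <= self.between_module_corr < self.within_module_corr < 1.0:
            raise ValueError(
                "require 0 <= between_module_corr < within_module_corr < 1"
            )
        if not self.node_labels:
            if self.n_nodes == len(DEFAULT_LABELS):
                self.node_labels = list(DEFAULT_LABELS)
            else:
                width = len(str(self.n_nodes - 1))
                self.node_labels = [
                    f"Node_{i:0{width}d}" for i in range(self.n_nodes)
                ]
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length must equal n_nodes")
        if self.hub_node is None:
            self.hub_node = (
                self.node_labels.index("Thalamus_L")
                if "Thalamus_L" in self.node_labels
                else 0
            )
        if not 0 <= self.hub_node < self.n_nodes:
            raise ValueError("hub_node out of range")
        unknown = set(self.affected_groups) - set(self.groups)
        if unknown:
            raise ValueError(f"affected_groups not in groups: {unknown}")

    @property
    def module_labels(self) -> np.ndarray:
        """Planted module index (0..M-1) per node."""
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)

    def base_correlation(self) -> np.ndarray:
        """Block correlation matrix without any hub effect."""
        mod = self.module_labels
        same = mod[:, None] == mod[None, :]
        c = np.where(same, self.within_module_corr, self.between_module_corr)
        np.fill_diagonal(c, 1.0)
        return c


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    age: float
    sex: int
    timeseries: RoiTimeSeries
    nuisance: NuisanceTable
    tremor_score: float
    planted_hub_effect: float
    updrs_items: dict[str, float] = field(default_factory=dict)


def _repair_psd(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to a small floor and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= PSD_EIGEN_FLOOR:
        return corr
    vals = np.clip(vals, PSD_EIGEN_FLOOR, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    vmin = np.linalg.eigvalsh(repaired).min()
    if vmin <= 0:
        raise ValueError(
            f"covariance not positive definite after repair (min eig {vmin:g})"
        )
    return repaired


def _subject_correlation(design: CohortDesign, increment: float) -> np.ndarray:
    """Base block correlation with the hub's cross-module entries raised."""
    c = design.base_correlation().copy()
    if increment != 0.0:
        mod = design.module_labels
        h = design.hub_node
        other = mod != mod[h]
        boosted = np.clip(c[h, other] + increment, -0.95, 0.95)
        c[h, other] = boosted
        c[other, h] = boosted
    return _repair_psd(c)


def _smooth_walk(rng: np.random.Generator, t: int, step_sd: float) -> np.ndarray:
    """Slow drifting series: cumulative sum of small Gaussian steps."""
    return np.cumsum(rng.normal(0.0, step_sd, size=t))


def _make_nuisance(rng: np.random.Generator, t: int) -> NuisanceTable:
    motion = np.column_stack(
        [_smooth_walk(rng, t, 0.02) for _ in range(3)]
        + [_smooth_walk(rng, t, 4e-4) for _ in range(3)]
    )
    wm = _smooth_walk(rng, t, 0.1)
    csf = _smooth_walk(rng, t, 0.1)
    return NuisanceTable(motion, wm, csf)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def build_cohort(design: CohortDesign) -> list[SyntheticSubject]:
    """Generate the cohort; fully reproducible from ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    subjects: list[SyntheticSubject] = []
    chol_cache: dict[float, np.ndarray] = {}
    for group in design.groups:
        affected = group in design.affected_groups
        for k in range(design.n_per_group):
            sid = f"{group}{k + 1:03d}"
            increment = 0.0
            if affected:
                increment = max(
                    0.0,
                    design.hub_boost + rng.normal(0.0, design.hub_jitter_sd),
                )
            key = round(increment, 12)
            if key not in chol_cache:
                chol_cache[key] = np.linalg.cholesky(
                    _subject_correlation(design, increment)
                )
            chol = chol_cache[key]
            z = rng.standard_normal((design.n_timepoints, design.n_nodes))
            values = z @ chol.T

            nuisance = _make_nuisance(rng, design.n_timepoints)
            shared = _standardize(nuisance.wm) + _standardize(nuisance.csf)
            shared = shared + _standardize(nuisance.motion6[:, 0])
            values = values + design.nuisance_mix * shared[:, None]

            ts = RoiTimeSeries(sid, list(design.node_labels), values,
                               design.tr_seconds)

            age = float(rng.uniform(45.0, 70.0))
            sex = int(rng.integers(0, 2))
            if design.confound_age and affected:
                age += 5.0  # optional planted confound for adjustment tests

            items = _updrs_items(rng, design, group, affected, increment)
            subjects.append(
                SyntheticSubject(
                    subject_id=sid,
                    group=group,
                    age=age,
                    sex=sex,
                    timeseries=ts,
                    nuisance=nuisance,
                    tremor_score=items["item20"],
                    planted_hub_effect=increment,
                    updrs_items=items,
                )
            )
    return subjects


def _updrs_items(
    rng: np.random.Generator,
    design: CohortDesign,
    group: str,
    affected: bool,
    increment: float,
) -> dict[str, float]:
    """Simulated UPDRS-like item scores.

    Resting tremor (item 20) reads out the hub increment with noise; tremor
    history/action items (16, 21) carry half that loading; rigidity (22) and
    bradykinesia (23-26) are hub-independent patient symptoms, giving the
    specificity screen a true null.
    """
    items = {f"item{i}": 0.0 for i in (16, 20, 21, 22, 23, 24, 25, 26)}
    patient = group != "HC"
    if affected:
        items["item20"] = max(
            0.0,
            TREMOR_BASELINE + SCORE_SCALE * increment
            + rng.normal(0.0, design.score_noise_sd),
        )
        for i in (16, 21):
            items[f"item{i}"] = max(
                0.0,
                0.5 * TREMOR_BASELINE + 0.5 * SCORE_SCALE * increment
                + rng.normal(0.0, 2.0),
            )
    if patient:
        items["item22"] = max(0.0, rng.normal(1.5, 1.0))
        for i in (23, 24, 25, 26):
            items[f"item{i}"] = max(0.0, rng.normal(1.5, 1.0))
        if not affected:
            # non-tremor-dominant patients: no resting tremor (item 20 = 0)
            # but mild hub-independent history/action tremor
            for i in (16, 21):
                items[f"item{i}"] = max(0.0, rng.normal(0.5, 0.5))
    return items


def cohort_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Subject-level table: ids, group, covariates, tremor score, item scores."""
    item_names = sorted(
        {k for s in subjects for k in s.updrs_items},
        key=lambda n: int(n.removeprefix("item")),
    )
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "tremor_score": s.tremor_score,
            "planted_hub_effect": s.planted_hub_effect,
            **{n: s.updrs_items.get(n, 0.0) for n in item_names},
        }
        for s in subjects
    ]
    cols = [
        "subject_id", "group", "age", "sex", "tremor_score",
        "planted_hub_effect", *item_names,
    ]
    return pd.DataFrame(rows, columns=cols)


def write_cohort(subjects: list[SyntheticSubject], directory: str) -> dict:
    """Write one time-series TSV and one nuisance TSV per subject plus a
    cohort CSV; returns a manifest of the written paths."""
    os.makedirs(directory, exist_ok=True)
    manifest: dict = {"timeseries": {}, "nuisance": {}, "cohort": None}
    for s in subjects:
        ts_path = os.path.join(directory, f"{s.subject_id}_timeseries.tsv")
        pd.DataFrame(
            s.timeseries.values, columns=s.timeseries.node_labels
        ).to_csv(ts_path, sep="\t", index=False)
        nu_path = os.path.join(directory, f"{s.subject_id}_nuisance.tsv")
        pd.DataFrame(
            s.nuisance.to_array(), columns=NUISANCE_COLUMNS
        ).to_csv(nu_path, sep="\t", index=False)
        manifest["timeseries"][s.subject_id] = ts_path
        manifest["nuisance"][s.subject_id] = nu_path
    cohort_path = os.path.join(directory, "cohort.csv")
    cohort_table(subjects).to_csv(cohort_path, index=False)
    manifest["cohort"] = cohort_path
    return manifest


def read_subject(
    ts_path: str, nuisance_path: str, subject_id: str, tr_seconds: float = 2.0
) -> tuple[RoiTimeSeries, NuisanceTable]:
    """Round-trip reader for the TSV dialects written by :func:`write_cohort`."""
    ts_df = pd.read_csv(ts_path, sep="\t")
    nu_df = pd.read_csv(nuisance_path, sep="\t")
    missing = [c for c in NUISANCE_COLUMNS if c not in nu_df.columns]
    if missing:
        raise ValueError(f"nuisance table missing columns {missing}")
    ts = RoiTimeSeries(
        subject_id, list(ts_df.columns), ts_df.to_numpy(float), tr_seconds
    )
    nuis = NuisanceTable(
        nu_df[NUISANCE_COLUMNS[:6]].to_numpy(float),
        nu_df["wm"].to_numpy(float),
        nu_df["csf"].to_numpy(float),
    )
    return ts, nuis
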