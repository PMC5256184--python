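"""Region-level time-series cleaning and head-motion quality control.

The cleaning pipeline for resting-state region-averaged BOLD signals is the
standard strict-motion recipe, applied in a fixed order:

1. discard the first ``n_discard`` volumes (scanner equilibration),
2. regress out a 26-column nuisance design — the 24-parameter motion
   expansion (6 rigid-body parameters, their first differences, and the
   squares of those 12) plus mean white-matter and CSF signals, with an
   intercept — by ordinary least squares,
3. band-pass the residuals to 0.01–0.08 Hz with a zero-phase Butterworth
   filter.

Regression precedes filtering so that filtered nuisance structure cannot be
reintroduced into the residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

#: Head-radius (mm) used to convert rotational displacement to millimetres
#: in the scalar framewise-displacement summary.
FD_HEAD_RADIUS_MM = 50.0

NUISANCE_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz", "wm", "csf"]


@dataclass
class RoiTimeSeries:
    """One subject's region-by-time signal matrix.

    ``values`` is T x N (time points by regions); ``node_labels`` has length
    N and is shared across a cohort; ``tr_seconds`` is the sampling interval.
    """

    subject_id: str
    node_labels: list[str]
    values: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        if self.values.shape[1] != len(self.node_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.node_labels)} node labels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class NuisanceTable:
    """Per-volume nuisance signals: 6 rigid-body motion parameters
    (translations in mm, rotations in radians) plus mean WM and CSF signals.
    """

    motion6: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.motion6 = np.asarray(self.motion6, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        if self.motion6.ndim != 2 or self.motion6.shape[1] != 6:
            raise ValueError("motion6 must be T x 6")
        t = self.motion6.shape[0]
        if self.wm.shape[0] != t or self.csf.shape[0] != t:
            raise ValueError("wm/csf length must match motion6 rows")

    @property
    def n_timepoints(self) -> int:
        return self.motion6.shape[0]

    def drop_initial(self, n_discard: int) -> "NuisanceTable":
        """Trim the same initial volumes that were discarded from the series."""
        if n_discard >= self.n_timepoints:
            raise ValueError("n_discard >= number of time points")
        return NuisanceTable(
            self.motion6[n_discard:], self.wm[n_discard:], self.csf[n_discard:]
        )

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.motion6, self.wm, self.csf])


@dataclass(frozen=True)
class MotionQc:
    """Scalar head-motion summaries (all nonnegative).

    sum_translation_mm: summed volume-to-volume Euclidean translation.
    sum_rotation_deg: analogous summed rotational excursion, in degrees.
    mean_fd_mm: mean scalar framewise displacement — the sum of absolute
    parameter differences with rotations scaled by a 50 mm head radius.
    """

    sum_translation_mm: float
    sum_rotation_deg: float
    mean_fd_mm: float


def discard_initial(ts: RoiTimeSeries, n_discard: int = 10) -> RoiTimeSeries:
    """Drop the first ``n_discard`` volumes (default 10)."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_timepoints} time points"
        )
    return replace(ts, values=ts.values[n_discard:].copy())


def expand_motion24(motion6: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body parameters into the 24-regressor motion model.

    Columns are ordered [6 parameters | 6 backward differences (first row
    zero) | squares of those 12].
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion6 must be T x 6")
    deriv = np.zeros_like(motion6)
    deriv[1:] = np.diff(motion6, axis=0)
    first12 = np.column_stack([motion6, deriv])
    return np.column_stack([first12, first12**2])


def regress_nuisance(ts: RoiTimeSeries, regressors: np.ndarray) -> RoiTimeSeries:
    """OLS-residualize every node series on the nuisance design.

    An intercept column is always appended, so residuals are demeaned.
    Collinear columns are dropped (with a warning naming their indices)
    before solving, making the solution the unique least-squares fit on the
    retained columns.  Residuals are orthogonal to every retained regressor.
    """
    x = np.asarray(regressors, dtype=float)
    if x.ndim != 2 or x.shape[0] != ts.n_timepoints:
        raise ValueError("regressors must be T x k with T matching the series")
    design = np.column_stack([np.ones(ts.n_timepoints), x])
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more time points than regressors")

    # Rank check via QR: drop columns that add no independent direction.
    _, r = np.linalg.qr(design, mode="reduced")
    diag = np.abs(np.diag(r))
    tol = design.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    keep = np.ones(design.shape[1], dtype=bool)
    if (diag <= tol).any():
        # Greedy re-selection from the left: keep a column iff it increases rank.
        keep[:] = False
        rank = 0
        cur = np.empty((design.shape[0], 0))
        for j in range(design.shape[1]):
            cand = np.column_stack([cur, design[:, j]])
            if np.linalg.matrix_rank(cand) > rank:
                keep[j] = True
                cur = cand
                rank += 1
        dropped = [int(j) - 1 for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping collinear nuisance column(s) {dropped}", stacklevel=2
        )
    design = design[:, keep]

    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    return replace(ts, values=resid)


def bandpass(
    ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> RoiTimeSeries:
    """Zero-phase band-pass filter (second-order Butterworth, forward-backward).

    Defaults pass 0.01–0.08 Hz, the conventional resting-state band.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0.0 < low_hz < high_hz):
        raise ValueError("require 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist} Hz for TR={ts.tr_seconds} s"
        )
    sos = signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return replace(ts, values=np.ascontiguousarray(filtered))


def motion_qc(motion6: np.ndarray, tr_seconds: float = 2.0) -> MotionQc:
    """Head-motion summaries from the 6 rigid-body parameters.

    Rotations are assumed to be in radians.  The framewise displacement is
    the Power-style scalar: the sum of absolute volume-to-volume parameter
    differences, rotations converted to arc length on a 50 mm sphere.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion6 must be T x 6")
    if motion6.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    d = np.diff(motion6, axis=0)
    dtrans, drot = d[:, :3], d[:, 3:]
    sum_translation = float(np.sqrt((dtrans**2).sum(axis=1)).sum())
    sum_rotation_deg = float(
        np.degrees(np.sqrt((drot**2).sum(axis=1))).sum()
    )
    fd = np.abs(dtrans).sum(axis=1) + FD_HEAD_RADIUS_MM * np.abs(drot).sum(axis=1)
    return MotionQc(sum_translation, sum_rotation_deg, float(fd.mean()))


def clean_subject(
    ts: RoiTimeSeries,
    nuisance: NuisanceTable,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> RoiTimeSeries:
    """Full cleaning pipeline: discard, 26-regressor OLS, band-pass.

    ``nuisance`` must cover the same volumes as ``ts``; both are trimmed by
    ``n_discard`` before regression.
    """
    if nuisance.n_timepoints != ts.n_timepoints:
        raise ValueError("nuisance table and series cover different volumes")
    trimmed = discard_initial(ts, n_discard) if n_discard else ts
    nui = nuisance.drop_initial(n_discard) if n_discard else nuisance
    design = np.column_stack([expand_motion24(nui.motion6), nui.wm, nui.csf])
    resid = regress_nuisance(trimmed, design)
    return bandpass(resid, low_hz, high_hz)
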