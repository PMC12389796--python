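"""Hemodynamic response estimation: HRF kernel, design matrix, per-session GLM.

The task-locked response amplitude on each channel and chromophore is the
ordinary-least-squares coefficient of an HRF-convolved boxcar regressor.
One boxcar spans the execution windows of each motor-imagery task; a
delta-train regressor captures transient responses to the visual cues of
all non-preparatory instructions; rest is left unmodeled and serves as the
GLM baseline.  Preparation-interval regressors are constructed and checked
(they correlate strongly with the cue train after convolution because of
their short duration) but excluded from the fitted model.

The canonical HRF is a difference of two gamma densities (peak at ~5 s,
undershoot at ~15 s, peak:undershoot ratio 6), sampled at the recording's
1/Fs and normalized to unit sum so that a long boxcar convolves to a
plateau of height ~1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .montage_events import EventSchedule
from .preprocess import FilterSpec, bandpass

TASK_LABELS = ("mi_left", "mi_right", "mi_affected", "mi_intact")


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma HRF parameters (seconds), matching the standard defaults."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    onset: float = 0.0
    kernel_length: float = 32.0


def canonical_hrf(dt: float, spec: HrfSpec | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF at interval ``dt``, unit-sum normalized."""
    spec = spec or HrfSpec()
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > spec.kernel_length:
        raise ValueError("dt must not exceed kernel_length")
    if spec.peak_dispersion <= 0 or spec.undershoot_dispersion <= 0:
        raise ValueError("dispersions must be positive")
    t = np.arange(0.0, spec.kernel_length + dt / 2, dt) - spec.onset
    peak = stats.gamma.pdf(
        t, a=spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        a=spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - under / spec.peak_undershoot_ratio
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate HRF: non-positive kernel sum")
    return h / s


@dataclass
class DesignMatrix:
    """Named HRF-convolved regressors for one session."""

    names: list[str]
    values: np.ndarray  # (n_times, n_regressors)
    fs: float
    prep_cue_correlation: float | None = None  # why prep regressors are dropped

    def __post_init__(self) -> None:
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names/values mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("regressor names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def filtered(self, spec: FilterSpec | None = None) -> "DesignMatrix":
        """Band-pass every column except the intercept with the data's filter.

        Filtering regressors and data identically avoids the attenuation
        bias that filtering only one side of the regression would cause.
        """
        vals = self.values.copy()
        for j, name in enumerate(self.names):
            if name != "intercept":
                vals[:, j] = bandpass(vals[:, j], self.fs, spec)
        return DesignMatrix(list(self.names), vals, self.fs, self.prep_cue_correlation)


def _boxcar(n: int, fs: float, windows: list[tuple[float, float]]) -> np.ndarray:
    box = np.zeros(n)
    for onset, duration in windows:
        i0 = int(round(onset * fs))
        i1 = int(round((onset + duration) * fs))
        box[i0:min(i1, n)] = 1.0
    return box


def build_design(schedule: EventSchedule, hrf: HrfSpec | None = None) -> DesignMatrix:
    """Assemble the session design matrix from the event timeline.

    Columns: one HRF-convolved boxcar per motor-imagery task present, a
    shared HRF-convolved delta train over non-preparatory cue onsets, and
    an intercept.  Rest and preparation intervals are unmodeled; the
    correlation between the (discarded) preparation regressor and the cue
    regressor is recorded in ``prep_cue_correlation``.
    """
    if not schedule.phases:
        raise ValueError("empty schedule")
    n = schedule.n_samples
    fs = schedule.fs
    kernel = canonical_hrf(1.0 / fs, hrf)

    def conv(x: np.ndarray) -> np.ndarray:
        return np.convolve(x, kernel)[:n]

    names: list[str] = []
    cols: list[np.ndarray] = []
    for task in TASK_LABELS:
        windows = [(p.onset, p.duration) for p in schedule.phases if p.label == task]
        if windows:
            names.append(task)
            cols.append(conv(_boxcar(n, fs, windows)))

    cue = np.zeros(n)
    for t, _label in schedule.cue_onsets:
        i = int(round(t * fs))
        if i < n:
            cue[i] = 1.0
    names.append("cue")
    cols.append(conv(cue))

    prep_windows = [
        (p.onset, p.duration) for p in schedule.phases if p.label in ("prep_rest", "prep_task")
    ]
    prep_corr = None
    if prep_windows:
        prep = conv(_boxcar(n, fs, prep_windows))
        with np.errstate(invalid="ignore"):
            prep_corr = float(np.corrcoef(prep, cols[-1])[0, 1])

    names.append("intercept")
    cols.append(np.ones(n))
    return DesignMatrix(names, np.column_stack(cols), fs, prep_corr)


class HemodynamicGLM(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares GLM over many series at once.

    ``fit(X, y)`` with ``X`` the (n_times, n_regressors) design values and
    ``y`` of shape (n_times,) or (n_times, n_series).  No prewhitening is
    applied.  Fitted attributes: ``coef_`` (n_regressors, n_series),
    ``r2_``, ``resid_sd_`` per series.
    """

    def __init__(self, check_rank: bool = True):
        self.check_rank = check_rank

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("design rows must equal series length")
        if self.check_rank:
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                bad = _collinear_columns(X)
                raise ValueError(f"rank-deficient design; collinear columns: {bad}")
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_res = (resid**2).sum(axis=0)
        ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        dof = max(X.shape[0] - X.shape[1], 1)
        self.coef_ = coef
        self.r2_ = r2
        self.resid_sd_ = np.sqrt(ss_res / dof)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise AttributeError("HemodynamicGLM is not fitted")
        out = np.asarray(X, float) @ self.coef_
        return out[:, 0] if out.shape[1] == 1 else out


def _collinear_columns(X: np.ndarray) -> list[int]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    thresh = max(X.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    return [int(i) for i in np.where(diag < thresh)[0]]


def fit_glm(
    y: np.ndarray,
    design: DesignMatrix,
    series_names: list[str] | None = None,
) -> pd.DataFrame:
    """Fit the session GLM; return a tidy (series × regressor) coefficient table.

    ``y`` is (n_times, n_series).  The returned frame has columns
    ``series, task, coefficient, r2, resid_sd`` with one row per
    (series, regressor).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    model = HemodynamicGLM().fit(design.values, y)
    n_series = y.shape[1]
    if series_names is None:
        series_names = [f"s{i}" for i in range(n_series)]
    rows = []
    for j, sname in enumerate(series_names):
        for k, rname in enumerate(design.names):
            rows.append(
                {
                    "series": sname,
                    "task": rname,
                    "coefficient": model.coef_[k, j],
                    "r2": model.r2_[j],
                    "resid_sd": model.resid_sd_[j],
                }
            )
    return pd.DataFrame(rows)
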