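"""ROS production rates and membrane-potential proxies from time series.

Two quantifiers operate on fluorescence traces sampled at a fixed frame
interval (5 s by default):

* the **ROS production rate** is the slope of an ordinary least-squares
  line fitted to the intensity-vs-time curve, reported per minute and,
  after normalization, as a percentage of the pooled control mean
  (control = 100 %);
* the **membrane-potential proxy** (TMRM/FCCP protocol) is the maximal
  pre-uncoupler fluorescence minus the post-FCCP plateau, the plateau
  being the mean of the last ``plateau_frames`` frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_FRAME_DT = 5.0  # seconds between frames


@dataclass
class FluorescenceTrace:
    """Timestamped intensity series for one cell/well."""

    trace_id: str
    times: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray
    probe: str = ""  # DCF | MitoSOX | CM-H2XRos | TMRM
    group: str = ""  # cell line + condition label

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if len(self.times) < 3:
            raise ValueError("a trace needs at least 3 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RateResult:
    trace_id: str
    slope_per_min: float
    intercept: float
    fit_window: tuple[int, int]
    r_squared: float
    probe: str = ""
    group: str = ""
    percent_of_control: float | None = None


@dataclass
class PotentialResult:
    trace_id: str
    f_max: float
    f_post_fccp: float
    delta_psi_proxy: float
    group: str = ""
    percent_of_control: float | None = None
    flag: str | None = None


class RateFitter(BaseEstimator, RegressorMixin):
    """OLS line fit to a fluorescence trace; slope in intensity/min.

    Parameters
    ----------
    window : tuple of (start_frame, stop_frame) or None
        Half-open frame range to fit; None fits the full trace.

    Attributes
    ----------
    slope_per_min_ : float
        Fitted slope, per minute.
    intercept_ : float
        Fitted intercept at t = 0.
    r_squared_ : float
        Coefficient of determination of the fit.
    """

    def __init__(self, window: tuple[int, int] | None = None):
        self.window = window

    def fit(self, times, intensities):
        t = np.asarray(times, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        lo, hi = (0, len(t)) if self.window is None else self.window
        if lo < 0 or hi > len(t):
            raise ValueError(
                f"fit window ({lo}, {hi}) outside trace of {len(t)} frames"
            )
        if hi - lo < 3:
            raise ValueError("fit window must contain at least 3 frames")
        tw, yw = t[lo:hi], y[lo:hi]
        if np.ptp(yw) == 0.0:
            # degenerate constant trace: linregress r is undefined, slope is 0
            slope, intercept, r, stderr = 0.0, float(yw[0]), 1.0, 0.0
        else:
            res = sps.linregress(tw, yw)
            slope, intercept, r, stderr = res.slope, res.intercept, res.rvalue, res.stderr
        self.slope_per_min_ = float(slope * 60.0)
        self.slope_se_per_min_ = float(stderr * 60.0)
        self.intercept_ = float(intercept)
        self.r_squared_ = float(r**2)
        self.fit_window_ = (lo, hi)
        self.n_features_in_ = 1
        return self

    def predict(self, times):
        t = np.asarray(times, dtype=float)
        return self.intercept_ + self.slope_per_min_ / 60.0 * t


def fit_rate(trace: FluorescenceTrace, window: tuple[int, int] | None = None) -> RateResult:
    """OLS slope of a trace over a frame window, reported per minute."""
    fitter = RateFitter(window=window).fit(trace.times, trace.intensities)
    return RateResult(
        trace_id=trace.trace_id,
        slope_per_min=fitter.slope_per_min_,
        intercept=fitter.intercept_,
        fit_window=fitter.fit_window_,
        r_squared=fitter.r_squared_,
        probe=trace.probe,
        group=trace.group,
    )


def normalize_to_control(
    results: list[RateResult], control_group: str | list[str]
) -> list[RateResult]:
    """Express every slope as a percentage of the mean control slope.

    ``control_group`` may name several groups (e.g. two control lines
    pooled before averaging); the control mean maps to exactly 100 %.
    """
    controls = (
        {control_group} if isinstance(control_group, str) else set(control_group)
    )
    ctrl = [r.slope_per_min for r in results if r.group in controls]
    if not ctrl:
        raise ValueError(f"no traces in control group(s) {sorted(controls)}")
    mean_ctrl = float(np.mean(ctrl))
    if mean_ctrl <= 0:
        raise ValueError(f"control mean slope is non-positive ({mean_ctrl:.4g})")
    return [
        replace(r, percent_of_control=100.0 * r.slope_per_min / mean_ctrl)
        for r in results
    ]


def measure_potential(
    trace: FluorescenceTrace, fccp_frame: int, plateau_frames: int = 5
) -> PotentialResult:
    """ΔΨm proxy: maximal (pre-FCCP plateau) signal minus the post-FCCP plateau.

    Both plateau levels are estimated as means of ``plateau_frames``
    frames: the last frames before uncoupler addition (where a
    potentiometric trace is at its maximum) and the final frames of the
    recording (robust to the transient right after addition).  A plain
    per-frame maximum would carry an extreme-value bias of several noise
    standard deviations, so it is not used.  A negative or near-zero
    difference is flagged, not silently clipped.
    """
    n = len(trace)
    if not 0 < fccp_frame < n:
        raise ValueError(f"fccp_frame {fccp_frame} outside trace of {n} frames")
    n_post = n - fccp_frame
    if n_post < plateau_frames:
        raise ValueError(
            f"post-FCCP segment has {n_post} frames, fewer than the "
            f"{plateau_frames}-frame plateau window"
        )
    pre = trace.intensities[:fccp_frame]
    f_max = float(np.mean(pre[-min(plateau_frames, len(pre)):]))
    f_post = float(np.mean(trace.intensities[-plateau_frames:]))
    delta = f_max - f_post
    flag = None
    if delta < 0:
        flag = "negative_delta"
    elif f_max > 0 and delta < 0.01 * f_max:
        flag = "no_drop"
    return PotentialResult(
        trace_id=trace.trace_id,
        f_max=f_max,
        f_post_fccp=f_post,
        delta_psi_proxy=delta,
        group=trace.group,
        flag=flag,
    )


def normalize_potentials(
    results: list[PotentialResult], control_group: str | list[str]
) -> list[PotentialResult]:
    """Percent-of-control normalization for ΔΨm proxies."""
    controls = (
        {control_group} if isinstance(control_group, str) else set(control_group)
    )
    ctrl = [r.delta_psi_proxy for r in results if r.group in controls]
    if not ctrl:
        raise ValueError(f"no traces in control group(s) {sorted(controls)}")
    mean_ctrl = float(np.mean(ctrl))
    if mean_ctrl <= 0:
        raise ValueError(f"control mean delta is non-positive ({mean_ctrl:.4g})")
    return [
        replace(r, percent_of_control=100.0 * r.delta_psi_proxy / mean_ctrl)
        for r in results
    ]


def traces_from_frame(df: pd.DataFrame) -> list[FluorescenceTrace]:
    """Build traces from a long table (trace_id, frame, time_s, intensity).

    Optional columns ``probe`` and ``group`` are carried through.
    """
    required = {"trace_id", "time_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    for tid, sub in df.groupby("trace_id", sort=True):
        sub = sub.sort_values("time_s")
        traces.append(
            FluorescenceTrace(
                trace_id=str(tid),
                times=sub["time_s"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
                probe=str(sub["probe"].iloc[0]) if "probe" in sub else "",
                group=str(sub["group"].iloc[0]) if "group" in sub else "",
            )
        )
    return traces


def rate_results_frame(results: list[RateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trace_id": r.trace_id,
                "probe": r.probe,
                "group": r.group,
                "slope_per_min": r.slope_per_min,
                "intercept": r.intercept,
                "fit_start": r.fit_window[0],
                "fit_stop": r.fit_window[1],
                "r_squared": r.r_squared,
                "percent_of_control": r.percent_of_control,
            }
            for r in results
        ]
    )


def potential_results_frame(results: list[PotentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trace_id": r.trace_id,
                "group": r.group,
                "f_max": r.f_max,
                "f_post_fccp": r.f_post_fccp,
                "delta_psi_proxy": r.delta_psi_proxy,
                "percent_of_control": r.percent_of_control,
                "flag": r.flag,
            }
            for r in results
        ]
    )
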