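"""Peak-based oscillation metrics, supply-level scans and the log-scaling fit.

Frequency and mean amplitude follow the published estimation protocol: peaks
of the fluctuation series are counted on the window t in [50, 1000] and the
frequency is the peak count divided by the window length (950); the mean
amplitude is the average peak height relative to the zero-fluctuation
baseline.

The sustained/decaying classification is based on persistence of the
fluctuation rather than on the peak list: a run is *sustained* when the RMS of
the windowed series over the last quarter of the window is at least 25% of the
RMS over the first quarter.  Near the onset the instability manifests as a
fluctuation that stops decaying (the trajectory is displaced to a nonzero
level) before visible peaks develop, so a persistence criterion — unlike a
raw peak count — localizes the critical supply level.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

from .model import ModelParameters
from .simulate import SolverSettings, Trajectory, integrate

__all__ = [
    "PeakSet",
    "OscillationSummary",
    "LogFit",
    "detect_peaks",
    "summarize",
    "scan_p",
    "find_critical_p_sim",
    "fit_log",
]

#: Analysis window of the published protocol: from t = 50 (around when the
#: oscillation initiates) to t = 1000.
DEFAULT_WINDOW = (50.0, 1000.0)

#: Minimum prominence of a counted peak, as a fraction of the window's
#: max |series|; suppresses solver-tolerance-level ripple.
DEFAULT_PROMINENCE_FRAC = 0.05

#: A run is sustained when late-quarter RMS >= this fraction of early-quarter
#: RMS over the analysis window.
DEFAULT_SUSTAINED_RATIO = 0.25


@dataclass(frozen=True)
class PeakSet:
    """Peaks of one fluctuation series within an analysis window.

    ``early_rms`` / ``late_rms`` are the RMS of the series over the first and
    last quarter of the window; they feed the sustained classification.
    """

    variable: str
    times: np.ndarray
    heights: np.ndarray
    window: tuple
    prominence: float
    max_abs: float
    early_rms: float
    late_rms: float

    def __post_init__(self):
        if len(self.times) != len(self.heights):
            raise ValueError("times and heights must have equal lengths")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")
        if len(self.times) and not np.all(np.isfinite(self.heights)):
            raise ValueError("peak heights must be finite")

    @property
    def n_peaks(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class OscillationSummary:
    """Mean amplitude, frequency and classification of one run."""

    n_peaks: int
    frequency: float
    mean_amplitude: float
    sustained: bool
    variable: str = "x"
    window: tuple = DEFAULT_WINDOW


@dataclass(frozen=True)
class LogFit:
    """OLS fit of a metric against ln(eps), eps = p - p_c."""

    slope: float
    intercept: float
    r: float
    eps_grid: np.ndarray
    n: int
    degenerate: bool = False


def detect_peaks(traj: Trajectory, variable: str = "x",
                 window: tuple = DEFAULT_WINDOW,
                 prominence_frac: float = DEFAULT_PROMINENCE_FRAC) -> PeakSet:
    """Strict local maxima of a fluctuation series within a window.

    Peaks with prominence below ``prominence_frac`` times the window's
    max |series| are discarded.  Deterministic for a fixed trajectory.
    """
    if variable not in ("x", "z"):
        raise ValueError(f"variable must be 'x' or 'z', got {variable!r}")
    sub = traj.window(*window)  # raises if the window is not covered
    series = sub.x if variable == "x" else sub.z
    mx = float(np.max(np.abs(series))) if series.size else 0.0
    q = max(1, series.size // 4)
    early = float(np.sqrt(np.mean(series[:q] ** 2))) if series.size else 0.0
    late = float(np.sqrt(np.mean(series[-q:] ** 2))) if series.size else 0.0
    if mx == 0.0:
        idx = np.array([], dtype=int)
    else:
        idx, _ = find_peaks(series, prominence=prominence_frac * mx)
    return PeakSet(variable=variable, times=sub.t[idx], heights=series[idx],
                   window=(float(window[0]), float(window[1])),
                   prominence=prominence_frac * mx, max_abs=mx,
                   early_rms=early, late_rms=late)


def summarize(peaks: PeakSet, ss=None,
              sustained_ratio: float = DEFAULT_SUSTAINED_RATIO) -> OscillationSummary:
    """Frequency, mean amplitude and sustained classification of a peak set.

    frequency = n_peaks / (window length); mean_amplitude = mean peak height
    relative to the zero-fluctuation baseline (equivalently, X_total minus
    X_s — ``ss`` is accepted for interface symmetry but the baseline of the
    fluctuation series is identically zero).  An empty peak set yields
    (0, 0, not sustained), which is not an error.
    """
    t_min, t_max = peaks.window
    length = t_max - t_min
    n = peaks.n_peaks
    frequency = n / length
    mean_amplitude = float(np.mean(peaks.heights)) if n else 0.0
    sustained = bool(
        peaks.max_abs > 0.0
        and peaks.early_rms > 0.0
        and peaks.late_rms >= sustained_ratio * peaks.early_rms
    )
    return OscillationSummary(n_peaks=n, frequency=frequency,
                              mean_amplitude=mean_amplitude,
                              sustained=sustained, variable=peaks.variable,
                              window=peaks.window)


def _summarize_run(params: ModelParameters, init, settings, variable, window,
                   prominence_frac, sustained_ratio) -> OscillationSummary:
    traj = integrate(params, init=init, settings=settings)
    peaks = detect_peaks(traj, variable=variable, window=window,
                         prominence_frac=prominence_frac)
    return summarize(peaks, sustained_ratio=sustained_ratio)


def scan_p(base_params: ModelParameters, p_values,
           settings: SolverSettings | None = None,
           init=(1e-6, 1e-6), variable: str = "x",
           window: tuple = DEFAULT_WINDOW,
           prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
           sustained_ratio: float = DEFAULT_SUSTAINED_RATIO,
           p_c: float | None = None) -> pd.DataFrame:
    """One integration + summary per supply level, in input order.

    Per-p failures are recorded in the ``failed`` / ``error`` columns and the
    scan continues.  ``eps`` is p - p_c when ``p_c`` is given, else NaN.
    """
    rows = []
    for p in p_values:
        row = {"p": float(p),
               "eps": float(p) - p_c if p_c is not None else math.nan}
        try:
            s = _summarize_run(base_params.with_p(p).validate(), init,
                               settings, variable, window, prominence_frac,
                               sustained_ratio)
            row.update(n_peaks=s.n_peaks, frequency=s.frequency,
                       mean_amplitude=s.mean_amplitude,
                       sustained=s.sustained, failed=False, error="")
        except Exception as exc:  # noqa: BLE001 - per-point failures recorded
            row.update(n_peaks=0, frequency=math.nan,
                       mean_amplitude=math.nan, sustained=False,
                       failed=True, error=str(exc))
        rows.append(row)
    cols = ["p", "eps", "n_peaks", "frequency", "mean_amplitude",
            "sustained", "failed", "error"]
    return pd.DataFrame(rows, columns=cols)


def find_critical_p_sim(base_params: ModelParameters, bracket=(0.795, 0.81),
                        resolution: float = 1e-3,
                        settings: SolverSettings | None = None,
                        init=(1e-6, 1e-6), variable: str = "x",
                        window: tuple = DEFAULT_WINDOW,
                        prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                        sustained_ratio: float = DEFAULT_SUSTAINED_RATIO) -> float:
    """Onset of sustained fluctuation, by bisection on the classification.

    The bracket endpoints must classify differently (one sustained, one not);
    bisection proceeds down to ``resolution`` in p and returns the midpoint
    of the final bracket.
    """
    if settings is None:
        settings = SolverSettings(t_end=2000.0)

    def classify(p):
        return _summarize_run(base_params.with_p(p).validate(), init,
                              settings, variable, window, prominence_frac,
                              sustained_ratio).sustained

    lo, hi = float(bracket[0]), float(bracket[1])
    s_lo, s_hi = classify(lo), classify(hi)
    if s_lo == s_hi:
        raise ValueError(
            f"bracket endpoints classify identically (sustained={s_lo} at "
            f"both p={lo} and p={hi}); cannot bisect"
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if classify(mid) == s_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_log(eps_values, metric_values) -> LogFit:
    """Ordinary least squares of a metric on ln(eps).

    eps values must be strictly positive and at least three points are
    required.  A constant metric yields slope 0 with the correlation flagged
    undefined.
    """
    eps = np.asarray(eps_values, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if eps.shape != y.shape or eps.ndim != 1:
        raise ValueError("eps and metric must be 1-D arrays of equal length")
    if eps.size < 3:
        raise ValueError(f"at least 3 points required, got {eps.size}")
    if np.any(eps <= 0) or not np.all(np.isfinite(eps)):
        raise ValueError("eps values must be strictly positive and finite")
    if not np.all(np.isfinite(y)):
        raise ValueError("metric values must be finite")
    le = np.log(eps)
    if np.allclose(y, y[0], rtol=0.0, atol=0.0):
        return LogFit(slope=0.0, intercept=float(y[0]), r=math.nan,
                      eps_grid=eps, n=eps.size, degenerate=True)
    res = linregress(le, y)
    return LogFit(slope=float(res.slope), intercept=float(res.intercept),
                  r=float(res.rvalue), eps_grid=eps, n=eps.size)
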