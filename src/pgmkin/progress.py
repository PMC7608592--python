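"""Progress-curve analysis: lag phases, steady-state rates, observed rate
constants and apparent dephosphorylation rates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProgressCurve",
    "LagResult",
    "detect_lag",
    "kobs_from_p31",
    "apparent_dephos_rate",
    "absorbance_to_concentration",
]

CURVE_KINDS = ("absorbance", "concentration", "normalised_integral")


@dataclass
class ProgressCurve:
    """A timestamped observable trace.

    ``kind`` is one of ``absorbance`` (AU), ``concentration`` (uM) or
    ``normalised_integral`` (dimensionless).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "concentration"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("times and values must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class LagResult:
    lag_time: float
    steady_rate: float
    window: tuple[float, float]
    r_squared: float


def _linfit(t: np.ndarray, y: np.ndarray):
    """Slope, intercept and R^2 of an OLS line.  R^2 for zero-variance y is
    1.0 when residuals also vanish (an exactly flat segment is 'linear')."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-300:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def _rolling_slopes(t: np.ndarray, y: np.ndarray, w: int):
    """Slope and R^2 of every length-w sliding window."""
    n = len(t)
    slopes = np.empty(n - w + 1)
    r2s = np.empty(n - w + 1)
    for i in range(n - w + 1):
        slopes[i], _, r2s[i] = _linfit(t[i : i + w], y[i : i + w])
    return slopes, r2s


def detect_lag(curve: ProgressCurve, window_frac: float = 0.1) -> LagResult:
    """Lag time and steady rate from the maximal-slope tangent.

    A sliding window of ``window_frac`` of the points is scanned for the
    maximal slope; the lag time is the (clamped) x-intercept of the line
    fitted there, measured from the start of the curve.
    """
    if not (0 < window_frac <= 1):
        raise ValueError("window_frac must lie in (0, 1]")
    n = len(curve)
    if n < 10:
        raise ValueError("need at least 10 points to detect a lag")
    if curve.values[-1] < curve.values[0]:
        raise ValueError("curve is decreasing; wrong observable direction for lag detection")
    t, y = curve.times, curve.values
    w = max(3, int(round(window_frac * n)))
    slopes, _ = _rolling_slopes(t, y, w)
    i = int(np.argmax(slopes))
    tw, yw = t[i : i + w], y[i : i + w]
    slope, intercept, r2 = _linfit(tw, yw)
    if slope > 0:
        x_int = -intercept / slope
        lag = max(0.0, x_int - t[0])
    else:
        lag = 0.0
    return LagResult(
        lag_time=lag,
        steady_rate=slope,
        window=(float(tw[0]), float(tw[-1])),
        r_squared=r2,
    )


def _steady_window(
    t: np.ndarray,
    y: np.ndarray,
    window_frac: float = 0.1,
    r2_min: float = 0.999,
):
    """Indices (i0, i1) of the steady-state linear segment.

    Anchors at the maximal-slope sliding window among windows whose linear
    fit reaches ``r2_min``, then expands greedily while the fit quality holds.
    """
    n = len(t)
    w = max(3, min(n, int(round(window_frac * n))))
    slopes, r2s = _rolling_slopes(t, y, w)
    ok = r2s >= r2_min
    if not np.any(ok):
        raise ValueError(
            f"no linear segment with R^2 >= {r2_min}; supply manual bounds"
        )
    masked = np.where(ok, slopes, -np.inf)
    i0 = int(np.argmax(masked))
    i1 = i0 + w
    # greedy symmetric expansion
    improved = True
    while improved:
        improved = False
        if i1 < n:
            _, _, r2 = _linfit(t[i0:i1 + 1], y[i0:i1 + 1])
            if r2 >= r2_min:
                i1 += 1
                improved = True
        if i0 > 0:
            _, _, r2 = _linfit(t[i0 - 1:i1], y[i0 - 1:i1])
            if r2 >= r2_min:
                i0 -= 1
                improved = True
    return i0, i1


def kobs_from_p31(
    curve: ProgressCurve,
    substrate_total: float,
    E_T: float,
    segment: str | tuple[float, float] = "auto",
    r2_min: float = 0.999,
) -> float:
    """Observed per-enzyme rate constant from a product-fraction time course.

    k_obs = slope(product fraction) * substrate_total / E_T, taken over the
    steady-state linear segment (auto-selected unless bounds are given).
    """
    if curve.kind != "normalised_integral":
        raise ValueError("kobs_from_p31 expects a normalised_integral curve")
    if not (E_T > 0):
        raise ValueError("E_T must be positive")
    t, y = curve.times, curve.values
    if segment == "auto":
        i0, i1 = _steady_window(t, y, r2_min=r2_min)
        slope, _, _ = _linfit(t[i0:i1], y[i0:i1])
    else:
        t0, t1 = segment
        mask = (t >= t0) & (t <= t1)
        if mask.sum() < 3:
            raise ValueError("manual segment contains fewer than 3 points")
        slope, _, _ = _linfit(t[mask], y[mask])
    return slope * substrate_total / E_T


def apparent_dephos_rate(
    curve: ProgressCurve,
    E_T: float,
    r2_min: float = 0.999,
) -> float:
    """Apparent dephosphorylation rate constant from agent depletion.

    rate = -(steady linear slope of the free-agent trace) / E_T.  The initial
    phosphorylation transient is excluded by the linear-segment selection.
    """
    if not (E_T > 0):
        raise ValueError("E_T must be positive")
    t, y = curve.times, curve.values
    if y[-1] >= y[0]:
        raise ValueError("curve is not decreasing; no depletion to measure")
    i0, i1 = _steady_window(t, -y, r2_min=r2_min)
    slope, _, _ = _linfit(t[i0:i1], y[i0:i1])
    if slope >= 0:
        raise ValueError("selected segment is not decreasing")
    return -slope / E_T


def absorbance_to_concentration(
    curve: ProgressCurve, epsilon: float, path: float = 1.0
) -> ProgressCurve:
    """Inverse Beer-Lambert conversion: AU -> uM."""
    if curve.kind != "absorbance":
        raise ValueError("expected an absorbance curve")
    if not (epsilon > 0) or not (path > 0):
        raise ValueError("extinction coefficient and path length must be positive")
    conc_uM = curve.values / (epsilon * path) * 1e6
    return ProgressCurve(curve.times.copy(), conc_uM, kind="concentration")
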