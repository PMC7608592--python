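"""Ping-pong bi-bi rate law with substrate inhibition: evaluation and global fitting.

The steady-state velocity of a double-displacement phosphomutase reaction with
substrate (donor) inhibition is

    v0 = k_cat [E_T] S I / ( S I + K_S I + K_I_int S (K_i + S)/K_i )

with S the donor phosphosugar concentration, I the bisphosphate intermediate
concentration, K_S and K_I_int the respective Michaelis constants and K_i the
donor inhibition constant.  Setting K_i = +inf disables inhibition and recovers
the plain ping-pong form.

Units throughout: concentrations in uM, time in s, rates in uM s^-1, k_cat in
s^-1 (enzyme concentration in uM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticParameters",
    "InitialRateRecord",
    "FitResult",
    "evaluate_rate",
    "global_fit",
    "fit_initial_rate",
    "default_start",
    "UnderdeterminedError",
]

_PARAM_NAMES = ("k_cat", "K_bG1P", "K_bG16BP", "K_i")


class UnderdeterminedError(ValueError):
    """Raised when fewer distinct conditions than free parameters are available."""


@dataclass(frozen=True)
class KineticParameters:
    """Parameter vector of the inhibited ping-pong rate law.

    Attributes
    ----------
    k_cat : float
        Turnover number (s^-1).
    K_bG1P : float
        Michaelis constant for the donor sugar phosphate (uM).
    K_bG16BP : float
        Michaelis constant for the bisphosphate intermediate (uM).
    K_i : float
        Donor substrate-inhibition constant (uM).  ``math.inf`` disables
        inhibition.
    """

    k_cat: float
    K_bG1P: float
    K_bG16BP: float
    K_i: float = math.inf

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @property
    def has_inhibition(self) -> bool:
        return math.isfinite(self.K_i)

    def as_array(self, include_inhibition: bool = True) -> np.ndarray:
        vals = [self.k_cat, self.K_bG1P, self.K_bG16BP]
        if include_inhibition:
            vals.append(self.K_i)
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_array(cls, arr, include_inhibition: bool = True) -> "KineticParameters":
        arr = np.asarray(arr, dtype=float)
        if include_inhibition:
            return cls(*arr[:4])
        return cls(arr[0], arr[1], arr[2], math.inf)

    def scaled(self, factor: float) -> "KineticParameters":
        """Every parameter multiplied by ``factor`` (finite ones only)."""
        return KineticParameters(
            self.k_cat * factor,
            self.K_bG1P * factor,
            self.K_bG16BP * factor,
            self.K_i * factor if self.has_inhibition else math.inf,
        )


@dataclass(frozen=True)
class InitialRateRecord:
    """One plate-reader initial-rate measurement."""

    conc_bG1P: float
    conc_bG16BP: float
    E_T: float
    v0: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.conc_bG1P < 0 or self.conc_bG16BP < 0:
            raise ValueError("concentrations must be nonnegative")
        if not (self.E_T > 0):
            raise ValueError("E_T must be strictly positive")
        if self.v0 < 0:
            raise ValueError("v0 must be nonnegative")


#: canonical column names of an initial-rate table
RATE_TABLE_COLUMNS = ("bG1P_uM", "bG16BP_uM", "ET_uM", "v0_uM_per_s", "replicate")


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        (r.conc_bG1P, r.conc_bG16BP, r.E_T, r.v0, r.replicate) for r in records
    ]
    return pd.DataFrame(rows, columns=list(RATE_TABLE_COLUMNS))


@dataclass
class FitResult:
    """Outcome of a global rate-law fit."""

    params: KineticParameters
    param_sd: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    n_used: int = 0
    n_excluded: int = 0
    converged: bool = False

    def summary(self) -> str:
        parts = []
        for name in _PARAM_NAMES:
            value = getattr(self.params, name)
            sd = self.param_sd.get(name, float("nan"))
            parts.append(f"{name}={value:.6g}±{sd:.2g}")
        return (
            f"fit(converged={self.converged}, n={self.n_used}, "
            f"excluded={self.n_excluded}, ssr={self.residual_norm:.3g}): "
            + ", ".join(parts)
        )


def evaluate_rate(params: KineticParameters, conc_bG1P, conc_bG16BP, E_T):
    """Evaluate the inhibited ping-pong rate law.

    Accepts scalars or numpy arrays (broadcast).  Returns 0 where exactly one
    substrate concentration is zero; raises if both are zero anywhere.
    """
    S = np.asarray(conc_bG1P, dtype=float)
    I = np.asarray(conc_bG16BP, dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise ValueError("concentrations must be nonnegative")
    both_zero = (S == 0) & (I == 0)
    if np.any(both_zero):
        raise ValueError("rate undefined when both substrate concentrations are zero")

    if params.has_inhibition:
        inhibition = (params.K_i + S) / params.K_i
    else:
        inhibition = 1.0
    denom = S * I + params.K_bG1P * I + params.K_bG16BP * S * inhibition
    rate = params.k_cat * np.asarray(E_T, dtype=float) * S * I / denom
    if rate.ndim == 0:
        return float(rate)
    return rate


def default_start(data: pd.DataFrame) -> KineticParameters:
    """Scale-free starting values: k_cat from the fastest observed per-enzyme
    rate, Michaelis constants from the concentration medians, K_i at ten times
    the largest donor concentration."""
    v_per_e = data["v0_uM_per_s"] / data["ET_uM"]
    k_cat = max(float(v_per_e.max()), 1e-9)
    K_S = max(float(data["bG1P_uM"].median()), 1e-9)
    K_I = max(float(data["bG16BP_uM"].median()), 1e-9)
    K_i = 10.0 * max(float(data["bG1P_uM"].max()), 1e-9)
    return KineticParameters(k_cat, K_S, K_I, K_i)


def global_fit(
    data: pd.DataFrame,
    start: KineticParameters | None = None,
    filter_max_bG16BP: float | None = None,
    average_replicates: bool = True,
    fit_inhibition: bool = True,
    bootstrap: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Globally fit the rate law to an initial-rate table.

    Parameters
    ----------
    data : DataFrame
        Columns ``bG1P_uM, bG16BP_uM, ET_uM, v0_uM_per_s, replicate``.
    start : KineticParameters, optional
        Starting values; a scale-free heuristic is used if omitted.
    filter_max_bG16BP : float, optional
        Drop rows with intermediate concentration strictly above this value
        before fitting (the count is reported as ``n_excluded``).
    average_replicates : bool
        Fit per-condition means (default) rather than every replicate point.
    fit_inhibition : bool
        If False the inhibition constant is pinned at +inf and only three
        parameters are floated.
    bootstrap : int
        If > 0, parameter standard deviations come from a seeded residual
        bootstrap with this many resamples instead of the Jacobian covariance.
    """
    missing = [c for c in RATE_TABLE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"initial-rate table is missing columns: {missing}")
    n_total = len(data)
    if filter_max_bG16BP is not None:
        kept = data[data["bG16BP_uM"] <= filter_max_bG16BP].reset_index(drop=True)
    else:
        kept = data.reset_index(drop=True)
    n_excluded = n_total - len(kept)

    if average_replicates:
        kept = (
            kept.groupby(["bG1P_uM", "bG16BP_uM", "ET_uM"], as_index=False)[
                "v0_uM_per_s"
            ]
            .mean()
        )
    n_params = 4 if fit_inhibition else 3
    n_conditions = len(kept[["bG1P_uM", "bG16BP_uM"]].drop_duplicates())
    if n_conditions < max(4, n_params):
        raise UnderdeterminedError(
            f"only {n_conditions} distinct (S, I) conditions after filtering; "
            f"need at least {max(4, n_params)}"
        )

    S = kept["bG1P_uM"].to_numpy(float)
    I = kept["bG16BP_uM"].to_numpy(float)
    E = kept["ET_uM"].to_numpy(float)
    v = kept["v0_uM_per_s"].to_numpy(float)

    if start is None:
        start = default_start(kept)
    theta0 = np.log(start.as_array(include_inhibition=fit_inhibition))

    def residuals(theta, vobs):
        # clamp to keep exp() strictly positive and finite during exploration
        p = KineticParameters.from_array(
            np.exp(np.clip(theta, -100.0, 100.0)), include_inhibition=fit_inhibition
        )
        return evaluate_rate(p, S, I, E) - vobs

    def solve(t0):
        return least_squares(
            residuals,
            t0,
            args=(v,),
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=20000,
        )

    # multi-start: the requested start, a scale-free heuristic and two
    # deterministic jitters guard against local minima of the log-space problem
    starts = [theta0]
    heuristic = np.log(
        default_start(kept).as_array(include_inhibition=fit_inhibition)
    )
    starts.append(heuristic)
    starts.append(theta0 + np.log(3.0))
    starts.append(theta0 - np.log(3.0))
    sol = None
    for t0 in starts:
        candidate = solve(t0)
        if sol is None or np.sum(candidate.fun**2) < np.sum(sol.fun**2):
            sol = candidate
    theta = np.clip(sol.x, -100.0, 100.0)
    params = KineticParameters.from_array(np.exp(theta), include_inhibition=fit_inhibition)
    ssr = float(np.sum(sol.fun**2))
    converged = bool(sol.status > 0)

    # uncertainties -------------------------------------------------------
    n, p = len(v), len(theta)
    param_sd = {name: float("nan") for name in _PARAM_NAMES}
    fitted_names = _PARAM_NAMES[:p] if fit_inhibition else _PARAM_NAMES[:3]
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        fit_res = residuals(theta, v)  # model - observed
        v_model = v + fit_res
        draws = []
        for _ in range(bootstrap):
            resampled = v_model - rng.choice(fit_res, size=n, replace=True)
            b = least_squares(residuals, theta, args=(resampled,), method="lm")
            draws.append(np.exp(b.x))
        draws = np.asarray(draws)
        for j, name in enumerate(fitted_names):
            param_sd[name] = float(np.std(draws[:, j], ddof=1))
    elif n > p:
        s2 = ssr / (n - p)
        JTJ = sol.jac.T @ sol.jac
        try:
            cov_log = np.linalg.inv(JTJ) * s2
            sd_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        except np.linalg.LinAlgError:
            sd_log = np.sqrt(np.clip(np.diag(np.linalg.pinv(JTJ)) * s2, 0, None))
        values = np.exp(theta)
        for j, name in enumerate(fitted_names):
            param_sd[name] = float(values[j] * sd_log[j])  # delta method

    if not fit_inhibition:
        param_sd["K_i"] = 0.0

    return FitResult(
        params=params,
        param_sd=param_sd,
        residual_norm=ssr,
        n_used=len(v),
        n_excluded=n_excluded,
        converged=converged,
    )


def fit_initial_rate(curve, window: tuple[float, float]):
    """Ordinary least-squares slope of a progress curve over a time window.

    Returns (slope, intercept) in the curve's value units per second.
    """
    t0, t1 = window
    times = np.asarray(curve.times, dtype=float)
    values = np.asarray(curve.values, dtype=float)
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValueError(
            f"window ({t0}, {t1}) outside curve domain ({times[0]}, {times[-1]})"
        )
    mask = (times >= t0) & (times <= t1)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points inside the window")
    slope, intercept = np.polyfit(times[mask], values[mask], 1)
    return float(slope), float(intercept)
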