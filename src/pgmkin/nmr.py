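"""Slow-exchange NMR computations.

Combined amide chemical-shift differences, two-state populations from peak
intensities, the two-site longitudinal (ZZ) exchange model with equal
relaxation in both states, and cis/trans classification of proline residues
from their 13C-beta chemical shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import presets

__all__ = [
    "AmidePeak",
    "ZZDataset",
    "ExchangeFit",
    "PopulationEstimate",
    "combined_shift_difference",
    "populations_from_intensities",
    "zz_intensities",
    "fit_zz_exchange",
    "classify_proline_isomer",
    "NITROGEN_WEIGHT",
]

#: weight applied to the 15N dimension in the combined shift difference
NITROGEN_WEIGHT = 0.12


@dataclass(frozen=True)
class AmidePeak:
    """One backbone amide resonance (position+code, 1H/15N shifts, intensity)."""

    residue: str          # e.g. "A113"
    dH: float             # ppm
    dN: float             # ppm
    intensity: float = 1.0
    state_label: str = "A"

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")
        if not (5.0 <= self.dH <= 13.0):
            raise ValueError(f"1H shift {self.dH} ppm outside plausible window 5-13")
        if not (100.0 <= self.dN <= 140.0):
            raise ValueError(f"15N shift {self.dN} ppm outside plausible window 100-140")
        if self.state_label not in ("A", "B", "other"):
            raise ValueError(f"unknown state label {self.state_label!r}")


@dataclass
class ZZDataset:
    """Mixing-time-resolved auto/cross intensities for two-site exchange."""

    mixing_times: np.ndarray
    I_AA: np.ndarray
    I_BB: np.ndarray
    I_AB: np.ndarray
    I_BA: np.ndarray
    pA_hint: float | None = None

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        for name in ("I_AA", "I_BB", "I_AB", "I_BA"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.mixing_times.shape:
                raise ValueError(f"{name} length differs from mixing_times")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative intensities")
            setattr(self, name, arr)


@dataclass
class ExchangeFit:
    k_ex: float
    pA: float
    R1: float
    amplitude: float = 1.0
    sd: dict = field(default_factory=dict)
    converged: bool = False
    degenerate: bool = False

    @property
    def k_AB(self) -> float:
        """Forward rate, detailed balance: k_AB = pB * k_ex."""
        return (1.0 - self.pA) * self.k_ex

    @property
    def k_BA(self) -> float:
        return self.pA * self.k_ex


def combined_shift_difference(x: AmidePeak, y: AmidePeak) -> float:
    """Weighted Euclidean 1H/15N shift difference (ppm), nitrogen weight 0.12."""
    if x.residue != y.residue:
        raise ValueError(f"residue mismatch: {x.residue} vs {y.residue}")
    return math.hypot(x.dH - y.dH, NITROGEN_WEIGHT * (x.dN - y.dN))


@dataclass
class PopulationEstimate:
    pA: float
    pB: float
    iqr: float
    n_used: int


def populations_from_intensities(pairs) -> PopulationEstimate:
    """Two-state populations from per-residue A/B peak intensity pairs.

    Each element of ``pairs`` is a (peak_A, peak_B) tuple for one residue.
    Per-residue pA = I_A/(I_A+I_B); the median across residues is reported
    together with the interquartile range.  Residues with zero total
    intensity are skipped.
    """
    ratios = []
    for peak_a, peak_b in pairs:
        if peak_a.residue != peak_b.residue:
            raise ValueError(
                f"residue mismatch in pair: {peak_a.residue} vs {peak_b.residue}"
            )
        total = peak_a.intensity + peak_b.intensity
        if total <= 0:
            continue
        ratios.append(peak_a.intensity / total)
    if not ratios:
        raise ValueError("no residue with nonzero total intensity")
    ratios = np.asarray(ratios)
    pA = float(np.median(ratios))
    q1, q3 = np.percentile(ratios, [25, 75])
    return PopulationEstimate(pA=pA, pB=1.0 - pA, iqr=float(q3 - q1), n_used=len(ratios))


def zz_intensities(pA: float, k_ex: float, R1: float, t):
    """Two-site longitudinal exchange intensities at mixing time(s) t.

    Equal longitudinal relaxation in both states:

        I_AA = pA (pA + pB e^{-k_ex t}) e^{-R1 t}
        I_BB = pB (pB + pA e^{-k_ex t}) e^{-R1 t}
        I_AB = I_BA = pA pB (1 - e^{-k_ex t}) e^{-R1 t}
    """
    if not (0 < pA < 1):
        raise ValueError("pA must lie strictly between 0 and 1")
    if k_ex < 0 or R1 < 0:
        raise ValueError("rates must be nonnegative")
    t = np.asarray(t, dtype=float)
    pB = 1.0 - pA
    mix = np.exp(-k_ex * t)
    relax = np.exp(-R1 * t)
    I_AA = pA * (pA + pB * mix) * relax
    I_BB = pB * (pB + pA * mix) * relax
    I_AB = pA * pB * (1.0 - mix) * relax
    return I_AA, I_BB, I_AB, I_AB.copy()


def fit_zz_exchange(data: ZZDataset) -> ExchangeFit:
    """Joint least-squares fit of (pA, k_ex, R1, amplitude) to a ZZ dataset.

    The two cross-peak series are averaged before fitting.  Degenerate data
    with vanishing cross peaks return k_ex = 0 with ``degenerate=True``
    rather than raising.
    """
    t = data.mixing_times
    if len(t) < 3:
        raise ValueError("need at least 3 mixing times")
    cross = 0.5 * (data.I_AB + data.I_BA)
    auto_scale = max(float(np.max(data.I_AA + data.I_BB)), 1e-300)
    if float(np.max(cross)) <= 1e-9 * auto_scale:
        # no exchange signal at all
        pA0 = data.pA_hint if data.pA_hint is not None else _pA_guess(data)
        return ExchangeFit(
            k_ex=0.0, pA=pA0, R1=_r1_guess(data), amplitude=auto_scale,
            converged=True, degenerate=True,
        )

    pA0 = data.pA_hint if data.pA_hint is not None else _pA_guess(data)
    theta0 = np.array([
        math.log(pA0 / (1.0 - pA0)),       # logit pA
        math.log(max(_kex_guess(data), 1e-3)),
        math.log(max(_r1_guess(data), 1e-3)),
        math.log(auto_scale),
    ])

    def unpack(theta):
        pA = 1.0 / (1.0 + math.exp(-theta[0]))
        return pA, math.exp(theta[1]), math.exp(theta[2]), math.exp(theta[3])

    def residuals(theta):
        pA, k_ex, R1, amp = unpack(theta)
        I_AA, I_BB, I_AB, _ = zz_intensities(pA, k_ex, R1, t)
        return np.concatenate([
            amp * I_AA - data.I_AA,
            amp * I_BB - data.I_BB,
            amp * I_AB - cross,
        ])

    sol = least_squares(residuals, theta0, xtol=1e-15, ftol=1e-15, gtol=1e-15,
                        max_nfev=20000)
    pA, k_ex, R1, amp = unpack(sol.x)

    sd: dict = {}
    n, p = sol.fun.size, sol.x.size
    if n > p:
        s2 = float(np.sum(sol.fun**2)) / (n - p)
        try:
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * s2
            sd_theta = np.sqrt(np.clip(np.diag(cov), 0, None))
            # delta method back to natural scale
            sd = {
                "pA": float(pA * (1 - pA) * sd_theta[0]),
                "k_ex": float(k_ex * sd_theta[1]),
                "R1": float(R1 * sd_theta[2]),
                "amplitude": float(amp * sd_theta[3]),
            }
        except np.linalg.LinAlgError:
            sd = {}

    return ExchangeFit(
        k_ex=k_ex, pA=pA, R1=R1, amplitude=amp, sd=sd,
        converged=bool(sol.status > 0), degenerate=False,
    )


def _pA_guess(data: ZZDataset) -> float:
    total = data.I_AA[0] + data.I_BB[0]
    if total > 0:
        return float(np.clip(data.I_AA[0] / total, 0.05, 0.95))
    return 0.5


def _r1_guess(data: ZZDataset) -> float:
    tot = data.I_AA + data.I_BB + data.I_AB + data.I_BA
    positive = tot > 0
    if positive.sum() >= 2:
        t = data.mixing_times[positive]
        slope = np.polyfit(t, np.log(tot[positive]), 1)[0]
        return max(-float(slope), 1e-3)
    return 1.0


def _kex_guess(data: ZZDataset) -> float:
    # crude: cross/auto ratio at the first mixing time ~ pA pB k_ex t
    t0 = data.mixing_times[0]
    total = data.I_AA[0] + data.I_BB[0]
    cross0 = 0.5 * (data.I_AB[0] + data.I_BA[0])
    if total > 0 and t0 > 0:
        return float(np.clip(cross0 / total / (0.25 * t0), 1e-2, 50.0))
    return 1.0


def classify_proline_isomer(
    cbeta_shift: float,
    trans_max: float = presets.PRO_TRANS_MAX_PPM,
    cis_min: float = presets.PRO_CIS_MIN_PPM,
) -> str:
    """Classify a proline peptide-bond isomer from its 13C-beta shift (ppm).

    Cis-proline 13C-beta resonates 2.0-2.5 ppm downfield of trans; the default
    thresholds bracket the observed trans range (30.4-31.9 ppm) with a gap of
    ambiguity between ``trans_max`` and ``cis_min``.
    """
    if not (25.0 <= cbeta_shift <= 40.0):
        raise ValueError(
            f"13C-beta shift {cbeta_shift} ppm outside the proline window 25-40"
        )
    if cbeta_shift <= trans_max:
        return "trans"
    if cbeta_shift >= cis_min:
        return "cis"
    return "ambiguous"
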