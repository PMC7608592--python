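"""Seeded synthetic-data generators for every pipeline input.

All generators are deterministic functions of (parameters, seed): identical
seeds give bit-identical outputs.  Noise is Gaussian with a relative component
and a small absolute floor; negative noisy observables are truncated at zero
(a documented small positive bias at very low signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from . import presets, scheme as scheme_mod
from .nmr import AmidePeak, ZZDataset, zz_intensities
from .progress import ProgressCurve
from .rate_law import KineticParameters, RATE_TABLE_COLUMNS, evaluate_rate

__all__ = [
    "NoiseModel",
    "gen_rate_table",
    "gen_progress_curves",
    "gen_zz_dataset",
    "gen_peak_pairs",
]


@dataclass(frozen=True)
class NoiseModel:
    relative_sd: float = 0.02
    absolute_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0 or self.absolute_floor < 0:
            raise ValueError("noise magnitudes must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Additive Gaussian noise, sd = max(relative*|v|, floor), truncated at 0."""
        values = np.asarray(values, dtype=float)
        if self.relative_sd == 0 and self.absolute_floor == 0:
            return values.copy()
        sd = np.maximum(self.relative_sd * np.abs(values), self.absolute_floor)
        noisy = values + rng.normal(0.0, 1.0, size=values.shape) * sd
        return np.clip(noisy, 0.0, None)


NOISELESS = NoiseModel(relative_sd=0.0, absolute_floor=0.0, seed=0)


def gen_rate_table(
    params: KineticParameters,
    bG1P_list=presets.WT_BG1P_GRID_UM,
    bG16BP_list=presets.WT_BG16BP_GRID_UM,
    E_T: float = presets.WT_ET_UM,
    replicates: int = 3,
    noise: NoiseModel = NOISELESS,
) -> pd.DataFrame:
    """Full factorial initial-rate grid with replicate noise."""
    if not len(bG1P_list) or not len(bG16BP_list):
        raise ValueError("concentration lists must be nonempty")
    if min(bG1P_list) <= 0 or min(bG16BP_list) <= 0:
        raise ValueError("concentration lists must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = noise.rng()
    rows = []
    for S, I in product(bG1P_list, bG16BP_list):
        v_true = evaluate_rate(params, S, I, E_T)
        noisy = noise.apply(np.full(replicates, v_true), rng)
        for rep in range(replicates):
            rows.append((S, I, E_T, float(noisy[rep]), rep))
    return pd.DataFrame(rows, columns=list(RATE_TABLE_COLUMNS))


def gen_progress_curves(
    agents=("F16BP", "AcP", "bG16BP"),
    catalytic: KineticParameters = presets.WT_PARAMS,
    E_T: float = presets.ASSAY_ET_WT_UM,
    bG1P: float = presets.ASSAY_BG1P_UM,
    agent_conc: dict | None = None,
    populations=presets.CONFORMER_POPULATIONS,
    t_grid=None,
    noise: NoiseModel = NOISELESS,
    scheme_overrides: dict | None = None,
) -> dict:
    """One coupled-assay A340 curve per phosphorylating-agent scenario."""
    if t_grid is None:
        t_grid = np.linspace(0.0, 8000.0, 1601)
    agent_conc = dict(presets.AGENT_SCENARIOS if agent_conc is None else agent_conc)
    rng = noise.rng()
    curves = {}
    for agent in agents:
        spec = scheme_mod.build_allomorphy_scheme(
            agent, params=scheme_overrides, catalytic=catalytic
        )
        init = scheme_mod.AssayConditions(initial={
            "A": populations[0] * E_T,
            "B": populations[1] * E_T,
            "bG1P": bG1P,
            "agent": agent_conc[agent],
        })
        traj = scheme_mod.integrate(spec, init, t_grid)
        clean = scheme_mod.absorbance_observable(traj)
        curves[agent] = ProgressCurve(
            clean.times, noise.apply(clean.values, rng), kind="absorbance"
        )
    return curves


def gen_zz_dataset(
    pA: float = presets.CONFORMER_POPULATIONS[0],
    k_ex: float = 0.5,
    R1: float = 1.2,
    mixing_times=presets.ZZ_MIXING_TIMES_S,
    noise: NoiseModel = NOISELESS,
    amplitude: float = 1.0,
) -> ZZDataset:
    """Two-site ZZ-exchange intensities at the given mixing times, plus noise."""
    t = np.asarray(mixing_times, dtype=float)
    I_AA, I_BB, I_AB, I_BA = zz_intensities(pA, k_ex, R1, t)
    rng = noise.rng()
    return ZZDataset(
        mixing_times=t,
        I_AA=noise.apply(amplitude * I_AA, rng),
        I_BB=noise.apply(amplitude * I_BB, rng),
        I_AB=noise.apply(amplitude * I_AB, rng),
        I_BA=noise.apply(amplitude * I_BA, rng),
        pA_hint=None,
    )


_AA_CODES = "ACDEFGHIKLMNQRSTVWY"


def gen_peak_pairs(
    populations=presets.CONFORMER_POPULATIONS,
    n_residues: int = 102,
    shift_offset_sd=(0.05, 0.5),
    noise: NoiseModel = NOISELESS,
    base_intensity: float = 1000.0,
) -> list:
    """Per-residue A/B amide peak pairs with intensity ratio pA:pB.

    Returns a list of (peak_A, peak_B) tuples.  Shifts are drawn uniformly in
    plausible amide windows; the B-state peak is offset by a Gaussian
    perturbation with per-dimension sd ``shift_offset_sd`` (1H, 15N ppm).
    """
    pA, pB = populations
    if not (0 < pA < 1) or abs(pA + pB - 1.0) > 1e-9:
        raise ValueError("populations must be fractions summing to 1")
    rng = noise.rng()
    pairs = []
    for i in range(n_residues):
        code = _AA_CODES[int(rng.integers(len(_AA_CODES)))]
        residue = f"{code}{i + 2}"
        dH = float(rng.uniform(6.5, 10.0))
        dN = float(rng.uniform(105.0, 132.0))
        dH_b = float(np.clip(dH + rng.normal(0.0, shift_offset_sd[0]), 5.0, 13.0))
        dN_b = float(np.clip(dN + rng.normal(0.0, shift_offset_sd[1]), 100.0, 140.0))
        int_a = float(noise.apply(np.asarray(base_intensity * pA), rng))
        int_b = float(noise.apply(np.asarray(base_intensity * pB), rng))
        pairs.append(
            (
                AmidePeak(residue, dH, dN, int_a, "A"),
                AmidePeak(residue, dH_b, dN_b, int_b, "B"),
            )
        )
    return pairs
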