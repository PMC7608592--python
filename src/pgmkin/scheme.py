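"""Mass-action / condensed ODE simulation of the two-conformer phosphomutase
reaction scheme.

The substrate-free enzyme interconverts between two conformers A and B.  A
phosphorylating agent converts each to its phospho-form (A_P, B_P); B_P slowly
isomerises to the catalytically competent A_P and both phospho-forms hydrolyse.
The mutase turnover of the donor sugar phosphate runs as a condensed flux on
[A_P] using the inhibited ping-pong rate law, with a configurable fraction of
that flux released to solution as the bisphosphate intermediate.  The free
intermediate phosphorylates either conformer directly to A_P (producing
product), which is what removes the lag when the intermediate itself is the
initiating agent.

Units: uM, s.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .rate_law import KineticParameters, evaluate_rate
from . import presets

__all__ = [
    "SPECIES",
    "SchemeSpec",
    "AssayConditions",
    "Trajectory",
    "IntegrationError",
    "build_allomorphy_scheme",
    "integrate",
    "absorbance_observable",
    "p31_observable",
]

SPECIES = (
    "A",
    "B",
    "A_P",
    "B_P",
    "A_agent",
    "bG1P",
    "bG16BP",
    "G6P",
    "agent",
    "byproduct",
    "Pi",
    "NADH",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}

AGENT_KINDS = ("F16BP", "AcP", "bG16BP")

# byproduct pool released by agent phosphorylation
_BYPRODUCT_LABEL = {"F16BP": "fructose monophosphate", "AcP": "acetate", "bG16BP": "none"}

# phosphate moiety counts per species, by agent kind (NADH is bookkeeping only)
_AGENT_PHOSPHATES = {"F16BP": 2.0, "AcP": 1.0, "bG16BP": 2.0}
_BYPRODUCT_PHOSPHATES = {"F16BP": 1.0, "AcP": 0.0, "bG16BP": 0.0}

#: default rate constants (calibrated, not measured — see module docs);
#: hydrolysis/isomerisation constants are literature-anchored.
DEFAULT_RATES = {
    "k_AB": 0.03,          # s^-1, A -> B (70:30 equilibrium, k_AB+k_BA = 0.1)
    "k_BA": 0.07,          # s^-1, B -> A
    "k_phos_A": 3e-5,      # uM^-1 s^-1, agent phosphorylation of A
    "k_phos_B": 3e-5,      # uM^-1 s^-1, agent phosphorylation of B
    "k_isoP": presets.K_ISO_BP_TO_AP,     # s^-1, B_P -> A_P
    "k_hyd_AP": presets.K_HYDROLYSIS_AP,  # s^-1
    "k_hyd_BP": presets.K_DEPHOS_BP,      # s^-1
    "k_act_G16BP": 5.0,    # uM^-1 s^-1, A|B + intermediate -> A_P + product
}
# per-agent phosphorylation speed: AcP is inherently the faster agent
_AGENT_PHOS_RATE = {"F16BP": 3e-5, "AcP": 5e-5, "bG16BP": 0.0}


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time {last_time:.6g} s)")
        self.last_time = last_time


@dataclass
class SchemeSpec:
    """Reaction set + rate constants of the two-conformer scheme."""

    agent_kind: str
    rates: dict = field(default_factory=dict)
    catalytic: KineticParameters = presets.WT_PARAMS
    release_fraction: float = 0.02
    byproduct_label: str = ""

    def __post_init__(self) -> None:
        if self.agent_kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.agent_kind!r}")
        for name, value in self.rates.items():
            if name not in DEFAULT_RATES:
                raise ValueError(f"unknown rate constant {name!r}")
            if value < 0:
                raise ValueError(f"rate constant {name} must be nonnegative")
        if not (0 <= self.release_fraction < 1):
            raise ValueError("release_fraction must lie in [0, 1)")
        if not self.byproduct_label:
            self.byproduct_label = _BYPRODUCT_LABEL[self.agent_kind]

    def rate(self, name: str) -> float:
        return self.rates.get(name, DEFAULT_RATES[name])

    def hash(self) -> str:
        payload = {
            "agent_kind": self.agent_kind,
            "rates": {k: self.rates[k] for k in sorted(self.rates)},
            "catalytic": list(self.catalytic.as_array()),
            "release_fraction": self.release_fraction,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class AssayConditions:
    """Initial concentrations (uM) plus informational metadata."""

    initial: dict = field(default_factory=dict)
    temperature_K: float = 298.0
    path_cm: float = presets.DEFAULT_PATH_CM
    volume_uL: float = 160.0

    def __post_init__(self) -> None:
        for name, value in self.initial.items():
            if name not in _IDX:
                raise ValueError(f"unknown species {name!r}")
            if value < 0:
                raise ValueError(f"initial concentration of {name} must be nonnegative")
        if not (self.path_cm > 0):
            raise ValueError("path length must be positive")

    def vector(self) -> np.ndarray:
        y0 = np.zeros(len(SPECIES))
        for name, value in self.initial.items():
            y0[_IDX[name]] = value
        return y0


@dataclass
class Trajectory:
    times: np.ndarray
    concentrations: np.ndarray  # shape (n_species, n_times)
    species: tuple = SPECIES
    metadata: dict = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        return self.concentrations[self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: time_s, species, conc_uM."""
        rows = {
            "time_s": np.repeat(self.times, len(self.species)),
            "species": np.tile(np.asarray(self.species), len(self.times)),
            "conc_uM": self.concentrations.T.ravel(),
        }
        return pd.DataFrame(rows)


def build_allomorphy_scheme(
    agent_kind: str,
    params: dict | None = None,
    catalytic: KineticParameters = presets.WT_PARAMS,
    release_fraction: float = 0.02,
) -> SchemeSpec:
    """Assemble the reaction set for a given phosphorylating agent.

    For ``agent_kind="bG16BP"`` the agent pool is the intermediate itself:
    there are no agent-phosphorylation reactions (hence no route to B_P) and
    initiation proceeds exclusively through direct activation of either
    conformer to A_P.
    """
    if agent_kind not in AGENT_KINDS:
        raise ValueError(f"unknown agent kind {agent_kind!r}")
    rates = dict(DEFAULT_RATES)
    phos = _AGENT_PHOS_RATE[agent_kind]
    rates["k_phos_A"] = phos
    rates["k_phos_B"] = phos
    if params:
        for name, value in params.items():
            if name not in rates:
                raise ValueError(f"unknown rate constant {name!r}")
            rates[name] = value
    if agent_kind == "bG16BP":
        rates["k_phos_A"] = 0.0
        rates["k_phos_B"] = 0.0
    return SchemeSpec(
        agent_kind=agent_kind,
        rates=rates,
        catalytic=catalytic,
        release_fraction=release_fraction,
    )


def _rhs_factory(scheme: SchemeSpec):
    k = {name: scheme.rates.get(name, DEFAULT_RATES[name]) for name in DEFAULT_RATES}
    cat = scheme.catalytic
    f_rel = scheme.release_fraction
    iA, iB, iAP, iBP = _IDX["A"], _IDX["B"], _IDX["A_P"], _IDX["B_P"]
    iS, iI, iP = _IDX["bG1P"], _IDX["bG16BP"], _IDX["G6P"]
    iag, iby, iPi, iN = _IDX["agent"], _IDX["byproduct"], _IDX["Pi"], _IDX["NADH"]

    def rhs(t, y):
        A, B, AP, BP = y[iA], y[iB], y[iAP], y[iBP]
        S, I, agent = y[iS], y[iI], y[iag]
        # guard tiny negatives from the integrator
        A, B, AP, BP = max(A, 0.0), max(B, 0.0), max(AP, 0.0), max(BP, 0.0)
        S, I, agent = max(S, 0.0), max(I, 0.0), max(agent, 0.0)

        v_AB = k["k_AB"] * A
        v_BA = k["k_BA"] * B
        v_phos_A = k["k_phos_A"] * A * agent
        v_phos_B = k["k_phos_B"] * B * agent
        v_iso = k["k_isoP"] * BP
        v_hyd_A = k["k_hyd_AP"] * AP
        v_hyd_B = k["k_hyd_BP"] * BP

        # condensed mutase flux on A_P (zero when either pool is empty)
        if S > 0.0 and I > 0.0 and AP > 0.0:
            v_cat = evaluate_rate(cat, S, I, AP)
        else:
            v_cat = 0.0
        v_cat_net = (1.0 - f_rel) * v_cat
        # intermediate-release channel: A_P + S -> A + intermediate
        if f_rel > 0.0 and S > 0.0 and AP > 0.0:
            v_rel = f_rel * cat.k_cat * AP * S / (cat.K_bG1P + S)
        else:
            v_rel = 0.0
        # direct activation by the intermediate: A|B + I -> A_P + product
        v_act_A = k["k_act_G16BP"] * A * I
        v_act_B = k["k_act_G16BP"] * B * I

        dy = np.zeros_like(y)
        dy[iA] = -v_AB + v_BA - v_phos_A + v_hyd_A + v_rel - v_act_A
        dy[iB] = v_AB - v_BA - v_phos_B + v_hyd_B - v_act_B
        dy[iAP] = v_phos_A + v_iso - v_hyd_A - v_rel + v_act_A + v_act_B
        dy[iBP] = v_phos_B - v_iso - v_hyd_B
        dy[iS] = -v_cat_net - v_rel
        dy[iI] = v_rel - v_act_A - v_act_B
        dy[iP] = v_cat_net + v_act_A + v_act_B
        dy[iag] = -v_phos_A - v_phos_B
        dy[iby] = v_phos_A + v_phos_B
        dy[iPi] = v_hyd_A + v_hyd_B
        dy[iN] = v_cat_net + v_act_A + v_act_B  # cumulative product formed
        return dy

    return rhs


def integrate(
    scheme: SchemeSpec,
    init: AssayConditions,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Stiff-capable deterministic integration of the scheme on a time grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must contain at least two times")
    if t_grid[0] != 0 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing from 0")
    if not (rtol > 0 and atol > 0):
        raise ValueError("tolerances must be positive")

    y0 = init.vector()
    if scheme.agent_kind == "bG16BP" and y0[_IDX["agent"]] > 0:
        # the agent pool IS the intermediate
        y0[_IDX["bG16BP"]] += y0[_IDX["agent"]]
        y0[_IDX["agent"]] = 0.0

    sol = solve_ivp(
        _rhs_factory(scheme),
        (t_grid[0], t_grid[-1]),
        y0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else t_grid[0]
        raise IntegrationError(f"solver failed: {sol.message}", last)
    conc = np.clip(sol.y, 0.0, None)  # clip only at output
    meta = {
        "scheme_hash": scheme.hash(),
        "agent_kind": scheme.agent_kind,
        "rtol": rtol,
        "atol": atol,
        "method": "LSODA",
    }
    return Trajectory(times=t_grid, concentrations=conc, metadata=meta)


def absorbance_observable(
    traj: Trajectory,
    epsilon_NADH: float = presets.NADH_EPSILON_M_CM,
    path: float = presets.DEFAULT_PATH_CM,
):
    """Coupled-assay A340 trace under instantaneous coupling.

    The reduced-cofactor pool equals the cumulative product formed, so
    A340(t) = epsilon * path * [NADH](t) with uM -> M conversion.
    """
    from .progress import ProgressCurve

    if not (epsilon_NADH > 0) or not (path > 0):
        raise ValueError("extinction coefficient and path length must be positive")
    nadh_uM = traj.series("NADH")
    a340 = epsilon_NADH * path * nadh_uM * 1e-6
    return ProgressCurve(traj.times.copy(), a340, kind="absorbance")


def p31_observable(traj: Trajectory):
    """Normalised substrate and product integrals versus time.

    Both series are normalised by the initial phosphosugar pool
    ([bG1P](0) + [G6P](0)), mirroring integral normalisation of the two
    31P resonances.
    """
    from .progress import ProgressCurve

    s = traj.series("bG1P")
    p = traj.series("G6P")
    total0 = s[0] + p[0]
    if total0 <= 0:
        raise ValueError("initial phosphosugar pool is zero; cannot normalise")
    sub = ProgressCurve(traj.times.copy(), s / total0, kind="normalised_integral")
    prod = ProgressCurve(traj.times.copy(), p / total0, kind="normalised_integral")
    return sub, prod
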