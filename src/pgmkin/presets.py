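"""Reported enzymological constants and assay layouts used as package defaults.

Values are the published steady-state parameters of the L. lactis
beta-phosphoglucomutase wild type and its P146A variant, the plate-reader
concentration grids they were determined on, and the NMR acquisition settings
of the accompanying exchange experiments.  Units: uM, s.
"""

from __future__ import annotations

import math

from .rate_law import KineticParameters

# --- globally fitted rate-law parameters (uM, s) -------------------------
WT_PARAMS = KineticParameters(k_cat=382.0, K_bG1P=91.0, K_bG16BP=8.5, K_i=1510.0)
P146A_PARAMS = KineticParameters(k_cat=19.2, K_bG1P=157.0, K_bG16BP=175.0, K_i=933.0)

# --- plate-reader initial-rate grids -------------------------------------
WT_BG1P_GRID_UM = (10.0, 20.0, 30.0, 50.0, 70.0, 100.0, 150.0, 200.0, 300.0, 500.0, 700.0)
WT_BG16BP_GRID_UM = (0.4, 1.0, 2.0, 5.0, 10.0)
WT_ET_UM = 0.001  # 1 nM

P146A_BG1P_GRID_UM = (5.0, 10.0, 15.0, 20.0, 30.0, 50.0, 70.0, 100.0, 200.0, 300.0, 500.0)
P146A_BG16BP_GRID_UM = (2.0, 5.0, 10.0, 35.0, 50.0, 100.0)
P146A_ET_UM = 0.1  # 100 nM

# WT global fit excluded intermediate concentrations above this value
WT_FILTER_MAX_BG16BP_UM = 10.0

# --- coupled-assay agent scenarios (uM) ----------------------------------
AGENT_SCENARIOS = {
    "F16BP": 1000.0,
    "AcP": 8000.0,
    "bG16BP": 10.0,
}
ASSAY_BG1P_UM = 50.0
ASSAY_ET_WT_UM = 0.005   # 5 nM
ASSAY_ET_P146A_UM = 0.2  # 200 nM

# --- optical constants ----------------------------------------------------
NADH_EPSILON_M_CM = 6220.0  # M^-1 cm^-1 at 340 nm
DEFAULT_PATH_CM = 1.0

# --- slow-exchange NMR ----------------------------------------------------
ZZ_MIXING_TIMES_S = (0.1, 0.3, 0.5, 0.9)
CONFORMER_POPULATIONS = (0.70, 0.30)        # standard buffer
CONFORMER_POPULATIONS_MILK = (0.60, 0.40)
KEX_UPPER_BOUND_S = 1.0

# --- phospho-enzyme decay constants (s^-1) --------------------------------
K_HYDROLYSIS_AP = 0.06
K_DEPHOS_BP = 0.003
K_ISO_BP_TO_AP = 0.003

# dephosphorylation assay conditions
DEPHOS_ET_UM = 200.0        # 0.2 mM enzyme
DEPHOS_F16BP_UM = 50000.0   # 50 mM agent

# proline 13C-beta classification window (ppm)
PRO_TRANS_MAX_PPM = 32.4  # printed trans upper bound 31.9 + 0.5
PRO_CIS_MIN_PPM = 33.9    # printed trans upper bound 31.9 + 2.0

NO_INHIBITION = math.inf
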