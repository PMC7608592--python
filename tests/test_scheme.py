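import numpy as np
import pytest

from pgmkin import presets
from pgmkin.rate_law import evaluate_rate
from pgmkin.scheme import (
    AGENT_KINDS,
    AssayConditions,
    SchemeSpec,
    Trajectory,
    absorbance_observable,
    build_allomorphy_scheme,
    integrate,
    p31_observable,
)

ENZYME_SPECIES = ("A", "B", "A_P", "B_P", "A_agent")
GLUCOSE_SPECIES = ("bG1P", "bG16BP", "G6P")

# phosphate moiety weights per agent kind
PHOSPHATE_WEIGHTS = {
    "F16BP": {"bG1P": 1, "bG16BP": 2, "G6P": 1, "A_P": 1, "B_P": 1,
              "agent": 2, "byproduct": 1, "Pi": 1},
    "AcP": {"bG1P": 1, "bG16BP": 2, "G6P": 1, "A_P": 1, "B_P": 1,
            "agent": 1, "byproduct": 0, "Pi": 1},
    "bG16BP": {"bG1P": 1, "bG16BP": 2, "G6P": 1, "A_P": 1, "B_P": 1,
               "agent": 2, "byproduct": 0, "Pi": 1},
}


def moiety_sum(traj: Trajectory, weights: dict) -> np.ndarray:
    total = np.zeros_like(traj.times)
    for name, w in weights.items():
        total = total + w * traj.series(name)
    return total


def assert_conserved(series: np.ndarray, rel: float = 1e-8):
    ref = series[0]
    assert ref > 0
    assert np.max(np.abs(series - ref)) / ref < rel


def default_init(agent: str, e_t: float = 0.005) -> AssayConditions:
    return AssayConditions(initial={
        "A": 0.7 * e_t,
        "B": 0.3 * e_t,
        "bG1P": 50.0,
        "agent": presets.AGENT_SCENARIOS[agent],
    })


class TestBuildScheme:
    def test_unknown_agent_raises(self):
        with pytest.raises(ValueError, match="agent kind"):
            build_allomorphy_scheme("G6P")

    def test_bg16bp_scheme_has_no_bp_source(self):
        spec = build_allomorphy_scheme("bG16BP")
        assert spec.rate("k_phos_A") == 0.0
        assert spec.rate("k_phos_B") == 0.0

    def test_f16bp_byproduct_label(self):
        spec = build_allomorphy_scheme("F16BP")
        assert spec.byproduct_label == "fructose monophosphate"

    def test_override_unknown_rate_raises(self):
        with pytest.raises(ValueError, match="unknown rate"):
            build_allomorphy_scheme("F16BP", params={"k_bogus": 1.0})

    def test_negative_override_raises(self):
        with pytest.raises(ValueError):
            build_allomorphy_scheme("F16BP", params={"k_AB": -1.0})

    def test_degenerate_two_state_scheme(self):
        spec = build_allomorphy_scheme(
            "F16BP",
            params={"k_hyd_AP": 0.0, "k_hyd_BP": 0.0, "k_phos_A": 0.0,
                    "k_phos_B": 0.0, "k_act_G16BP": 0.0},
            release_fraction=0.0,
        )
        for name in ("k_hyd_AP", "k_hyd_BP", "k_phos_A", "k_phos_B"):
            assert spec.rate(name) == 0.0


class TestIntegrate:
    def test_two_state_symmetric_relaxation(self):
        # all reactions off except A<->B with k_AB = k_BA = k
        k = 0.05
        spec = build_allomorphy_scheme(
            "F16BP",
            params={"k_AB": k, "k_BA": k, "k_phos_A": 0.0, "k_phos_B": 0.0,
                    "k_hyd_AP": 0.0, "k_hyd_BP": 0.0, "k_isoP": 0.0,
                    "k_act_G16BP": 0.0},
            release_fraction=0.0,
        )
        e_t = 1.0
        init = AssayConditions(initial={"A": e_t})
        t = np.linspace(0, 200, 401)
        traj = integrate(spec, init, t)
        analytic = e_t / 2 + (e_t - e_t / 2) * np.exp(-2 * k * t)
        assert np.max(np.abs(traj.series("A") - analytic)) < 1e-6
        assert traj.series("A")[-1] == pytest.approx(e_t / 2, rel=1e-6)
        assert traj.series("B")[-1] == pytest.approx(e_t / 2, rel=1e-6)

    def test_equilibrium_populations_stationary(self):
        # start at the 70:30 equilibrium of k_BA:k_AB = 7:3 -> no drift
        spec = build_allomorphy_scheme(
            "F16BP",
            params={"k_AB": 0.03, "k_BA": 0.07, "k_phos_A": 0.0, "k_phos_B": 0.0,
                    "k_hyd_AP": 0.0, "k_hyd_BP": 0.0, "k_isoP": 0.0,
                    "k_act_G16BP": 0.0},
            release_fraction=0.0,
        )
        init = AssayConditions(initial={"A": 0.7, "B": 0.3})
        t = np.linspace(0, 500, 101)
        traj = integrate(spec, init, t)
        assert np.max(np.abs(traj.series("A") - 0.7)) < 1e-7
        assert np.max(np.abs(traj.series("B") - 0.3)) < 1e-7

    @pytest.mark.parametrize("agent", AGENT_KINDS)
    def test_enzyme_conservation(self, agent):
        spec = build_allomorphy_scheme(agent)
        traj = integrate(spec, default_init(agent), np.linspace(0, 2000, 201))
        enzyme = sum(traj.series(s) for s in ENZYME_SPECIES)
        assert_conserved(enzyme)

    @pytest.mark.parametrize("agent", AGENT_KINDS)
    def test_glucose_moiety_conservation(self, agent):
        spec = build_allomorphy_scheme(agent)
        traj = integrate(spec, default_init(agent), np.linspace(0, 2000, 201))
        glucose = sum(traj.series(s) for s in GLUCOSE_SPECIES)
        assert_conserved(glucose)

    @pytest.mark.parametrize("agent", AGENT_KINDS)
    def test_phosphate_moiety_conservation(self, agent):
        spec = build_allomorphy_scheme(agent)
        traj = integrate(spec, default_init(agent), np.linspace(0, 2000, 201))
        assert_conserved(moiety_sum(traj, PHOSPHATE_WEIGHTS[agent]))

    def test_no_bp_on_intermediate_pathway(self):
        spec = build_allomorphy_scheme("bG16BP")
        e_t = 0.005
        traj = integrate(spec, default_init("bG16BP", e_t), np.linspace(0, 2000, 201))
        assert traj.series("B_P").max() < 1e-3 * e_t

    def test_deterministic(self):
        spec = build_allomorphy_scheme("AcP")
        t = np.linspace(0, 100, 51)
        a = integrate(spec, default_init("AcP"), t)
        b = integrate(spec, default_init("AcP"), t)
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_bad_grid_raises(self):
        spec = build_allomorphy_scheme("AcP")
        with pytest.raises(ValueError, match="increasing"):
            integrate(spec, default_init("AcP"), [1.0, 0.5, 2.0])
        with pytest.raises(ValueError):
            integrate(spec, default_init("AcP"), [0.0, 1.0], rtol=-1.0)

    def test_steady_state_flux_matches_rate_law(self):
        """All enzyme clamped as A_P, no decay channels: d[G6P]/dt == rate law."""
        e_t, S0, I0 = 0.001, 200.0, 5.0
        spec = build_allomorphy_scheme(
            "F16BP",
            params={"k_AB": 0.0, "k_BA": 0.0, "k_phos_A": 0.0, "k_phos_B": 0.0,
                    "k_hyd_AP": 0.0, "k_hyd_BP": 0.0, "k_isoP": 0.0,
                    "k_act_G16BP": 0.0},
            release_fraction=0.0,
        )
        init = AssayConditions(initial={"A_P": e_t, "bG1P": S0, "bG16BP": I0})
        t = np.linspace(0, 1.0, 11)
        traj = integrate(spec, init, t)
        slope = (traj.series("G6P")[-1] - traj.series("G6P")[0]) / t[-1]
        expected = evaluate_rate(presets.WT_PARAMS, S0, I0, e_t)
        assert slope == pytest.approx(expected, rel=0.01)

    def test_unknown_species_in_conditions(self):
        with pytest.raises(ValueError, match="unknown species"):
            AssayConditions(initial={"X": 1.0})


class TestObservables:
    def test_beer_lambert_arithmetic(self):
        traj = Trajectory(
            times=np.array([0.0, 1.0]),
            concentrations=np.zeros((12, 2)),
        )
        traj.concentrations[traj.species.index("NADH")] = [0.0, 100.0]
        curve = absorbance_observable(traj, epsilon_NADH=6220.0, path=1.0)
        assert curve.values[-1] == pytest.approx(0.622, rel=1e-12)

    def test_zero_trajectory_flat_curve(self):
        traj = Trajectory(times=np.linspace(0, 10, 5),
                          concentrations=np.zeros((12, 5)))
        curve = absorbance_observable(traj)
        assert np.all(curve.values == 0.0)

    def test_full_conversion_plateau(self):
        spec = build_allomorphy_scheme("bG16BP")
        traj = integrate(spec, default_init("bG16BP"), np.linspace(0, 3000, 301))
        curve = absorbance_observable(traj)
        # 50 uM substrate fully converted: A340 ~ 6220 * 50e-6 = 0.311
        assert curve.values[-1] == pytest.approx(0.311, rel=0.05)
        assert np.all(np.diff(curve.values) >= -1e-12)  # monotone

    def test_p31_normalisation(self):
        spec = build_allomorphy_scheme("AcP")
        traj = integrate(spec, default_init("AcP"), np.linspace(0, 2000, 201))
        sub, prod = p31_observable(traj)
        assert sub.values[0] + prod.values[0] == pytest.approx(1.0, rel=1e-12)
        # substrate + product fractions never exceed the glucose pool; the
        # deficit is exactly the intermediate in solution
        assert np.all(sub.values + prod.values <= 1.0 + 1e-9)
        combined = sub.values + prod.values + traj.series("bG16BP") / 50.0
        assert np.allclose(combined, 1.0, atol=1e-6)

    def test_p31_no_enzyme(self):
        spec = build_allomorphy_scheme("AcP")
        init = AssayConditions(initial={"bG1P": 50.0, "agent": 8000.0})
        traj = integrate(spec, init, np.linspace(0, 100, 11))
        sub, prod = p31_observable(traj)
        assert np.allclose(sub.values, 1.0)
        assert np.allclose(prod.values, 0.0)

    def test_p31_zero_pool_raises(self):
        traj = Trajectory(times=np.linspace(0, 10, 5),
                          concentrations=np.zeros((12, 5)))
        with pytest.raises(ValueError, match="normalise"):
            p31_observable(traj)

    def test_p146a_p31_profile_lag_then_linear(self):
        """High-substrate equilibration with AcP: product curve shows an
        initial lag followed by a near-linear segment."""
        spec = build_allomorphy_scheme("AcP", catalytic=presets.P146A_PARAMS)
        init = AssayConditions(initial={
            "B": 2.0, "bG1P": 10000.0, "agent": 20000.0,
        })
        t = np.linspace(0, 3000, 601)
        traj = integrate(spec, init, t)
        _, prod = p31_observable(traj)
        early = (prod.values[20] - prod.values[0]) / (t[20] - t[0])
        late = (prod.values[400] - prod.values[300]) / (t[400] - t[300])
        assert late > 3 * early  # acceleration out of the lag
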