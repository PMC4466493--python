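"""The six flux components against closed forms and independent arithmetic.

The frozen numbers below were computed by evaluating each published rate
law step by step (plain scalar arithmetic, no package code) before the
vectorized implementations were written.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from rpewave import fluxes
from rpewave.params import ModelParams, count_to_um


@pytest.fixture(scope="module")
def p():
    return ModelParams()


class TestSSCC:
    def test_rest_is_fixed_point(self, p):
        dO, dtheta = fluxes.sscc_rates(0.0, 0.0, p)
        assert dO == 0.0 and dtheta == 0.0
        assert fluxes.sscc_flux(0.0, p) == 0.0

    def test_steady_state_open_fraction(self, p):
        theta = 0.096
        O_inf = theta * p.k_f / (theta * p.k_f + p.k_b)
        dO, _ = fluxes.sscc_rates(O_inf, theta, p)
        assert dO == pytest.approx(0.0, abs=1e-15)

    def test_stretch_relaxes_exponentially(self, p):
        theta0 = 0.096
        sol = solve_ivp(
            lambda t, y: [fluxes.sscc_rates(0.0, y[0], p)[1]],
            (0.0, 30.0),
            [theta0],
            rtol=1e-10,
            atol=1e-14,
            dense_output=True,
        )
        t = np.linspace(0.0, 30.0, 7)
        assert np.allclose(sol.sol(t)[0], theta0 * np.exp(-p.k_theta * t), rtol=1e-6)


class TestP2Y2:
    def test_no_ligand_rest_state(self, p):
        dR_S, dR_Sp = fluxes.p2y2_receptor_rates(p.R_T, 0.0, 0.0, p)
        assert dR_S == 0.0 and dR_Sp == 0.0

    def test_phosphorylation_saturates(self, p):
        R_S = 17000.0
        _, dR_Sp = fluxes.p2y2_receptor_rates(R_S, 0.0, 1e12, p)
        assert dR_Sp == pytest.approx(p.k_p * R_S, rel=1e-6)

    def test_phosphorylation_rate_at_K1(self, p):
        # L = K1 = 5 μM, R_S = 17000: dR_Sp/dt = 5 · 0.03 · 17000 / 10 = 255
        _, dR_Sp = fluxes.p2y2_receptor_rates(17000.0, 0.0, 5.0, p)
        assert dR_Sp == pytest.approx(255.0)

    def test_gprotein_basal_fixed_point(self, p):
        G_star = p.k_a * p.delta * p.G_T / (p.k_a * p.delta + p.k_d)
        assert G_star == pytest.approx(14.03, abs=5e-3)  # the tabulated initial G = 14
        assert fluxes.gprotein_rate(G_star, 17000.0, 0.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_full_occupancy_limit(self, p):
        assert fluxes.receptor_occupancy(p.xi * p.R_T, 1e12, p) == pytest.approx(1.0, rel=1e-6)

    def test_gprotein_saturation_bound(self, p):
        assert fluxes.gprotein_rate(p.G_T, 17000.0, 10.0, p) == pytest.approx(-p.k_d * p.G_T)


class TestIP3Production:
    def test_pure_degradation_without_gprotein(self, p):
        dIP3, _ = fluxes.ip3_production_rates(0.5, p.PIP2_T, 0.2, 0.0, p)
        assert dIP3 == pytest.approx(-p.k_deg * 0.5)

    def test_hydrolysis_saturates_in_calcium(self, p):
        assert fluxes.plc_hydrolysis_rate(1e9, 100.0, p) == pytest.approx(
            p.alpha * 100.0, rel=1e-6
        )

    def test_hydrolysis_half_max(self, p):
        # Ca = K3, G = 1e5: r_h = alpha/2 · G
        assert fluxes.plc_hydrolysis_rate(p.K3, 1e5, p) == pytest.approx(1.3905, rel=1e-6)

    def test_pip2_conservation_at_totals(self, p):
        # at PIP2 = PIP2_T with no hydrolysis and no IP3, replenishment is zero
        _, dPIP2 = fluxes.ip3_production_rates(0.0, p.PIP2_T, 1e-12, 0.0, p)
        assert dPIP2 == pytest.approx(0.0, abs=1e-9)


class TestIP3R3:
    def test_no_agonist_no_flux(self, p):
        assert fluxes.ip3r3_open_probability(0.12, 0.0, 0.0413, p) == 0.0
        assert fluxes.ip3r3_flux(0.12, 0.0, 0.0413, p) == 0.0

    def test_calcium_half_activation(self, p):
        k1 = p.alpha1 * p.beta1**3 / (p.beta1**3 + p.beta1**3)
        assert k1 == pytest.approx(p.alpha1 / 2.0)

    def test_basal_open_probability_oracle(self, p):
        # frozen step-by-step evaluation at Ca=0.12, IP3=0.01, alpha4=0.0413:
        # k1=0.1345459, k4=0.02065, phi=0.3387663, O=9.721724e-4
        O = fluxes.ip3r3_open_probability(0.12, 0.01, 0.0413, p)
        assert O == pytest.approx(9.721724e-4, rel=1e-6)
        assert fluxes.ip3r3_flux(0.12, 0.01, 0.0413, p) == pytest.approx(
            1.391684e-10, rel=1e-5
        )


class TestRyR:
    def test_high_calcium_limits(self, p):
        assert fluxes.ryr_open_probability(1e9, p) == pytest.approx(1.0, rel=1e-6)
        assert fluxes.ryr_flux(1e9, p) == pytest.approx(p.k_RyR, rel=1e-6)

    def test_basal_open_probability_oracle(self, p):
        # frozen step-by-step evaluation at Ca=0.12:
        # u=(Ka/Ca)^4, q=(Ca/Kb)^3, w=0.8424739, P=9.0614986e-3
        assert fluxes.ryr_open_probability(0.12, p) == pytest.approx(9.0614986e-3, rel=1e-6)
        assert fluxes.ryr_flux(0.12, p) == pytest.approx(0.1453464, rel=1e-5)

    def test_zero_calcium_rejected(self, p):
        with pytest.raises(ValueError):
            fluxes.ryr_open_probability(0.0, p)


class TestPump:
    def test_half_max_by_construction(self, p):
        assert fluxes.pump_flux(p.K_Pump, p) == pytest.approx(p.V_Pump / 2.0)
        assert p.V_Pump / 2.0 == pytest.approx(2.6705)

    def test_zero_and_basal(self, p):
        assert fluxes.pump_flux(0.0, p) == 0.0
        assert fluxes.pump_flux(0.12, p) == pytest.approx(0.2876134, rel=1e-6)


class TestGapJunctions:
    def test_no_gradient_no_flux(self, p):
        p0 = p.replace(In_Ca=0.0, In_IP3=0.0)
        areas = np.array([1512.0, 2520.0, 3528.0])
        j_ca, j_ip3 = fluxes.gj_fluxes(
            np.full(4, 0.12), np.full(4, 0.01), areas, p0
        )
        assert np.allclose(j_ca, 0.0) and np.allclose(j_ip3, 0.0)

    def test_two_layer_antisymmetry(self, p):
        p0 = p.replace(In_Ca=0.0, In_IP3=0.0)
        areas = np.array([1512.0])
        j_ca, _ = fluxes.gj_fluxes(np.array([0.3, 0.15]), np.zeros(2), areas, p0)
        assert j_ca[1] > 0
        assert j_ca[0] == pytest.approx(-j_ca[1])

    def test_interlayer_term_magnitude(self, p):
        # D/A · ΔCa = 512.7/1512 · 0.1445 ≈ 0.049 μM/s
        term = (p.D_Ca / 1512.0) * 0.1445
        assert term == pytest.approx(0.049, abs=5e-4)

    def test_boundary_terms(self, p):
        areas = np.array([1512.0])
        j_ca, j_ip3 = fluxes.gj_fluxes(np.full(2, 0.12), np.full(2, 0.01), areas, p)
        assert j_ca[0] == pytest.approx(p.In_Ca)
        assert j_ip3[0] == pytest.approx(p.In_IP3)
        assert j_ca[1] == pytest.approx(-p.Out_Ca)


# --- property tests ----------------------------------------------------------

positive_ca = st.floats(min_value=1e-4, max_value=100.0)


@settings(derandomize=True, max_examples=200)
@given(
    Ca=positive_ca,
    IP3=st.floats(min_value=0.0, max_value=1e3),
    alpha4=st.floats(min_value=1e-4, max_value=10.0),
)
def test_gating_quantities_bounded(Ca, IP3, alpha4):
    p = ModelParams()
    O = fluxes.ip3r3_open_probability(Ca, IP3, alpha4, p)
    assert 0.0 <= O <= 1.0 and 0.0 <= O**4 <= 1.0
    P = fluxes.ryr_open_probability(Ca, p)
    assert 0.0 <= P <= 1.0


@settings(derandomize=True, max_examples=100)
@given(lo=positive_ca, hi=positive_ca)
def test_pump_and_ip3r3_activation_monotone_in_calcium(lo, hi):
    p = ModelParams()
    a, b = sorted((lo, hi))
    assert fluxes.pump_flux(a, p) <= fluxes.pump_flux(b, p)
    k1 = lambda Ca: p.alpha1 * Ca**3 / (p.beta1**3 + Ca**3)
    assert k1(a) <= k1(b)


def test_ryr_monotone_above_Kb(p):
    Ca = np.linspace(ModelParams().Kb, 50.0, 500)
    J = fluxes.ryr_flux(Ca, p)
    assert np.all(np.diff(J) >= -1e-12)


def test_flux_functions_are_pure(p):
    args = (0.31, 0.22, 0.0413)
    a = fluxes.ip3r3_flux(*args, p)
    b = fluxes.ip3r3_flux(*args, p)
    assert a == b
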