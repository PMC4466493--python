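"""Assembly and integration of the coupled monolayer system."""

import numpy as np
import pytest

import rpewave as rw
from rpewave.simulator import Scenario, assemble_rhs, initial_state


class TestScenario:
    def test_gap_junction_switch_is_enforced(self, geom):
        assert Scenario.from_name("control", geom).gap_junctions_on
        assert not Scenario.from_name("GA_treated", geom).gap_junctions_on
        with pytest.raises(ValueError):
            Scenario(name=rw.ScenarioName.CONTROL, gap_junctions_on=False)
        with pytest.raises(ValueError):
            Scenario(name=rw.ScenarioName.GA_TREATED, gap_junctions_on=True)

    def test_suramin_overrides_interpolate_printed_endpoints(self, geom):
        s = Scenario.from_name("GA_suramin", geom)
        assert s.K1_per_layer[0] == pytest.approx(8.83)
        assert s.K1_per_layer[-1] == pytest.approx(5.15)
        assert s.k_p_per_layer[0] == pytest.approx(0.19)
        assert s.k_p_per_layer[-1] == pytest.approx(0.05)
        assert np.all(np.diff(s.K1_per_layer) < 0)
        with pytest.raises(ValueError):
            Scenario(name=rw.ScenarioName.CONTROL, gap_junctions_on=True,
                     K1_per_layer=(1.0,) * 10)


class TestRHS:
    def test_sscc_masked_beyond_ring_four(self, geom, params, stim):
        # open all channels everywhere: only rings 1-4 feel the SSCC flux
        rhs = assemble_rhs(Scenario.from_name("GA_treated", geom), params, geom, stim)
        y = initial_state(params, geom, stim).reshape(8, geom.n_layers)
        y[0] = 1.0  # O_SSCC
        base = rhs(50.0, y.ravel()).reshape(8, geom.n_layers)
        y2 = y.copy()
        y2[0] = 0.0
        no_sscc = rhs(50.0, y2.ravel()).reshape(8, geom.n_layers)
        dCa_diff = base[7] - no_sscc[7]
        assert np.allclose(dCa_diff[:4], params.k_SSCC)
        assert np.allclose(dCa_diff[4:], 0.0)

    def test_gap_junction_terms_only_in_control(self, geom, params):
        # use a stimulus whose GA and control alpha4 laws coincide so the
        # only difference between the two assembled systems is component VI
        stim = rw.StimulusParams(alpha4_prefactor_ga=0.0282, alpha4_growth_ga=0.0138)
        y = initial_state(params, geom, stim)
        rhs_ga = assemble_rhs(Scenario.from_name("GA_treated", geom), params, geom, stim)
        rhs_c = assemble_rhs(Scenario.from_name("control", geom), params, geom, stim)
        d_ga = rhs_ga(1.0, y).reshape(8, -1)
        d_c = rhs_c(1.0, y).reshape(8, -1)
        # uniform initial concentrations: the only GJ contribution is the
        # constant MS-cell input into ring 1
        assert d_c[7, 0] - d_ga[7, 0] == pytest.approx(params.In_Ca)
        assert d_c[5, 0] - d_ga[5, 0] == pytest.approx(params.In_IP3)
        assert np.allclose(d_c[:, 1:], d_ga[:, 1:])

    def test_state_length_mismatch_rejected(self, geom, params, stim):
        rhs = assemble_rhs(Scenario.from_name("GA_treated", geom), params, geom, stim)
        with pytest.raises(ValueError):
            rhs(1.0, np.zeros(7))

    def test_finite_difference_consistency(self, geom, params, stim):
        # the RHS is the derivative of a short accurate integration
        from scipy.integrate import solve_ivp

        rhs = assemble_rhs(Scenario.from_name("control", geom), params, geom, stim)
        y0 = initial_state(params, geom, stim)
        h = 1e-4
        fwd = solve_ivp(rhs, (5.0, 5.0 + h), y0, rtol=1e-10, atol=1e-12)
        bwd = solve_ivp(rhs, (5.0, 5.0 - h), y0, rtol=1e-10, atol=1e-12)
        fd = (fwd.y[:, -1] - bwd.y[:, -1]) / (2 * h)
        f = rhs(5.0, y0)
        scale = np.maximum(np.abs(f), 1e-6)
        assert np.all(np.abs(fd - f) / scale < 1e-3)


class TestSimulate:
    def test_deterministic_repeat(self, geom, params, stim, ga_traces):
        again = rw.simulate("GA_treated", params, geom, stim)
        assert np.array_equal(again.ca, ga_traces.ca)
        assert np.array_equal(again.time, ga_traces.time)

    def test_grid_and_shape(self, ga_traces, geom):
        assert ga_traces.time[0] == 0.0
        assert ga_traces.time[-1] == pytest.approx(90.0)
        assert np.allclose(np.diff(ga_traces.time), 0.1)
        assert ga_traces.ca.shape == (901, geom.n_layers)
        assert ga_traces.units == "uM"

    def test_short_horizon_smoke(self, geom, params, stim):
        ts = rw.simulate("GA_treated", params, geom, stim, t_end=0.1)
        assert ts.ca.shape[0] == 2
        assert np.isfinite(ts.ca).all()

    def test_uncoupled_layers_are_independent(self, geom, params, stim):
        # no drivers, no gap junctions: one ring's trajectory is unaffected
        # by arbitrary changes to the others
        quiet = stim.scaled(theta_scale=0.0, ligand_scale=0.0)
        full = rw.simulate("GA_treated", params, geom, quiet, t_end=10.0)
        single = rw.simulate("GA_treated", params, geom, quiet, t_end=10.0,
                             layer_subset=[7])
        assert np.allclose(full.layer(7), single.layer(7), rtol=1e-6, atol=1e-9)

    def test_layer_subset_requires_uncoupled(self, geom, params, stim):
        with pytest.raises(ValueError):
            rw.simulate("control", params, geom, stim, layer_subset=[1])

    def test_counts_stay_within_pools(self, control_traces, params):
        s = control_traces.states
        R_S, R_Sp, G, PIP2, Ca = s[:, 2], s[:, 3], s[:, 4], s[:, 6], s[:, 7]
        assert np.all(R_S >= 0) and np.all(R_Sp >= 0)
        assert np.all(R_S + R_Sp <= params.R_T * (1 + 1e-9))
        assert np.all(G <= params.G_T) and np.all(G >= 0)
        assert np.all(PIP2 <= params.PIP2_T * (1 + 1e-9)) and np.all(PIP2 >= 0)
        assert np.all(Ca > 0)

    def test_invalid_t_end(self, geom, params, stim):
        with pytest.raises(ValueError):
            rw.simulate("GA_treated", params, geom, stim, t_end=0.0)


class TestNormalizedFluorescence:
    def test_baseline_maps_to_one(self, ga_traces):
        nf = rw.to_normalized_fluorescence(ga_traces)
        assert nf.units == "NF"
        assert np.allclose(nf.ca[0], ga_traces.ca[0] / 0.12)
        assert nf.ca[0, -1] == pytest.approx(1.0, rel=1e-6)

    def test_round_trip_identity(self, ga_traces):
        back = rw.to_micromolar(rw.to_normalized_fluorescence(ga_traces))
        assert np.allclose(back.ca, ga_traces.ca)
        assert back.units == "uM"

    def test_linearity_and_zero_baseline(self, ga_traces):
        nf = rw.to_normalized_fluorescence(ga_traces, baseline=0.06)
        assert np.allclose(nf.ca, ga_traces.ca / 0.06)
        with pytest.raises(ValueError):
            rw.to_normalized_fluorescence(ga_traces, baseline=0.0)
        with pytest.raises(ValueError):
            rw.to_normalized_fluorescence(nf)  # already NF
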