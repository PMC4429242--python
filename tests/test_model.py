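"""Core ODE model: steady state, simulation invariants, observables."""

import numpy as np
import pytest

from pigletbrain.model import (
    InputTrace,
    State,
    baseline_inputs,
    derivatives,
    observables,
    simulate,
    steady_state,
)
from pigletbrain.parameters import default_parameters


class TestInputTrace:
    def test_validation(self):
        t = np.array([0.0, 60.0, 120.0])
        ok = dict(sao2=[0.9] * 3, pa=[50.0] * 3, paco2=[40.0] * 3, occ=[0.0] * 3)
        InputTrace(t, **{k: np.array(v) for k, v in ok.items()})
        with pytest.raises(ValueError, match="increasing"):
            InputTrace(t[::-1], **{k: np.array(v) for k, v in ok.items()})
        bad = dict(ok, sao2=[1.5] * 3)
        with pytest.raises(ValueError, match="sao2"):
            InputTrace(t, **{k: np.array(v) for k, v in bad.items()})
        bad = dict(ok, pa=[-1.0] * 3)
        with pytest.raises(ValueError, match="pa"):
            InputTrace(t, **{k: np.array(v) for k, v in bad.items()})
        with pytest.raises(ValueError, match="length"):
            InputTrace(t, np.array([0.9, 0.9]), *(np.array(v) for v in
                       (ok["pa"], ok["paco2"], ok["occ"])))

    def test_interpolation(self):
        u = InputTrace.constant(100.0, sao2=0.5, pa=40.0)
        assert u.at(50.0) == (0.5, 40.0, 40.0, 0.0)


class TestSteadyState:
    def test_baseline_pins_named_parameters(self, p_default, baseline_state):
        ss = baseline_state
        assert ss.lac == pytest.approx(p_default.lac_n, rel=1e-6)
        assert ss.oxfrac == pytest.approx(p_default.oxfrac_n, rel=1e-6)
        assert ss.atp == pytest.approx(p_default.structural["atp_n"], rel=1e-6)
        assert 6.9 <= ss.ph <= 7.15
        assert ss.ph == pytest.approx(p_default.ph_m_n, abs=1e-6)

    def test_derivatives_vanish_at_steady_state(self, p_default, baseline_state):
        d = derivatives(baseline_state, p_default, baseline_inputs(p_default))
        scale = np.array([0.02, 0.02, 0.5, 1.0, 2.0, 1.0, 3.0, 1e-4])
        assert np.all(np.abs(d.to_array()) / scale < 1e-9)

    def test_perturbed_operating_point_converges(self, p_default):
        # lower pressure, mild hypoxia: still a valid fixed point
        ss = steady_state(p_default, (0.90, 45.0, 40.0, 0.0))
        d = derivatives(ss, p_default, (0.90, 45.0, 40.0, 0.0))
        assert np.all(np.isfinite(d.to_array()))
        assert ss.r > 0 and 0 < ss.oxfrac < 1


class TestDerivatives:
    def test_hypoxia_ischaemia_signs(self, p_default, baseline_state):
        """At the former steady state, occlusion with desaturation raises
        lactate production and drives CuA toward reduction."""
        u_hi = (0.30, p_default.pa_n, 40.0, 1.0)
        d = derivatives(baseline_state, p_default, u_hi)
        assert d.lac > 0
        assert d.oxfrac < 0

    def test_desaturation_alone_reduces_cua(self, p_default, baseline_state):
        u = (0.30, p_default.pa_n, 40.0, 0.0)
        d = derivatives(baseline_state, p_default, u)
        assert d.oxfrac < 0

    def test_nonfinite_inputs_named(self, p_default, baseline_state):
        with pytest.raises(ValueError, match="pa"):
            derivatives(baseline_state, p_default,
                        (0.9, float("nan"), 40.0, 0.0))
        bad = State(*np.r_[baseline_state.to_array()[:7], np.inf])
        with pytest.raises(ValueError, match="hconc"):
            derivatives(bad, p_default, baseline_inputs(p_default))


class TestSimulate:
    def test_fixed_point_invariance(self, p_default, constant_inputs):
        """Two hours of constant baseline inputs leave every concentration
        change at zero."""
        res = simulate(p_default, constant_inputs)
        for key in ("dHbO2_mM", "dHHb_mM", "doxCCO_mM"):
            assert np.abs(res.observables[key]).max() < 1e-6
        assert np.abs(res.observables["cbf_pct"] - 100).max() < 1e-3
        assert np.abs(res.observables["ntp_frac"] - 1).max() < 1e-6

    def test_pool_conservation(self, hi_run_default, p_default):
        s = p_default.structural
        states = hi_run_default.states
        # adenine and creatine pools are built in algebraically; the
        # phosphate chain (ATP+PCr+Pi) is conserved only up to solver error
        total_p = states[:, 3] + states[:, 4] + states[:, 5]
        assert np.abs(total_p - total_p[0]).max() < 1e-5 * total_p[0]
        assert states[:, 3].max() <= s["adn_tot"] + 1e-9
        assert states[:, 4].max() <= s["cr_tot"] + 1e-9

    def test_hi_response_signs(self, hi_run_default, hi_protocol):
        """During the insult pH falls and lactate rises; both recover."""
        u, pb = hi_protocol
        o = hi_run_default.observables
        occ = (u.t >= pb.edges[1]) & (u.t < pb.edges[3])
        post = u.t >= pb.edges[4]
        assert o["pH"][occ].min() < o["pH"][0] - 0.05
        lac = hi_run_default.state("lac")
        assert lac[occ].max() > lac[0] * 1.5
        assert o["pH"][post][-1] > o["pH"][occ].min() + 0.05

    def test_monotone_occlusion_response(self, p_default):
        """CBF is non-increasing in the occlusion fraction."""
        prev = None
        for occ in (0.0, 0.25, 0.5, 0.75, 1.0):
            u = InputTrace.constant(1200.0, pa=p_default.pa_n, occ=occ, n=21)
            res = simulate(p_default, u,
                           y0=steady_state(p_default, (0.96, p_default.pa_n,
                                                       40.0, 0.0)))
            cbf = res.observables["cbf"][-1]
            if prev is not None:
                assert cbf <= prev + 1e-9
            prev = cbf

    def test_autoregulation_damps_pressure_response(self, p_default):
        """With intact autoregulation a pressure step moves steady CBF
        strictly less than with autoregulation absent."""
        for step in (1.2, 0.8):
            changes = {}
            for k_aut in (1.0, 0.0):
                p = p_default.replace(k_aut=k_aut)
                base = steady_state(p, (0.96, p.pa_n, 40.0, 0.0))
                u = InputTrace.constant(3600.0, pa=step * p.pa_n, n=61)
                res = simulate(p, u, y0=base)
                changes[k_aut] = abs(res.observables["cbf_pct"][-1] - 100.0)
            assert changes[1.0] < changes[0.0]

    def test_doxcco_scales_linearly_with_cco_tot(self, p_default, hi_protocol):
        """The oxCCO signal amplitude is proportional to the CCO pool for a
        fixed redox trajectory."""
        u, _ = hi_protocol
        amps = []
        for f in (0.5, 1.0, 2.0):
            p = p_default.replace(cco_tot=f * p_default.cco_tot)
            res = simulate(p, u)
            amps.append(np.abs(res.observables["doxCCO_mM"]).max())
        assert amps[1] == pytest.approx(2 * amps[0], rel=1e-6)
        assert amps[2] == pytest.approx(4 * amps[0], rel=1e-6)

    def test_grid_refinement(self, p_default, hi_protocol):
        """Halving solver tolerances moves observable extrema < 0.5 %."""
        u, _ = hi_protocol
        coarse = simulate(p_default, u, rtol=1e-7, atol=1e-9)
        fine = simulate(p_default, u, rtol=5e-8, atol=5e-10)
        for key in ("dHbO2_mM", "dHHb_mM", "doxCCO_mM", "cbf_pct", "ntp_frac"):
            a = np.abs(coarse.observables[key] - coarse.observables[key][0]).max()
            b = np.abs(fine.observables[key] - fine.observables[key][0]).max()
            assert a == pytest.approx(b, rel=5e-3)


class TestObservables:
    def test_baseline_trajectory_gives_zero_changes(self, p_default,
                                                    baseline_state):
        states = np.tile(baseline_state.to_array(), (5, 1))
        obs = observables(states, p_default, baseline_state)
        for key in ("dHbO2_mM", "dHHb_mM", "doxCCO_mM"):
            assert np.allclose(obs[key], 0.0, atol=1e-15)
        assert np.allclose(obs["ntp_frac"], 1.0)

    def test_doxcco_arithmetic(self, p_default, baseline_state):
        p = p_default.replace(cco_tot=0.007)
        shifted = baseline_state.to_array().copy()
        shifted[2] -= 0.1
        obs = observables(np.vstack([baseline_state.to_array(), shifted]),
                          p, baseline_state)
        assert obs["doxCCO_mM"][1] == pytest.approx(-0.0007, rel=1e-12)

    def test_ntp_fraction_halves_with_atp(self, p_default, baseline_state):
        shifted = baseline_state.to_array().copy()
        shifted[3] *= 0.5
        obs = observables(shifted[None, :], p_default, baseline_state)
        assert obs["ntp_frac"][0] == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self, p_default, baseline_state):
        with pytest.raises(ValueError):
            observables(np.zeros((3, 5)), p_default, baseline_state)
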