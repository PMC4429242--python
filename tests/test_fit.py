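"""Objective function, swarm fitting surface and reporting."""

import numpy as np
import pytest

from pigletbrain.fit import (
    FAILURE_PENALTY,
    ObjectiveSpec,
    PigletHIModel,
    fit_report,
    objective_cost,
    pswarm_fit,
)
from pigletbrain.model import simulate
from pigletbrain.parameters import default_bounds, default_parameters
from pigletbrain.pso import SwarmConfig


@pytest.fixture(scope="module")
def self_fit_setup(hi_protocol):
    """Observed traces generated by the model at a known parameter point."""
    u, _ = hi_protocol
    truth = default_parameters().replace(glu_rate_n=0.00352)
    res = simulate(truth, u, rtol=1e-6, atol=1e-8)
    observed = {
        "dHbO2": res.observables["dHbO2_mM"],
        "dHHb": res.observables["dHHb_mM"],
        "doxCCO": res.observables["doxCCO_mM"],
        "pH": res.observables["pH"],
    }
    return u, truth, observed


class TestObjective:
    def test_zero_cost_at_generating_point(self, self_fit_setup):
        u, truth, observed = self_fit_setup
        spec = ObjectiveSpec(
            observed=observed, protocol=u, param_names=("glu_rate_n",),
            bounds=default_bounds(), base=default_parameters(),
        )
        assert objective_cost([truth.glu_rate_n], spec) == pytest.approx(
            0.0, abs=1e-20)

    def test_constant_offset_equals_weight_scaled_ratio(self, self_fit_setup):
        """sim - obs constant = c: cost = w * (c / SD(obs))^2 exactly."""
        u, truth, observed = self_fit_setup
        c = 0.01
        shifted = {"dHbO2": observed["dHbO2"] - c}
        spec = ObjectiveSpec(
            observed=shifted, protocol=u, param_names=("glu_rate_n",),
            bounds=default_bounds(), base=default_parameters(),
            weights={"dHbO2": 2.5},
        )
        sd = np.std(shifted["dHbO2"])
        expected = 2.5 * (c / sd) ** 2
        assert objective_cost([truth.glu_rate_n], spec) == pytest.approx(
            expected, rel=1e-6)

    def test_simulation_failure_returns_penalty_not_exception(self,
                                                              self_fit_setup):
        u, _, observed = self_fit_setup
        # r_m above the active-tension peak radius makes the model invalid
        spec = ObjectiveSpec(
            observed=observed, protocol=u, param_names=("r_m",),
            bounds={"r_m": (0.001, 0.05)}, base=default_parameters(),
        )
        assert objective_cost([0.03], spec) == FAILURE_PENALTY

    def test_ridge_disabled_by_default(self, self_fit_setup):
        u, truth, observed = self_fit_setup
        spec = ObjectiveSpec(
            observed=observed, protocol=u, param_names=("glu_rate_n",),
            bounds=default_bounds(), base=default_parameters(),
        )
        assert spec.ridge == 0.0

    def test_spec_validation(self, self_fit_setup):
        u, _, observed = self_fit_setup
        with pytest.raises(ValueError, match="non-empty"):
            ObjectiveSpec(observed=observed, protocol=u, param_names=(),
                          bounds={})
        with pytest.raises(ValueError, match="grid"):
            ObjectiveSpec(observed={"pH": np.zeros(3)}, protocol=u,
                          param_names=("lac_n",), bounds=default_bounds())
        with pytest.raises(ValueError, match="weight"):
            ObjectiveSpec(observed=observed, protocol=u,
                          param_names=("lac_n",), bounds=default_bounds(),
                          weights={"pH": -1.0})


class TestPswarmFit:
    def test_one_parameter_self_fit_recovers_truth(self, self_fit_setup):
        u, truth, observed = self_fit_setup
        spec = ObjectiveSpec(
            observed=observed, protocol=u, param_names=("glu_rate_n",),
            bounds=default_bounds(), base=default_parameters(),
        )
        res = pswarm_fit(spec, SwarmConfig(n_particles=8, iterations=25,
                                           seed=0), refine=True)
        assert res.values[0] == pytest.approx(truth.glu_rate_n, rel=0.05)
        assert res.cost <= res.cost_trace[0]
        assert np.all(np.diff(res.cost_trace) <= 1e-15)

    def test_fit_reproducible(self, self_fit_setup):
        u, _, observed = self_fit_setup
        spec = ObjectiveSpec(
            observed=observed, protocol=u, param_names=("glu_rate_n",),
            bounds=default_bounds(), base=default_parameters(),
        )
        cfg = SwarmConfig(n_particles=6, iterations=8, seed=3)
        r1 = pswarm_fit(spec, cfg)
        r2 = pswarm_fit(spec, cfg)
        assert np.array_equal(r1.values, r2.values)
        assert r1.cost == r2.cost


class TestReporting:
    def test_fit_report_percent_changes(self):
        from pigletbrain.fit import OptimisationResult

        res = OptimisationResult(
            param_names=("glu_rate_n", "lac_n"),
            values=np.array([0.00352, 3.00]),
            cost=0.0, cost_trace=np.array([0.0]), n_evaluations=1, seed=0,
            converged=True, message="",
        )
        rep = fit_report(res).set_index("parameter")
        assert rep.loc["glu_rate_n", "percent_change"] == pytest.approx(-20.0)
        assert rep.loc["lac_n", "percent_change"] == pytest.approx(0.0)

    def test_bound_hit_flag(self):
        from pigletbrain.fit import OptimisationResult

        bounds = default_bounds()
        res = OptimisationResult(
            param_names=("glu_rate_n",),
            values=np.array([bounds["glu_rate_n"][0]]),
            cost=0.0, cost_trace=np.array([0.0]), n_evaluations=1, seed=0,
            converged=True, message="",
        )
        assert bool(fit_report(res)["at_bound"][0])

    def test_model_results_surface(self, self_fit_setup):
        u, truth, observed = self_fit_setup
        model = PigletHIModel(observed, u, param_names=("glu_rate_n",))
        results = model.fit(seed=0, n_particles=6, iterations=10)
        assert "glu_rate_n" in results.params.index
        text = results.summary()
        assert "glu_rate_n" in text and "best cost" in text
        pct = results.percent_change()
        assert pct.index.tolist() == ["glu_rate_n"]
        sim = results.simulate()
        assert sim.t.shape == u.t.shape

    def test_from_dataframe_roundtrip(self, self_fit_setup):
        import pandas as pd

        u, _, observed = self_fit_setup
        frame = pd.DataFrame({"time_s": u.t,
                              **{k: v for k, v in observed.items()}})
        model = PigletHIModel.from_dataframe(frame, u,
                                             param_names=("lac_n",))
        assert set(model.spec.observed) == {"dHbO2", "dHHb", "doxCCO", "pH"}
        with pytest.raises(KeyError):
            PigletHIModel.from_dataframe(frame.drop(columns=["pH"]), u)
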