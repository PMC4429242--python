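"""Morris elementary-effects screening: design, effects, oracles."""

import numpy as np
import pytest

from pigletbrain.morris import (
    elementary_effects,
    morris_design,
    rms_deviation_summaries,
    screen_model,
)

BOUNDS3 = {"a": (0.0, 1.0), "b": (-2.0, 2.0), "c": (10.0, 20.0)}


class TestDesign:
    def test_row_count_and_single_coordinate_steps(self):
        d = morris_design(BOUNDS3, R=4, L=4, seed=0)
        assert d.unit_samples.shape == (4 * (3 + 1), 3)
        for r in range(4):
            traj = d.trajectory(r)
            for step in range(3):
                dx = traj[step + 1] - traj[step]
                assert np.sum(np.abs(dx) > 1e-12) == 1
                assert np.abs(dx).max() == pytest.approx(d.delta)
        assert d.unit_samples.min() >= 0.0 and d.unit_samples.max() <= 1.0

    def test_each_parameter_perturbed_once_per_trajectory(self):
        d = morris_design(BOUNDS3, R=6, L=4, seed=1)
        for r in range(6):
            traj = d.trajectory(r)
            moved = [int(np.argmax(np.abs(traj[s + 1] - traj[s])))
                     for s in range(3)]
            assert sorted(moved) == [0, 1, 2]

    def test_determinism_and_seed_sensitivity(self):
        d1 = morris_design(BOUNDS3, R=5, L=4, seed=42)
        d2 = morris_design(BOUNDS3, R=5, L=4, seed=42)
        d3 = morris_design(BOUNDS3, R=5, L=4, seed=43)
        assert np.array_equal(d1.unit_samples, d2.unit_samples)
        assert not np.array_equal(d1.unit_samples, d3.unit_samples)

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            morris_design(BOUNDS3, R=2)
        with pytest.raises(ValueError):
            morris_design(BOUNDS3, R=4, L=5)
        with pytest.raises(ValueError):
            morris_design({"a": (0.0, float("inf"))}, R=4)


class TestElementaryEffects:
    def test_linear_function_exact(self):
        """y = sum a_i x_i: every elementary effect equals a_i exactly."""
        coeffs = np.array([3.0, -1.5, 0.25])
        d = morris_design({f"p{i}": (0.0, 1.0) for i in range(3)}, R=6, L=4,
                          seed=2)
        y = d.unit_samples @ coeffs
        res = elementary_effects(d, y)
        assert np.allclose(res.mu_star["y"], np.abs(coeffs), atol=1e-12)
        assert np.allclose(res.mu["y"], coeffs, atol=1e-12)
        assert np.allclose(res.sigma["y"], 0.0, atol=1e-12)
        assert list(res.rank["y"]) == [1, 2, 3]

    def test_quadratic_matches_bruteforce_oracle(self):
        """y = x0^2: mu/mu*/sigma agree with a naive two-loop recomputation
        over the same design to 1e-12."""
        d = morris_design({"x0": (0.0, 1.0), "x1": (0.0, 1.0)}, R=8, L=4,
                          seed=3)
        y = d.unit_samples[:, 0] ** 2
        res = elementary_effects(d, y)

        # independent oracle: walk every trajectory, divide by signed step
        effects = {0: [], 1: []}
        k = 2
        for r in range(8):
            block = d.unit_samples[r * (k + 1): (r + 1) * (k + 1)]
            yb = y[r * (k + 1): (r + 1) * (k + 1)]
            for s in range(k):
                dx = block[s + 1] - block[s]
                i = int(np.argmax(np.abs(dx)))
                effects[i].append((yb[s + 1] - yb[s]) / dx[i])
        for i in range(2):
            assert res.mu["y"][i] == pytest.approx(np.mean(effects[i]),
                                                   abs=1e-12)
            assert res.mu_star["y"][i] == pytest.approx(
                np.mean(np.abs(effects[i])), abs=1e-12)
            assert res.sigma["y"][i] == pytest.approx(
                np.std(effects[i], ddof=1), abs=1e-12)
        # analytically EE for x0 is 2x + delta at the lower sample
        assert res.mu_star["y"][1] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_ranks(self):
        d = morris_design(BOUNDS3, R=6, L=4, seed=4)
        rng = np.random.default_rng(0)
        y = rng.normal(size=d.unit_samples.shape[0])
        r1 = elementary_effects(d, {"out": y})
        r2 = elementary_effects(d, {"out": 137.0 * y})
        assert np.array_equal(r1.rank["out"], r2.rank["out"])

    def test_zero_width_bounds_give_zero_effect_and_last_rank(self):
        bounds = {"a": (0.0, 1.0), "z": (5.0, 5.0)}
        d = morris_design(bounds, R=4, L=4, seed=5)
        y = d.native_samples().sum(axis=1)
        res = elementary_effects(d, y)
        # native value of z never changes, so its effect on y is zero
        assert res.mu_star["y"][1] == pytest.approx(0.0, abs=1e-12)
        assert res.rank["y"][1] == 2

    def test_failed_trajectories_dropped_with_warning(self):
        d = morris_design({"a": (0.0, 1.0)}, R=6, L=4, seed=6)
        y = d.unit_samples[:, 0].astype(float)
        y[0] = np.nan  # poisons trajectory 0
        with pytest.warns(UserWarning, match="dropped 1/6"):
            res = elementary_effects(d, y)
        assert res.mu_star["y"][0] == pytest.approx(1.0)
        y[:] = np.nan
        with pytest.raises(RuntimeError):
            with pytest.warns(UserWarning):
                elementary_effects(d, y)


class TestScreenModel:
    def test_small_screen_runs_and_ranks_are_permutations(self, hi_protocol):
        u, _ = hi_protocol
        res = screen_model(protocol=u, R=4, seed=0)
        for out in ("dHbO2", "dHHb", "doxCCO", "pH"):
            assert sorted(res.rank[out]) == list(range(1, 11))

    def test_screen_determinism(self, hi_protocol):
        u, _ = hi_protocol
        r1 = screen_model(protocol=u, R=4, seed=9,
                          p_names=("cco_tot", "hbtot_n"))
        r2 = screen_model(protocol=u, R=4, seed=9,
                          p_names=("cco_tot", "hbtot_n"))
        for out in r1.outputs:
            assert np.array_equal(r1.mu_star[out], r2.mu_star[out])

    def test_summary_is_rms_deviation_from_baseline(self, p_default,
                                                    hi_protocol):
        u, _ = hi_protocol
        s = rms_deviation_summaries(p_default, u)
        from pigletbrain.model import simulate

        res = simulate(p_default, u, rtol=1e-6, atol=1e-8)
        tr = res.observables["doxCCO_mM"]
        assert s["doxCCO"] == pytest.approx(
            float(np.sqrt(np.mean((tr - tr[0]) ** 2))), rel=1e-9)

    def test_unknown_parameter_rejected(self, hi_protocol):
        u, _ = hi_protocol
        with pytest.raises(KeyError):
            screen_model(p_names=("nonsense",), protocol=u, R=4, seed=0)
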