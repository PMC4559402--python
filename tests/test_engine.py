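"""Initialisation, settle phase, stepping and run-level contracts."""

import numpy as np
import pytest

import huddlesim as hs
from huddlesim import engine
from huddlesim.behaviour import Variant

from conftest import make_config


class TestInitialisation:
    def test_pups_start_within_one_radius_of_centre(self):
        cfg = hs.SimConfig()
        litter = engine.initialize_litter(cfg, np.random.default_rng(3))
        assert np.all(np.linalg.norm(litter.positions, axis=1) <= cfg.pup_radius)

    def test_same_seed_identical_initial_state(self):
        cfg = hs.SimConfig()
        a = engine.initialize_litter(cfg, np.random.default_rng(9))
        b = engine.initialize_litter(cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.headings, b.headings)

    def test_uniform_disc_second_moment(self):
        # E|x|^2 = r^2/2 for a uniform disc
        cfg = hs.SimConfig(n_pups=4000)
        litter = engine.initialize_litter(cfg, np.random.default_rng(0))
        m2 = (np.linalg.norm(litter.positions, axis=1) ** 2).mean()
        assert m2 == pytest.approx(0.5, abs=0.02)

    def test_endothermic_starts_clamped(self):
        cfg = hs.SimConfig(variant="endothermic")
        litter = engine.initialize_litter(cfg, np.random.default_rng(0))
        assert np.all(litter.body_temperatures == 37.0)


class TestSettle:
    def test_positions_and_headings_frozen(self):
        cfg = make_config("ectothermic", 20.0)
        litter = engine.initialize_litter(cfg, np.random.default_rng(1))
        before = (litter.positions.copy(), litter.headings.copy())
        engine.settle(litter, cfg)
        np.testing.assert_array_equal(litter.positions, before[0])
        np.testing.assert_array_equal(litter.headings, before[1])

    def test_endothermic_settle_is_noop(self):
        cfg = make_config("endothermic", 20.0)
        litter = engine.initialize_litter(cfg, np.random.default_rng(1))
        engine.settle(litter, cfg)
        assert np.all(litter.body_temperatures == 37.0)

    def test_settle_follows_euler_trajectory_for_isolated_pup(self):
        cfg = make_config("ectothermic", 20.0)
        cfg = cfg.replace(n_pups=1, settle_steps=100)
        litter = engine.initialize_litter(cfg, np.random.default_rng(1))
        engine.settle(litter, cfg)
        # closed-form solution of dTb/dt = -k1(Tb - Ta) + G over 5 time units
        p = cfg.thermal
        target = 20.0 + p.thermogenesis / p.k1
        exact = (30.0 - target) * np.exp(-p.k1 * 100 * p.dt) + target
        assert litter.body_temperatures[0] == pytest.approx(exact, rel=0.01)


class TestStepAndRun:
    def test_single_pup_moves_straight_at_constant_speed(self):
        cfg = make_config("endothermic", 20.0, steps=50).replace(n_pups=1)
        res = hs.run_simulation(cfg, seed=4)
        tr = res.trajectory
        assert np.ptp(tr.heading[:, 0]) == 0.0
        step_len = np.hypot(np.diff(tr.x[:, 0]), np.diff(tr.y[:, 0]))
        np.testing.assert_allclose(step_len, cfg.kinematic.v2 * cfg.thermal.dt, atol=1e-12)

    def test_bitwise_determinism_under_fixed_seed(self):
        cfg = make_config("homeothermotaxic", 15.0, steps=120)
        a = hs.run_simulation(cfg, seed=11).trajectory
        b = hs.run_simulation(cfg, seed=11).trajectory
        for name in ("x", "y", "heading", "body_temperature", "eta"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self):
        cfg = make_config("homeothermotaxic", 15.0, steps=120)
        a = hs.run_simulation(cfg, seed=11).trajectory
        b = hs.run_simulation(cfg, seed=12).trajectory
        assert not np.array_equal(a.x, b.x)

    def test_zero_steps_yields_empty_trajectory_and_settled_state(self):
        cfg = make_config("ectothermic", 20.0, steps=0)
        res = hs.run_simulation(cfg, seed=2)
        assert res.trajectory.n_steps == 0
        assert res.final_state.n_pups == cfg.n_pups
        assert np.all(np.linalg.norm(res.final_state.positions, axis=1) <= 1.0)

    def test_pups_stay_inside_arena(self):
        cfg = make_config("endothermic", 45.0, steps=1500)
        tr = hs.run_simulation(cfg, seed=5).trajectory
        assert np.all(np.hypot(tr.x, tr.y) <= cfg.arena_radius)

    def test_contacting_endothermic_pair_turns_toward_each_other_when_cold(self):
        cfg = make_config("endothermic", 20.0).replace(n_pups=2)
        litter = hs.LitterState(
            positions=np.array([[-0.75, 0.0], [0.75, 0.0]]),
            headings=np.array([np.pi / 2, np.pi / 2]),
            body_temperatures=np.array([37.0, 37.0]),
        )
        engine.step(litter, cfg, np.random.default_rng(0))
        # left pup turns clockwise (toward +x), right pup counterclockwise
        assert litter.headings[0] < np.pi / 2 < litter.headings[1]

    def test_nonfinite_state_aborts_with_diagnostic(self):
        cfg = make_config("ectothermic", 20.0, steps=200)
        cfg.thermal.dt = 80.0  # wildly unstable Euler step
        with np.errstate(over="ignore"), pytest.raises(RuntimeError, match="non-finite"):
            hs.run_simulation(cfg, seed=0)


class TestSweep:
    def test_cardinality_and_reproducibility(self):
        cfg = make_config("endothermic", 20.0, steps=60, n_thermometers=64)
        table = engine.run_sweep(cfg, "ambient", [10.0, 40.0], replicates=2, base_seed=7)
        assert len(table) == 4
        assert table["seed"].nunique() == 4
        again = engine.run_sweep(cfg, "ambient", [10.0, 40.0], replicates=2, base_seed=7)
        assert table.equals(again)

    def test_invalid_parameter_rejected(self):
        cfg = make_config("endothermic", 20.0, steps=10)
        with pytest.raises(ValueError, match="sweep parameter"):
            engine.run_sweep(cfg, "v2", [0.1], replicates=1)

    def test_boundary_toggle_matched_seeds_small_difference(self):
        # removing the arena wall barely changes huddling at cold ambient
        base = make_config("homeothermotaxic", 5.0, steps=1500)
        on = hs.run_simulation(base, seed=3).summary.huddling
        off = hs.run_simulation(base.replace(boundary_enabled=False), seed=3).summary.huddling
        assert abs(on - off) < 0.05


class TestSweepSummary:
    def test_mean_and_se_per_value(self):
        cfg = make_config("endothermic", 20.0, steps=40, n_thermometers=64)
        table = engine.run_sweep(cfg, "ambient", [15.0, 40.0], replicates=3, base_seed=1)
        agg = engine.summarize_sweep(table)
        assert len(agg) == 2
        assert set(["huddling_mean", "huddling_se", "replicates"]) <= set(agg.columns)
        expected = table[table["value"] == 15.0]["huddling"].mean()
        assert agg.loc[agg["value"] == 15.0, "huddling_mean"].iloc[0] == pytest.approx(expected)


class TestContactScaling:
    @pytest.mark.parametrize(
        "ambient,expect_huddle",
        [(16.0, True), (21.0, False)],
        ids=["below_scaled_critical", "above_scaled_critical"],
    )
    def test_endothermic_transition_shifts_to_scaled_clamp(self, ambient, expect_huddle):
        # s = 0.5 makes contacts register 18.5 degC, so the attraction/
        # avoidance switch moves from 37 to s*37 = 18.5 degC
        cfg = make_config("endothermic", ambient, steps=3000)
        cfg.thermal.contact_scaling = 0.5
        h = hs.run_simulation(cfg, seed=6).summary.huddling
        assert (h > 0.25) if expect_huddle else (h < 0.1)
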