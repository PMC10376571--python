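"""MPC solver against a brute-force dense QP oracle, soft-constraint
behaviour, reference blending and closed-loop tracking properties."""

import numpy as np
import pytest
from scipy.optimize import minimize

from emgexo import mpc, plant
from emgexo.mpc import MpcConfig, ReferenceBundle
from emgexo.plant import PlantConfig


def oracle_qp_solve(config: MpcConfig, plant_config: PlantConfig, x0, r_v, u_prev=0.0):
    """Independent dense solve: simulate the model move by move and
    minimize the exact cost with scipy (horizons <= 5 only)."""
    a, b, _ = plant.linearized_model(plant_config)
    hp, hc = config.prediction_horizon, config.control_horizon
    lb, ub = config.c_mo
    rho = config.effective_slack_penalty if config.soft_constraints else 1e10

    def predict(u_moves):
        x = np.array(x0, dtype=float)
        vs = []
        for k in range(hp):
            u = u_moves[min(k, hc - 1)]
            x = a @ x + b[:, 0] * u
            vs.append(x[1])
        return np.array(vs)

    def cost(u_moves):
        v = predict(u_moves)
        j = config.w_mo * np.sum((v - r_v) ** 2)
        j += config.u_reg * np.sum(u_moves**2)
        du = np.diff(np.r_[u_prev, u_moves])
        j += config.w_mv * np.sum(du**2)
        viol = np.maximum(v - ub, 0.0) + np.maximum(lb - v, 0.0)
        j += rho * np.sum(viol**2)
        return j

    res = minimize(cost, np.zeros(hc), method="BFGS", tol=1e-14)
    return res.x


class TestSolverAgainstOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_oracle_small_horizons(self, seed):
        """Hc = Hp <= 5, random states/references -> agreement to 1e-6."""
        rng = np.random.default_rng(seed)
        hp = int(rng.integers(2, 6))
        cfg = MpcConfig(prediction_horizon=hp, control_horizon=hp, u_reg=1e-6)
        pcfg = PlantConfig()
        solver = mpc.LinearMpc(cfg, pcfg)
        x0 = np.array([rng.normal() * 1e-3, rng.normal() * 3e-3])
        r_v = rng.uniform(-6e-3, 6e-3, size=hp)
        u = solver.solve(x0, r_v)
        u_oracle = oracle_qp_solve(cfg, pcfg, x0, r_v)
        np.testing.assert_allclose(u, u_oracle, atol=1e-6)

    @pytest.mark.parametrize("seed", range(8, 14))
    def test_matches_oracle_with_active_soft_constraints(self, seed):
        """References beyond the +/-7 mm/s band engage the slack penalty."""
        rng = np.random.default_rng(seed)
        hp = int(rng.integers(2, 6))
        cfg = MpcConfig(
            prediction_horizon=hp, control_horizon=hp, u_reg=1e-6, slack_penalty=0.5
        )
        pcfg = PlantConfig()
        solver = mpc.LinearMpc(cfg, pcfg)
        x0 = np.array([0.0, rng.uniform(-5e-3, 5e-3)])
        r_v = rng.uniform(8e-3, 12e-3, size=hp)  # beyond the soft bound
        u = solver.solve(x0, r_v)
        u_oracle = oracle_qp_solve(cfg, pcfg, x0, r_v)
        np.testing.assert_allclose(u, u_oracle, atol=1e-6)

    def test_matches_oracle_hc_smaller_than_hp(self):
        cfg = MpcConfig(prediction_horizon=5, control_horizon=2, u_reg=1e-6)
        pcfg = PlantConfig()
        solver = mpc.LinearMpc(cfg, pcfg)
        x0 = np.array([0.0, 1e-3])
        r_v = np.full(5, 4e-3)
        np.testing.assert_allclose(
            solver.solve(x0, r_v), oracle_qp_solve(cfg, pcfg, x0, r_v), atol=1e-6
        )

    def test_move_penalty_uses_previous_input(self):
        cfg = MpcConfig(prediction_horizon=4, control_horizon=4, w_mv=0.05, u_reg=1e-6)
        pcfg = PlantConfig()
        solver = mpc.LinearMpc(cfg, pcfg)
        x0 = np.array([0.0, 0.0])
        r_v = np.full(4, 3e-3)
        u_prev = 5e-3
        np.testing.assert_allclose(
            solver.solve(x0, r_v, u_prev=u_prev),
            oracle_qp_solve(cfg, pcfg, x0, r_v, u_prev=u_prev),
            atol=1e-6,
        )


class TestSolveStep:
    def test_constant_reference_converges(self):
        """3 mm/s reference, ideal plant: command settles at 3 mm/s."""
        cfg = MpcConfig()
        pcfg = PlantConfig(tau=0.0)
        state = plant.PlantState()
        cmds = []
        for _ in range(200):
            u = mpc.solve_step(state, np.full(20, 3.0), cfg, pcfg)
            state = plant.step(state, u, pcfg)
            cmds.append(u)
        assert cmds[-1] == pytest.approx(3.0, abs=1e-6)
        assert state.velocity == pytest.approx(3.0, abs=1e-6)
        # monotone approach after the initial transient
        errs = np.abs(np.array(cmds[5:]) - 3.0)
        assert np.all(np.diff(errs) <= 1e-12)

    def test_short_reference_holds_last_value(self):
        cfg = MpcConfig()
        u_short = mpc.solve_step(plant.PlantState(), np.array([3.0]), cfg)
        u_full = mpc.solve_step(plant.PlantState(), np.full(20, 3.0), cfg)
        assert u_short == pytest.approx(u_full, rel=1e-9)

    def test_nan_reference_rejected(self):
        with pytest.raises(mpc.MpcError, match="NaN"):
            mpc.solve_step(plant.PlantState(), np.array([1.0, np.nan]), MpcConfig())

    def test_soft_violation_shrinks_with_penalty(self):
        """9 mm/s reference against the 7 mm/s soft bound: the steady command
        exceeds the bound by a slack that shrinks as the penalty grows."""
        violations = []
        for rho in (0.1, 1.0, 10.0, 1000.0):
            cfg = MpcConfig(slack_penalty=rho)
            pcfg = PlantConfig(v_sat=50.0)  # plant must not mask the controller
            state = plant.PlantState()
            for _ in range(300):
                u = mpc.solve_step(state, np.full(20, 9.0), cfg, pcfg)
                state = plant.step(state, u, pcfg)
            violations.append(state.velocity - 7.0)
        assert all(v > 0 for v in violations[:2])  # soft: leaves the range
        assert all(b < a + 1e-12 for a, b in zip(violations, violations[1:]))
        assert violations[-1] < 0.05  # large penalty pins it near the bound

    def test_hard_constraints_keep_output_in_band(self):
        cfg = MpcConfig(soft_constraints=False)
        pcfg = PlantConfig(v_sat=50.0)
        state = plant.PlantState()
        for _ in range(300):
            u = mpc.solve_step(state, np.full(20, 9.0), cfg, pcfg)
            state = plant.step(state, u, pcfg)
        assert state.velocity <= 7.0 + 1e-6

    def test_invalid_horizons_rejected(self):
        with pytest.raises(ValueError, match="Hc"):
            MpcConfig(prediction_horizon=2, control_horizon=5)


class TestBlendReferences:
    def test_therapy_priority(self):
        therapy = np.linspace(0, 5, 100)
        emg = np.full(100, 2.0)
        refs = ReferenceBundle(ts=0.001, therapy_v=therapy, emg_v=emg, priority="therapy")
        np.testing.assert_array_equal(mpc.blend_references(refs), therapy)

    def test_emg_priority_on_active_interval(self):
        therapy = np.full(100, 3.0)
        emg = np.full(100, 5.0)
        active = np.zeros(100, dtype=bool)
        active[:50] = True
        refs = ReferenceBundle(
            ts=0.001, therapy_v=therapy, emg_v=emg, emg_active=active, priority="emg"
        )
        eff = mpc.blend_references(refs)
        np.testing.assert_array_equal(eff[:50], 5.0)
        np.testing.assert_array_equal(eff[50:], 3.0)

    def test_equal_weights_equal_refs(self):
        r = np.linspace(-2, 2, 50)
        refs = ReferenceBundle(ts=0.001, therapy_v=r, emg_v=r.copy(), priority=(0.5, 0.5))
        np.testing.assert_allclose(mpc.blend_references(refs), r)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ReferenceBundle(ts=0.001, therapy_v=np.zeros(10), emg_v=np.zeros(11))


class TestClosedLoop:
    def test_zero_reference_zero_everything(self):
        refs = ReferenceBundle(ts=0.001, therapy_v=np.zeros(500))
        log, metrics = mpc.run_closed_loop(PlantConfig(), MpcConfig(), refs)
        assert metrics["mse_velocity"] == 0.0
        assert metrics["mse_position"] == 0.0
        np.testing.assert_array_equal(log["cmd_v"], 0.0)

    def test_duration_shorter_than_step_rejected(self):
        refs = ReferenceBundle(ts=0.001, therapy_v=np.zeros(100))
        with pytest.raises(ValueError, match="duration"):
            mpc.run_closed_loop(PlantConfig(), MpcConfig(), refs, duration_s=1e-5)

    def test_emg_priority_tracks_emg_not_therapy(self):
        """With EMG priority active on the first interval, the loop follows
        the assistance velocity there and the therapy reference afterwards."""
        n = 4000
        therapy = np.full(n, 3.0)
        emg = np.full(n, 5.0)
        active = np.zeros(n, dtype=bool)
        active[: n // 2] = True
        refs = ReferenceBundle(
            ts=0.001, therapy_v=therapy, emg_v=emg, emg_active=active, priority="emg"
        )
        log, _ = mpc.run_closed_loop(PlantConfig(), MpcConfig(), refs)
        v = log["v"].to_numpy()
        assert np.allclose(v[1000 : n // 2 - 100], 5.0, atol=0.05)
        assert np.allclose(v[n // 2 + 1000 :], 3.0, atol=0.05)

    def test_velocity_mse_decreases_with_w_mo(self):
        """Raising the output weight from ~0 improves velocity tracking."""
        ref = mpc.ramp_reference(5.0, cycles=1)
        mses = []
        for w in (1e-4, 1e-2, 0.135):
            refs = ReferenceBundle(ts=0.001, therapy_v=ref)
            # a non-negligible effort penalty makes the tradeoff visible
            cfg = MpcConfig(w_mo=w, u_reg=1e-4)
            _, metrics = mpc.run_closed_loop(PlantConfig(), cfg, refs)
            mses.append(metrics["mse_velocity"])
        assert mses[0] > mses[1] > mses[2]

    def test_speed_tracking_predominates_over_position(self):
        """Velocity is the weighted output: an initial position offset is
        never corrected, while the velocity reference is still tracked."""
        ref = mpc.ramp_reference(5.0, cycles=1)
        refs = ReferenceBundle(ts=0.001, therapy_v=ref)
        cfg = MpcConfig()
        pcfg = PlantConfig()
        solver = mpc.LinearMpc(cfg, pcfg)
        a, b, _ = plant.linearized_model(pcfg)
        x = np.array([2e-3, 0.0])  # 2 mm initial offset
        eff = ref * 1e-3
        eff_pad = np.r_[eff, np.full(20, eff[-1])]
        verr = []
        for k in range(len(eff)):
            u = solver.solve(x, eff_pad[k + 1 : k + 21])[0]
            x = a @ x + b[:, 0] * np.clip(u, -7e-3, 7e-3)
            verr.append(x[1] - eff[k])
        assert abs(x[0] - eff.sum() * 0.001 - 2e-3) < 1e-4  # offset persists
        assert np.sqrt(np.mean(np.square(verr))) < 1e-4  # velocity tracked

    def test_ramp_tracking_mse_small(self):
        """7 mm/s ramp over 2 cycles: velocity MSE far below 5e-8 (m/s)^2."""
        ref = mpc.ramp_reference(7.0, cycles=2)
        refs = ReferenceBundle(ts=0.001, therapy_v=ref)
        _, metrics = mpc.run_closed_loop(PlantConfig(), MpcConfig(), refs)
        assert metrics["mse_velocity"] <= 4.9636e-8
        assert metrics["mse_position"] <= 1.7161e-7


class TestReferenceBuilders:
    def test_ramp_shape(self):
        ref = mpc.ramp_reference(7.0, cycles=7, cycle_period_s=4.0)
        assert ref.size == 28000
        assert ref.max() == pytest.approx(7.0)
        assert ref.min() == pytest.approx(-7.0)
        # each cycle integrates to zero net displacement
        assert abs(ref[:4000].sum()) * 0.001 < 1e-9

    def test_pwm_shape(self):
        ref = mpc.pwm_reference(5.0, period_s=2.0, duration_s=4.0)
        assert set(np.unique(ref)) == {-5.0, 5.0}
        assert ref[0] == 5.0 and ref[1500] == -5.0
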