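"""Linear constrained MPC with a dual (therapy / EMG-assistance) reference.

The controller tracks a velocity reference over a prediction horizon
``Hp`` with ``Hc`` free control moves (moves beyond ``Hc`` are held),
minimizing the quadratic cost

    J(U) = Σₖ W_MO (vₖ − rₖ)²  +  W_pos Σₖ (pₖ − rpₖ)²
         + W_MV Σₖ Δuₖ²  +  ε‖U‖²  +  ρ Σₖ slackₖ²

where the output (velocity) bound C-MO is *soft*: violations enter
through quadratic slack penalized by ρ, so the output "can leave the
range minimally" and the violation shrinks to zero as ρ → ∞.  Default
weights follow the tuned controller: ts = 1 ms, Hp = 20, Hc = 2,
W_MO = 0.135 on velocity, W_MV = 0 (a tiny ε keeps the QP strictly
convex), C-MO = ±0.007 m/s, input unconstrained.

The QP decision is the Hc-vector of moves; with soft constraints the
objective is piecewise quadratic and is solved exactly by an active-set
Newton iteration (the active penalty set stabilizes in a few steps).

Internally the controller works in SI units (m, m/s) — the plant and the
reference builders speak mm and mm/s, and :func:`run_closed_loop`
converts explicitly.  All reported MSEs are in controller units (m/s for
velocity, m for position).

Two references can drive the loop: the therapy trajectory and the
EMG-derived assistance velocity from the fuzzy stage.  With EMG priority
the controller discards the therapy reference wherever the assistance
channel is active, which is what lets it compensate muscle fatigue
independently of the prescribed motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import plant as plant_mod
from .plant import PlantConfig, PlantState

MM = 1e-3  # mm -> m


class MpcError(RuntimeError):
    pass


class MpcInfeasibleError(MpcError):
    """Hard output constraints cannot be met."""


@dataclass
class MpcConfig:
    ts: float = 0.001  # s
    prediction_horizon: int = 20  # Hp
    control_horizon: int = 2  # Hc
    w_mo: float = 0.135  # velocity tracking weight
    w_pos: float = 0.0  # optional position tracking weight
    w_mv: float = 0.0  # move (Δu) penalty
    u_reg: float = 1e-8  # strict-convexity regularizer on U
    c_mo: tuple[float, float] = (-0.007, 0.007)  # m/s output bound
    soft_constraints: bool = True
    slack_penalty: float = 1.0  # ρ
    performance: str = "nominal"  # nominal | robust | aggressive

    def __post_init__(self) -> None:
        if self.control_horizon < 1 or self.prediction_horizon < 1:
            raise ValueError("horizons must be >= 1")
        if self.control_horizon > self.prediction_horizon:
            raise ValueError(
                f"Hc={self.control_horizon} must be <= Hp={self.prediction_horizon}"
            )
        if min(self.w_mo, self.w_pos, self.w_mv, self.u_reg) < 0:
            raise ValueError("weights must be non-negative")
        if self.ts <= 0:
            raise ValueError("ts must be positive")
        if self.c_mo[0] >= self.c_mo[1]:
            raise ValueError("c_mo must be an increasing pair")
        if self.performance not in ("nominal", "robust", "aggressive"):
            raise ValueError(f"unknown performance preset {self.performance!r}")

    @property
    def effective_slack_penalty(self) -> float:
        scale = {"nominal": 1.0, "robust": 10.0, "aggressive": 0.1}[self.performance]
        return self.slack_penalty * scale


@dataclass
class ReferenceBundle:
    """Therapy velocity plus optional EMG-derived assistance velocity.

    Velocity traces are sampled at ``ts`` in mm/s.  ``priority`` selects
    the effective reference: "therapy", "emg" (assistance wins wherever
    ``emg_active``), or a (w_therapy, w_emg) weight pair for a blend.
    """

    ts: float
    therapy_v: np.ndarray  # mm/s
    emg_v: np.ndarray | None = None  # mm/s
    emg_active: np.ndarray | None = None  # bool mask
    priority: str | tuple[float, float] = "therapy"

    def __post_init__(self) -> None:
        self.therapy_v = np.asarray(self.therapy_v, dtype=float)
        if self.emg_v is not None:
            self.emg_v = np.asarray(self.emg_v, dtype=float)
            if self.emg_v.shape != self.therapy_v.shape:
                raise ValueError("therapy_v and emg_v must share the grid")
            if self.emg_active is None:
                self.emg_active = np.ones(self.therapy_v.shape, dtype=bool)
            else:
                self.emg_active = np.asarray(self.emg_active, dtype=bool)
        if isinstance(self.priority, str):
            if self.priority not in ("therapy", "emg"):
                raise ValueError(f"unknown priority {self.priority!r}")
        else:
            w = tuple(float(x) for x in self.priority)
            if len(w) != 2 or min(w) < 0 or sum(w) == 0:
                raise ValueError("weight pair must be two non-negative weights")
            self.priority = w

    @property
    def n_samples(self) -> int:
        return self.therapy_v.size


def blend_references(refs: ReferenceBundle) -> np.ndarray:
    """Effective velocity reference (mm/s) over the whole horizon."""
    if refs.priority == "therapy" or refs.emg_v is None:
        return refs.therapy_v.copy()
    if refs.priority == "emg":
        eff = refs.therapy_v.copy()
        eff[refs.emg_active] = refs.emg_v[refs.emg_active]
        return eff
    w_t, w_e = refs.priority
    return (w_t * refs.therapy_v + w_e * refs.emg_v) / (w_t + w_e)


def _prediction_matrices(
    a: np.ndarray, b: np.ndarray, hp: int, hc: int
) -> tuple[np.ndarray, np.ndarray]:
    """Phi (hp, 2, 2) and Gam (hp, 2, hc): xₖ = Phi[k-1] x0 + Gam[k-1] U,
    with moves beyond Hc held at the last move."""
    phi = np.empty((hp, 2, 2))
    gam = np.zeros((hp, 2, hc))
    a_pow = np.eye(2)
    impulse = []  # A^j B
    for _ in range(hp):
        impulse.append(a_pow @ b)
        a_pow = a_pow @ a
    a_pow = np.eye(2)
    for k in range(hp):
        a_pow = a_pow @ a
        phi[k] = a_pow
        for j in range(k + 1):
            col = min(j, hc - 1)
            gam[k, :, col] += impulse[k - j][:, 0]
    return phi, gam


class LinearMpc:
    """Receding-horizon solver bound to one plant model and configuration."""

    def __init__(self, config: MpcConfig, plant_config: PlantConfig):
        if abs(config.ts - plant_config.ts) > 1e-12:
            raise MpcError(
                f"controller ts={config.ts} differs from plant ts={plant_config.ts}"
            )
        self.config = config
        a, b, _ = plant_mod.linearized_model(plant_config)
        hp, hc = config.prediction_horizon, config.control_horizon
        phi, gam = _prediction_matrices(a, b, hp, hc)
        self.phi_p, self.gam_p = phi[:, 0, :], gam[:, 0, :]  # position rows
        self.phi_v, self.gam_v = phi[:, 1, :], gam[:, 1, :]  # velocity rows
        # move-difference operator (Δu0 = u0 - u_prev handled in linear term)
        d = np.eye(hc) - np.eye(hc, k=-1)
        self._h0 = 2.0 * (
            config.w_mo * self.gam_v.T @ self.gam_v
            + config.w_pos * self.gam_p.T @ self.gam_p
            + config.w_mv * d.T @ d
            + config.u_reg * np.eye(hc)
        )
        self._d = d
        self._rho = config.effective_slack_penalty

    def _linear_term(self, x0, r_v, r_p, u_prev) -> np.ndarray:
        cfg = self.config
        g = -2.0 * cfg.w_mo * self.gam_v.T @ (r_v - self.phi_v @ x0)
        if cfg.w_pos > 0 and r_p is not None:
            g += -2.0 * cfg.w_pos * self.gam_p.T @ (r_p - self.phi_p @ x0)
        if cfg.w_mv > 0:
            e0 = np.zeros(self._d.shape[0])
            e0[0] = 1.0
            g += -2.0 * cfg.w_mv * self._d.T @ (e0 * u_prev)
        return g

    def solve(
        self,
        x0: np.ndarray,
        r_v: np.ndarray,
        r_p: np.ndarray | None = None,
        u_prev: float = 0.0,
    ) -> np.ndarray:
        """Optimal move sequence U (length Hc) for the current state (m, m/s)."""
        cfg = self.config
        hp = cfg.prediction_horizon
        x0 = np.asarray(x0, dtype=float)
        r_v = np.asarray(r_v, dtype=float)
        if r_v.size < hp:  # hold last value
            r_v = np.r_[r_v, np.full(hp - r_v.size, r_v[-1] if r_v.size else 0.0)]
        r_v = r_v[:hp]
        if r_p is not None:
            r_p = np.asarray(r_p, dtype=float)[:hp]
        g = self._linear_term(x0, r_v, r_p, u_prev)
        u = np.linalg.solve(self._h0, -g)
        lb, ub = cfg.c_mo
        free_v = self.phi_v @ x0
        v = free_v + self.gam_v @ u
        if np.all(v <= ub) and np.all(v >= lb):
            return u
        rho = self._rho if cfg.soft_constraints else 1e10
        u = self._penalized_solve(u, g, free_v, rho)
        if not cfg.soft_constraints:
            v = free_v + self.gam_v @ u
            tol = 1e-8 * max(abs(lb), abs(ub))
            if np.any(v > ub + tol) or np.any(v < lb - tol):
                worst = float(np.max(np.maximum(v - ub, lb - v)))
                raise MpcInfeasibleError(
                    f"hard output bound [{lb}, {ub}] m/s violated by {worst:.3e}"
                )
        return u

    def _penalized_solve(
        self, u: np.ndarray, g: np.ndarray, free_v: np.ndarray, rho: float
    ) -> np.ndarray:
        """Exact active-set solution of the piecewise-quadratic penalized QP."""
        lb, ub = self.config.c_mo
        active_prev: tuple | None = None
        for _ in range(100):
            v = free_v + self.gam_v @ u
            up = v > ub
            lo = v < lb
            active = (tuple(np.nonzero(up)[0]), tuple(np.nonzero(lo)[0]))
            if active == active_prev:
                break
            active_prev = active
            h = self._h0.copy()
            rhs = -g.copy()
            if up.any():
                gu = self.gam_v[up]
                h += 2.0 * rho * gu.T @ gu
                rhs += 2.0 * rho * gu.T @ (ub - free_v[up])
            if lo.any():
                gl = self.gam_v[lo]
                h += 2.0 * rho * gl.T @ gl
                rhs += 2.0 * rho * gl.T @ (lb - free_v[lo])
            u = np.linalg.solve(h, rhs)
        return u


def solve_step(
    state: PlantState,
    refs_over_horizon: np.ndarray,
    config: MpcConfig,
    plant_config: PlantConfig | None = None,
    u_prev: float = 0.0,
) -> float:
    """Single receding-horizon solve; returns the first move in mm/s.

    ``refs_over_horizon`` is the future velocity reference in mm/s (the
    last value is held if fewer than Hp samples are given).  Convenience
    wrapper over :class:`LinearMpc`; closed-loop runs reuse one solver.
    """
    plant_config = plant_config or PlantConfig(ts=config.ts)
    solver = LinearMpc(config, plant_config)
    refs = np.asarray(refs_over_horizon, dtype=float) * MM
    if np.isnan(refs).any():
        raise MpcError("NaN in reference over horizon")
    x0 = np.array([state.position * MM, state.velocity * MM])
    u = solver.solve(x0, refs, u_prev=u_prev * MM)
    return float(u[0] / MM)


# ---------------------------------------------------------------------------
# Reference builders (mm/s)
# ---------------------------------------------------------------------------

def ramp_reference(
    peak_mm_s: float,
    cycles: int = 7,
    cycle_period_s: float = 4.0,
    ts: float = 0.001,
) -> np.ndarray:
    """Flexion/extension triangular velocity profile (constant acceleration).

    Each cycle is one opening/closing finger motion: velocity ramps
    0 → +peak → 0 over the first half (flexion), then 0 → −peak → 0 over
    the second half (extension), giving a quadratic (accelerated)
    position trajectory.
    """
    n_cycle = int(round(cycle_period_s / ts))
    t = np.arange(n_cycle) * ts
    knots_t = np.array([0.0, 0.25, 0.5, 0.75, 1.0]) * cycle_period_s
    knots_v = np.array([0.0, peak_mm_s, 0.0, -peak_mm_s, 0.0])
    one = np.interp(t, knots_t, knots_v)
    return np.tile(one, cycles)


def pwm_reference(
    amplitude_mm_s: float,
    period_s: float = 5.2,
    duration_s: float = 10.4,
    ts: float = 0.001,
    duty: float = 0.5,
) -> np.ndarray:
    """Square-wave (PWM-style) velocity reference alternating ±amplitude."""
    n = int(round(duration_s / ts))
    t = np.arange(n) * ts
    phase = (t % period_s) / period_s
    return np.where(phase < duty, amplitude_mm_s, -amplitude_mm_s)


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------

def run_closed_loop(
    plant_config: PlantConfig,
    mpc_config: MpcConfig,
    refs: ReferenceBundle,
    duration_s: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the MPC-driven actuator loop at ts.

    Returns the trajectory log (t, references, command, achieved velocity,
    exact and quantized position — mm units) and a metrics dict with MSEs
    in controller units (velocity: (m/s)², position: m²) plus Pearson
    correlations between the MPC command and the EMG/effective reference,
    split by flexion (reference > 0) and extension (reference < 0) phases.
    """
    ts = mpc_config.ts
    if abs(ts - refs.ts) > 1e-12:
        raise MpcError("reference bundle ts differs from controller ts")
    n_total = refs.n_samples
    if duration_s is not None:
        n = int(round(duration_s / ts))
        if n < 1:
            raise ValueError(f"duration {duration_s} s is shorter than one step")
        n = min(n, n_total)
    else:
        n = n_total
    if n < 1:
        raise ValueError("empty reference")

    eff_mm = blend_references(refs)[:n]
    eff = eff_mm * MM  # m/s
    solver = LinearMpc(mpc_config, plant_config)
    a, b, _ = plant_mod.linearized_model(plant_config)
    hp = mpc_config.prediction_horizon
    eff_pad = np.r_[eff, np.full(hp, eff[-1])]

    x = np.zeros(2)  # m, m/s (exact state)
    v_sat = plant_config.v_sat * MM
    lo, hi = (plant_config.stroke_limits[0] * MM, plant_config.stroke_limits[1] * MM)
    cmd = np.empty(n)
    vel = np.empty(n)
    pos = np.empty(n)
    u_prev = 0.0
    for k in range(n):
        u = solver.solve(x, eff_pad[k + 1 : k + 1 + hp], u_prev=u_prev)[0]
        u_prev = u
        u_ap = min(max(u, -v_sat), v_sat)
        x = a @ x + b[:, 0] * u_ap
        if x[0] <= lo:
            x[0], x[1] = lo, max(x[1], 0.0)
        elif x[0] >= hi:
            x[0], x[1] = hi, min(x[1], 0.0)
        cmd[k] = u
        vel[k] = x[1]
        pos[k] = x[0]

    # reference position: discrete integral of the effective velocity
    ref_pos = np.cumsum(eff) * ts
    t = (np.arange(n) + 1) * ts
    quant = plant_config.quantization * MM
    pos_q = np.round(pos / quant) * quant if quant > 0 else pos.copy()

    log = pd.DataFrame(
        {
            "t": t,
            "ref_v": eff_mm[:n],
            "therapy_v": refs.therapy_v[:n],
            "emg_v": (refs.emg_v[:n] if refs.emg_v is not None else np.full(n, np.nan)),
            "cmd_v": cmd / MM,
            "v": vel / MM,
            "p_exact": pos / MM,
            "p_quantized": pos_q / MM,
            "ref_p": ref_pos / MM,
        }
    )

    metrics = {
        "mse_velocity": float(np.mean((vel - eff) ** 2)),
        "mse_position": float(np.mean((pos - ref_pos) ** 2)),
        "rmse_velocity": float(np.sqrt(np.mean((vel - eff) ** 2))),
        "n_steps": int(n),
    }
    corr_target = (
        refs.emg_v[:n] * MM if refs.emg_v is not None else eff
    )
    for phase, mask in (("flexion", eff_mm[:n] > 0), ("extension", eff_mm[:n] < 0)):
        key = f"corr_{phase}"
        if mask.sum() >= 2 and np.std(corr_target[mask]) > 0 and np.std(cmd[mask]) > 0:
            metrics[key] = float(np.corrcoef(cmd[mask], corr_target[mask])[0, 1])
        else:
            metrics[key] = float("nan")
    return log, metrics
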