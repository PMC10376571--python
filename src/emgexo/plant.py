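"""Discrete-time model of the exoskeleton's linear servo-actuator.

The driven element is a small linear actuator (nominal speed band
2–7 mm/s, position readout resolved to 0.3 mm) whose integrated low-level
position loop is abstracted as a first-order velocity lag feeding an
integrator:

    v̇ = (u_sat − v) / τ,   ṗ = v,   u_sat = clip(u, ±v_sat)

discretized exactly (zero-order hold) at the control sample time.  The
exact continuous position is kept internally; the quantized readout
models the 0.3 mm sensing grid.  In the limit τ → 0 the model reduces to
a pure integrator on position (velocity follows the command within one
step), which is the form used by analytic tests.

Units: mm and mm/s throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np


@dataclass
class PlantConfig:
    ts: float = 0.001  # s, control sample time
    tau: float = 0.010  # s, velocity lag time constant (0 = ideal integrator)
    v_sat: float = 7.0  # mm/s hard actuator speed limit
    quantization: float = 0.3  # mm position readout grid (0 disables)
    stroke_limits: tuple[float, float] = (-50.0, 50.0)  # mm

    def __post_init__(self) -> None:
        if self.ts <= 0:
            raise ValueError(f"ts must be positive, got {self.ts}")
        if self.tau < 0 or self.quantization < 0 or self.v_sat <= 0:
            raise ValueError("tau/quantization must be >= 0 and v_sat > 0")
        if self.stroke_limits[0] >= self.stroke_limits[1]:
            raise ValueError("stroke_limits must be an increasing pair")


@dataclass
class PlantState:
    position: float = 0.0  # mm, exact (unquantized)
    velocity: float = 0.0  # mm/s

    def quantized_position(self, config: PlantConfig) -> float:
        if config.quantization <= 0:
            return self.position
        return round(self.position / config.quantization) * config.quantization


def linearized_model(config: PlantConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact ZOH discretization of the lag+integrator.

    State x = [position; velocity], input u = commanded velocity,
    output y = C x = [position; velocity].
    """
    ts, tau = config.ts, config.tau
    if tau == 0.0:
        # velocity reaches the command instantaneously within the step
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        b = np.array([[ts], [1.0]])
    else:
        alpha = math.exp(-ts / tau)
        a = np.array([[1.0, tau * (1.0 - alpha)], [0.0, alpha]])
        b = np.array([[ts - tau * (1.0 - alpha)], [1.0 - alpha]])
    c = np.eye(2)
    return a, b, c


def step(state: PlantState, commanded_v: float, config: PlantConfig) -> PlantState:
    """Advance one sample: saturate the command, apply the exact discrete
    dynamics, clip the stroke.  Commands are saturated, never rejected."""
    if not math.isfinite(commanded_v):
        raise ValueError(f"commanded velocity must be finite, got {commanded_v}")
    u = min(max(commanded_v, -config.v_sat), config.v_sat)
    a, b, _ = linearized_model(config)
    x = np.array([state.position, state.velocity])
    p, v = a @ x + b[:, 0] * u
    lo, hi = config.stroke_limits
    if p <= lo:
        p, v = lo, max(v, 0.0)
    elif p >= hi:
        p, v = hi, min(v, 0.0)
    return PlantState(position=float(p), velocity=float(v))


def simulate(
    commands: np.ndarray,
    config: PlantConfig,
    initial: PlantState | None = None,
) -> np.ndarray:
    """Run a command sequence; returns an (n, 4) array of
    (commanded_v, velocity, position_exact, position_quantized)."""
    state = initial or PlantState()
    a, b, _ = linearized_model(config)
    out = np.empty((len(commands), 4))
    for i, u in enumerate(commands):
        state = step(state, float(u), config)
        out[i] = (u, state.velocity, state.position, state.quantized_position(config))
    return out
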