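"""Sugeno-type MISO fuzzy inference: fatigue-level scores → assistance velocity.

Inputs are the three one-vs-rest detector scores (nonfatigue, transition,
fatigue), each fuzzified over a triangular {low, medium, high} partition
on [0, 1] whose memberships sum to one.  Rules are generated
programmatically from a declarative monotone policy over the partition
labels; consequents are zero-order (crisp) actions in
{decrease = −1, hold = 0, increase = +1}:

* fatigue score **high** → increase the assistance velocity;
* fatigue score **low** → decrease;
* fatigue score **medium** → hold, unless the nonfatigue score is high
  (clearly unfatigued → decrease).

Defuzzification is the Sugeno weighted average of consequents under
product firing strengths — a convex combination, so the aggregated action
lies in [−1, 1].  The velocity command integrates the action with a ramp
slope of 0.1 mm/s per update (|Δv| never exceeds the slope) and is
clamped to [0, v_max] with v_max = 10 mm/s by default (nominal actuator
band 0–7 mm/s).

The rule count depends on the partition granularity and is reported by
the rulebase; it is not forced to any particular published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

ACTIONS = {"decrease": -1.0, "hold": 0.0, "increase": 1.0}
INPUT_NAMES = ("nonfatigue", "transition", "fatigue")


class CoverageError(ValueError):
    """Membership partitions leave part of the input space without a firing rule."""


@dataclass
class FuzzyPartition:
    """Triangular fuzzy partition of [0, 1] with peaks at the given nodes.

    Adjacent triangles overlap and memberships sum to one everywhere
    (Ruspini partition), so coverage is guaranteed.
    """

    nodes: tuple[float, ...] = (0.0, 0.5, 1.0)
    labels: tuple[str, ...] = ("low", "medium", "high")

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.labels):
            raise ValueError("one label per node required")
        if len(self.nodes) < 2:
            raise CoverageError("a partition needs at least two nodes")
        if any(b <= a for a, b in zip(self.nodes, self.nodes[1:])):
            raise CoverageError("partition nodes must be strictly increasing")

    def membership(self, x: float) -> np.ndarray:
        x = float(np.clip(x, self.nodes[0], self.nodes[-1]))
        mu = np.zeros(len(self.nodes))
        if x <= self.nodes[0]:
            mu[0] = 1.0
            return mu
        j = int(np.searchsorted(self.nodes, x))  # nodes[j-1] < x <= nodes[j]
        left, right = self.nodes[j - 1], self.nodes[j]
        t = (x - left) / (right - left)
        mu[j - 1] = 1.0 - t
        mu[j] = t
        return mu


@dataclass
class FuzzyRule:
    antecedent: tuple[int, ...]  # label index per input
    consequent: str  # action name

    def firing(self, memberships: list[np.ndarray]) -> float:
        w = 1.0
        for mu, idx in zip(memberships, self.antecedent):
            w *= mu[idx]
        return w


def default_policy(labels: tuple[str, ...]) -> dict[tuple[int, ...], str]:
    """Monotone consequent table over (nonfatigue, transition, fatigue) labels."""
    table: dict[tuple[int, ...], str] = {}
    hi = len(labels) - 1
    for combo in product(range(len(labels)), repeat=3):
        l_non, _l_tr, l_fat = combo
        if l_fat == hi:
            action = "increase"
        elif l_fat == 0:
            action = "decrease"
        else:
            action = "decrease" if l_non == hi else "hold"
        table[combo] = action
    return table


@dataclass
class FuzzyRulebase:
    partitions: list[FuzzyPartition]
    rules: list[FuzzyRule]
    slope: float = 0.1  # mm/s velocity change per update at full action
    v_max: float = 10.0  # mm/s hard ceiling
    v_nominal: float = 7.0  # mm/s nominal actuator band (documentation)

    @property
    def rule_count(self) -> int:
        return len(self.rules)

    def aggregate(self, level_scores) -> float:
        """Sugeno weighted-average action in [-1, 1] for the three scores."""
        scores = np.asarray(level_scores, dtype=float).ravel()
        if scores.size != len(self.partitions):
            raise ValueError(
                f"expected {len(self.partitions)} scores, got {scores.size}"
            )
        if np.isnan(scores).any():
            raise ValueError("NaN level scores")
        if scores.min() < 0.0 or scores.max() > 1.0:
            raise ValueError("level scores must lie in [0, 1]")
        memberships = [p.membership(s) for p, s in zip(self.partitions, scores)]
        weights = np.array([r.firing(memberships) for r in self.rules])
        total = weights.sum()
        if total <= 0:
            raise CoverageError("no rule fires for this input")
        values = np.array([ACTIONS[r.consequent] for r in self.rules])
        return float(weights @ values / total)


def build_rulebase(
    nodes: tuple[float, ...] = (0.0, 0.5, 1.0),
    labels: tuple[str, ...] = ("low", "medium", "high"),
    policy: dict[tuple[int, ...], str] | None = None,
    slope: float = 0.1,
    v_max: float = 10.0,
) -> FuzzyRulebase:
    """Generate the full-coverage rulebase from the declarative policy."""
    partitions = [FuzzyPartition(nodes=nodes, labels=labels) for _ in INPUT_NAMES]
    if policy is None:
        policy = default_policy(labels)
    rules = []
    for combo in product(range(len(labels)), repeat=len(INPUT_NAMES)):
        if combo not in policy:
            raise CoverageError(f"policy missing a consequent for {combo}")
        action = policy[combo]
        if action not in ACTIONS:
            raise ValueError(f"unknown action {action!r}")
        rules.append(FuzzyRule(antecedent=combo, consequent=action))
    return FuzzyRulebase(partitions=partitions, rules=rules, slope=slope, v_max=v_max)


@dataclass
class VelocityCommand:
    v: float  # mm/s
    timestamp: float  # s


def update_velocity(
    rulebase: FuzzyRulebase,
    level_scores,
    current_v: float,
    dt: float = 0.7,
    timestamp: float = 0.0,
) -> VelocityCommand:
    """One fuzzy update of the assistance velocity.

    The aggregated action scales the ramp slope, so the velocity changes
    by at most ``rulebase.slope`` per update and stays in [0, v_max].
    ``dt`` is carried on the returned timestamp only; the slope is per
    update, matching a fuzzy stage that runs at the EMG window rate.
    """
    if not 0.0 <= current_v <= rulebase.v_max:
        raise ValueError(
            f"current_v={current_v} outside [0, {rulebase.v_max}] mm/s"
        )
    action = rulebase.aggregate(level_scores)
    v = float(np.clip(current_v + rulebase.slope * action, 0.0, rulebase.v_max))
    return VelocityCommand(v=v, timestamp=timestamp + dt)


def simulate_velocity(
    rulebase: FuzzyRulebase,
    score_sequence: np.ndarray,
    v0: float = 0.0,
    dt: float = 0.7,
) -> np.ndarray:
    """Integrate the fuzzy updates over a sequence of score triples."""
    v = float(v0)
    out = np.empty(len(score_sequence))
    for i, scores in enumerate(score_sequence):
        v = update_velocity(rulebase, scores, v, dt=dt, timestamp=i * dt).v
        out[i] = v
    return out
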