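"""Turtle decision-making and energy budget.

A turtle is a capital breeder cycling through five internal states:

    feeding -> foraging_migration -> feeding          (patch switching)
    feeding -> prenesting -> nesting -> postnesting -> feeding

While feeding it accumulates energy from its patch; it leaves a depleting
patch with a small per-step probability shaped by its foraging
patch-fidelity strategy ``S_F`` (1 = stayer, 0 = mover), and it departs on
prenesting migration once its reserves cover a full reproductive cycle:
round-trip migration to the natal rookery plus the nesting stay, whose
duration and cost scale with the nesting allocation strategy ``S_N``
(1 = investment, 0 = conservative). There is no mortality; energy may go
negative during unexpectedly long migrations and is never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .landscape import distance

FEEDING = "feeding"
PRENESTING = "prenesting"
POSTNESTING = "postnesting"
NESTING = "nesting"
FORAGING_MIGRATION = "foraging_migration"

STATES = (FEEDING, PRENESTING, POSTNESTING, NESTING, FORAGING_MIGRATION)

#: Legal state-machine edges.
LEGAL_TRANSITIONS = frozenset({
    (FEEDING, FORAGING_MIGRATION),
    (FORAGING_MIGRATION, FEEDING),
    (FEEDING, PRENESTING),
    (PRENESTING, NESTING),
    (NESTING, POSTNESTING),
    (POSTNESTING, FEEDING),
})


@dataclass
class Turtle:
    turtle_id: int
    x: float
    y: float
    nesting_site_id: int
    current_patch_id: int
    internal_state: str = FEEDING
    energy: float = 0.0
    s_f: float = 0.5
    s_n: float = 0.5
    avoidance_rotation_direction: Optional[str] = None  # "left" | "right" | None
    wall_following: bool = False
    heading: float = 0.0  # radians, persistent while wall-following
    migration_target: Optional[tuple[float, float]] = None
    target_patch_id: Optional[int] = None
    nesting_steps_remaining: int = 0
    last_nesting_completion_step: Optional[int] = None
    cycle_energy: float = 0.0  # cached trigger threshold for the current patch
    # positive ledger totals, for energy-conservation checks
    total_gain: float = 0.0
    total_migration_cost: float = 0.0
    total_nesting_cost: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_f <= 1.0 and 0.0 <= self.s_n <= 1.0):
            raise ValueError("strategies S_F, S_N must lie in [0, 1]")

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)

    def transition(self, new_state: str) -> None:
        if (self.internal_state, new_state) not in LEGAL_TRANSITIONS:
            raise ValueError(
                f"illegal transition {self.internal_state} -> {new_state}"
            )
        self.internal_state = new_state


def feed(turtle: Turtle, patch, alpha_step: float) -> float:
    """One feeding step: gain ``alpha * phi`` (per-step rate) from the patch.

    Increments the patch's time-usage tally. Returns the updated energy.
    """
    if turtle.internal_state != FEEDING:
        raise ValueError("feed() requires the feeding state")
    gain = alpha_step * patch.phi
    turtle.energy += gain
    turtle.total_gain += gain
    patch.time_usage += 1
    return turtle.energy


def leave_probability(phi: float, s_f: float, a: float, b: float) -> float:
    """Per-step probability of abandoning the current feeding patch.

    A falling logistic of the resource level ``phi`` with steepness ``a``
    and leaving threshold ``b``, scaled by 1/1000 (so even a mover leaves a
    barren patch on the order of once per thousand steps) and by
    ``(1 - S_F)``: a perfect stayer (``S_F = 1``) never leaves.
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    if not 0.0 <= s_f <= 1.0:
        raise ValueError("S_F must lie in [0, 1]")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    z = (phi - b) / a
    if z > 0:
        sig = 1.0 / (1.0 + math.exp(-z))
    else:
        e = math.exp(z)
        sig = e / (1.0 + e)
    return (1.0 - s_f) * 1e-3 * (1.0 - sig)


def patch_choice_weights(
    from_point: tuple[float, float],
    candidates: Sequence,
    lambda_decay: float,
    d_min: float,
    d_max: float,
) -> np.ndarray:
    """Distance-decay weights ``(1 - d_relative) ** lambda`` over candidates.

    ``d_relative`` rescales the distance into [0, 1] using the landscape's
    min/max inter-patch distances; the farthest conceivable patch gets
    weight 0, the nearest weight 1.
    """
    span = d_max - d_min
    w = np.empty(len(candidates))
    for i, p in enumerate(candidates):
        d = distance(from_point, (p.x, p.y))
        d_rel = 0.0 if span <= 0 else min(max((d - d_min) / span, 0.0), 1.0)
        w[i] = (1.0 - d_rel) ** lambda_decay
    return w


def choose_new_patch(
    current_patch_id: Optional[int],
    patch_registry: Sequence,
    from_point: tuple[float, float],
    lambda_decay: float,
    d_min: float,
    d_max: float,
    rng: np.random.Generator,
) -> int:
    """Sample a destination patch with distance-decay preference.

    Candidates are all registered patches except the current one (pass
    ``current_patch_id=None`` to include all, as at initial allocation,
    where the distance is measured from the nesting site). Degenerate
    all-zero weights fall back to the single nearest candidate.
    """
    candidates = [p for p in patch_registry if p.patch_id != current_patch_id]
    if not candidates:
        raise ValueError("no candidate patch to choose from")
    if len(candidates) == 1:
        return candidates[0].patch_id
    w = patch_choice_weights(from_point, candidates, lambda_decay, d_min, d_max)
    total = w.sum()
    if total <= 0.0:
        dists = [distance(from_point, (p.x, p.y)) for p in candidates]
        return candidates[int(np.argmin(dists))].patch_id
    idx = rng.choice(len(candidates), p=w / total)
    return candidates[int(idx)].patch_id


def cycle_energy_requirement(
    distance_to_nest: float,
    c: float,
    s_n: float,
    t_n_max: float,
    delta_eps_m: float,
    delta_eps_n: float,
) -> float:
    """Energy needed for one full reproductive cycle from a given patch.

    Round-trip migration (``2 * delta_eps_m * d / c`` with speed ``c`` in
    km/day and the cost in energy/day) plus the nesting stay
    (``S_N * T_n_max`` days at ``delta_eps_n`` per day).
    """
    if c <= 0:
        raise ValueError("migration speed c must be > 0")
    if distance_to_nest < 0 or delta_eps_m < 0 or delta_eps_n < 0 or t_n_max < 0:
        raise ValueError("distances and costs must be >= 0")
    return 2.0 * delta_eps_m * distance_to_nest / c + s_n * t_n_max * delta_eps_n


def should_start_prenesting(turtle: Turtle, energy_cycle: float) -> bool:
    """True once reserves cover the full cycle (threshold inclusive)."""
    if turtle.internal_state != FEEDING:
        raise ValueError("prenesting decision requires the feeding state")
    return turtle.energy >= energy_cycle


def nesting_duration_steps(s_n: float, t_n_max: float) -> int:
    """Nesting stay in half-day steps: ``round(S_N * T_n_max * 2)``."""
    if not 0.0 <= s_n <= 1.0:
        raise ValueError("S_N must lie in [0, 1]")
    return int(round(s_n * t_n_max * 2.0))


def nest_step(turtle: Turtle, delta_eps_n_step: float, step: int,
              observation_store=None) -> bool:
    """One half-day of nesting; returns True when the stay completes.

    Energy drops by the per-step nesting cost. On completion a nesting
    event (turtle, site, step, post-nesting energy) is recorded if a store
    is given, and the turtle heads back to its last preferred patch.
    """
    if turtle.internal_state != NESTING:
        raise ValueError("nest_step() requires the nesting state")
    if turtle.nesting_steps_remaining <= 0:
        raise ValueError("no nesting steps remaining")
    turtle.energy -= delta_eps_n_step
    turtle.total_nesting_cost += delta_eps_n_step
    turtle.nesting_steps_remaining -= 1
    if turtle.nesting_steps_remaining == 0:
        turtle.last_nesting_completion_step = step
        if observation_store is not None:
            observation_store.record_nesting_event(
                turtle.turtle_id, turtle.nesting_site_id, step, turtle.energy
            )
        return True
    return False
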