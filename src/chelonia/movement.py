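"""Per-step displacement with coast avoidance and optional advection.

A migrating turtle swims at a fixed motor speed toward its target
(nesting site or feeding patch). When land blocks the way within the
sensing horizon it wall-follows: the heading is rotated away from the
target in fixed angular increments, always on a memorized side, by the
minimal angle that clears the lookahead. The side is chosen at the first
obstruction of a migration leg as the one needing the smaller turn (ties
go left) and is flipped between the outbound and return legs so that the
two legs trace roughly mirror-image routes around a barrier.

Currents, when enabled, add the local water velocity vector to the motor
displacement. Headings are radians, 0 = east, counter-clockwise positive
("left" rotates CCW).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .landscape import Landscape, distance


@dataclass(frozen=True)
class MovementParams:
    speed_km_per_day: float = 65.0
    angle_step_deg: float = 15.0
    detection_range_km: float = 7.0
    sensing_radius_km: float = 100.0
    migration_cost_per_day: float = 10.0

    def __post_init__(self) -> None:
        if min(self.speed_km_per_day, self.angle_step_deg,
               self.detection_range_km, self.sensing_radius_km) <= 0:
            raise ValueError("movement parameters must be positive")
        if self.migration_cost_per_day < 0:
            raise ValueError("migration cost must be >= 0")
        if 360.0 % self.angle_step_deg != 0:
            raise ValueError("angle_step_deg must divide 360")


def arrived(position: tuple[float, float], target: tuple[float, float],
            detection_range_km: float) -> bool:
    """Closed-boundary arrival test: within the detection range, inclusive."""
    return distance(position, target) <= detection_range_km


def reset_rotation_direction(turtle, transition: str) -> None:
    """Update coast-avoidance side memory at a migration-phase boundary.

    Starting a postnesting leg flips the memorized side (mirror-image
    return route); starting a prenesting leg leaves it to be re-derived at
    the first obstruction; foraging-migration boundaries clear it, since
    those trips are independent of the nesting round trip.
    """
    if transition == "start_postnesting":
        side = turtle.avoidance_rotation_direction
        if side == "left":
            turtle.avoidance_rotation_direction = "right"
        elif side == "right":
            turtle.avoidance_rotation_direction = "left"
    elif transition == "start_prenesting":
        turtle.avoidance_rotation_direction = None
    elif transition in ("start_foraging_migration", "end_foraging_migration"):
        turtle.avoidance_rotation_direction = None
    else:
        raise ValueError(f"unknown transition {transition!r}")
    turtle.wall_following = False


def _min_clear_rotation(landscape: Landscape, position, desired_heading,
                        lookahead, sensing, angle_step_rad, sign) -> int | None:
    """Smallest k >= 1 such that rotating k*angle_step on side `sign` clears."""
    n_max = int(round(2.0 * math.pi / angle_step_rad))
    for k in range(1, n_max):
        h = desired_heading + sign * k * angle_step_rad
        blocked, _ = landscape.coast_ahead(position, h, lookahead, sensing)
        if not blocked:
            return k
    return None


def avoid_coast(position: tuple[float, float], desired_heading: float,
                rotation_direction: str | None, landscape: Landscape,
                params: MovementParams,
                lookahead_km: float) -> tuple[float | None, str | None]:
    """Adjust a heading so the next step stays off land.

    Returns ``(heading, rotation_direction)``. The heading is the desired
    one when it is clear — this is also what lets a wall-follower relax
    back onto the target bearing each step, because the caller always
    passes the bearing to the target as the desired heading. When blocked,
    the heading rotates on the memorized side by the minimal multiple of
    the angle step that clears; at a first-ever obstruction the side with
    the smaller clearing angle is picked (ties go left) and memorized.
    A fully enclosed position yields ``(None, rotation_direction)``.
    """
    blocked, _ = landscape.coast_ahead(position, desired_heading, lookahead_km,
                                       params.sensing_radius_km)
    if not blocked:
        return (desired_heading, rotation_direction)
    step_rad = math.radians(params.angle_step_deg)
    if rotation_direction is None:
        k_left = _min_clear_rotation(landscape, position, desired_heading,
                                     lookahead_km, params.sensing_radius_km,
                                     step_rad, +1)
        k_right = _min_clear_rotation(landscape, position, desired_heading,
                                      lookahead_km, params.sensing_radius_km,
                                      step_rad, -1)
        if k_left is None and k_right is None:
            return (None, None)
        if k_right is None or (k_left is not None and k_left <= k_right):
            return (desired_heading + k_left * step_rad, "left")
        return (desired_heading - k_right * step_rad, "right")
    sign = +1 if rotation_direction == "left" else -1
    k = _min_clear_rotation(landscape, position, desired_heading, lookahead_km,
                            params.sensing_radius_km, step_rad, sign)
    if k is None:
        return (None, rotation_direction)
    return (desired_heading + sign * k * step_rad, rotation_direction)


def _truncate_to_ocean(landscape: Landscape, x0: float, y0: float,
                       x1: float, y1: float) -> tuple[float, float]:
    """Project a displacement endpoint back to the last ocean point.

    Walks the segment from its far end toward the start in fine steps and
    returns the first non-land point; falls back to the start.
    """
    seg = math.hypot(x1 - x0, y1 - y0)
    if seg == 0.0:
        return (x0, y0)
    n = max(2, int(math.ceil(seg / (landscape.cell_size_km / 4.0))))
    for i in range(n, -1, -1):
        t = i / n
        x, y = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        if not landscape.is_land(x, y):
            return (x, y)
    return (x0, y0)


def _wrap(angle: float) -> float:
    """Normalize an angle to (-pi, pi]."""
    a = math.fmod(angle + math.pi, 2.0 * math.pi)
    if a <= 0.0:
        a += 2.0 * math.pi
    return a - math.pi


def _clear_toward_target(landscape: Landscape, pos, desired: float,
                         lookahead: float, sensing: float,
                         d_target: float) -> bool:
    """True when the turtle may head straight for its target.

    Either the ray is unobstructed, or the first obstruction lies beyond
    the target itself — a site or patch tucked against a coast is reached
    by swimming up to it, not treated as walled off by the land behind it.
    """
    blocked, d_block = landscape.coast_ahead(pos, desired, lookahead, sensing)
    return (not blocked) or (d_block is not None and d_target < d_block)


def _wall_follow_heading(turtle, desired: float, d_target: float,
                         landscape: Landscape, params: MovementParams,
                         lookahead: float) -> float | None:
    """Continue an ongoing wall-follow; returns the new heading or None.

    The previous heading persists between steps. Each step the turtle
    first checks whether the target bearing itself has come clear (then
    coast-following ends); otherwise it relaxes its heading incrementally
    back toward the target while the way stays clear, or rotates further
    away on the memorized side when even its previous heading is blocked.
    """
    sensing = params.sensing_radius_km
    step_rad = math.radians(params.angle_step_deg)
    sign = +1 if turtle.avoidance_rotation_direction == "left" else -1
    pos = (turtle.x, turtle.y)
    if _clear_toward_target(landscape, pos, desired, lookahead, sensing,
                            d_target):
        turtle.wall_following = False
        return desired
    h = turtle.heading
    blocked, _ = landscape.coast_ahead(pos, h, lookahead, sensing)
    if blocked:
        k = _min_clear_rotation(landscape, pos, h, lookahead, sensing,
                                step_rad, sign)
        if k is None:
            return None
        return _wrap(h + sign * k * step_rad)
    # rotate back toward the target while the way ahead stays clear,
    # never past the (blocked) target bearing itself
    back = (sign * (h - desired)) % (2.0 * math.pi)
    n_back = int(back / step_rad)
    for _j in range(n_back):
        h2 = h - sign * step_rad
        blocked, _ = landscape.coast_ahead(pos, h2, lookahead, sensing)
        if blocked:
            break
        h = h2
    return _wrap(h)


def step_toward(turtle, target: tuple[float, float], landscape: Landscape,
                params: MovementParams, use_currents: bool) -> bool:
    """Advance a migrating turtle by one half-day step.

    The motor displacement has length ``c/2`` km (or less on the final
    approach: if the target is closer than one step and the bearing is
    clear, the turtle lands exactly on it), aimed at the target bearing
    unless land is in the way, in which case the turtle wall-follows on
    its memorized side. With currents on, the local water velocity (halved
    per half-day step) is added to the motor displacement; if the summed
    displacement would end on land or off-grid it is truncated at the last
    ocean point along the segment. The step always costs half the daily
    migration energy. Returns False only when the turtle is fully enclosed
    and stays put (it still pays the step cost while stranded).
    """
    x, y = turtle.x, turtle.y
    if landscape.is_land(x, y):
        raise ValueError(f"turtle {turtle.turtle_id} starts on land: corrupt state")
    step_len = params.speed_km_per_day / 2.0
    cost = params.migration_cost_per_day / 2.0
    turtle.energy -= cost
    turtle.total_migration_cost += cost

    tx, ty = target
    d_target = math.hypot(tx - x, ty - y)
    desired = math.atan2(ty - y, tx - x) if d_target > 0 else 0.0
    if turtle.wall_following:
        heading = _wall_follow_heading(turtle, desired, d_target, landscape,
                                       params, step_len)
    elif _clear_toward_target(landscape, (x, y), desired, step_len,
                              params.sensing_radius_km, d_target):
        heading = desired
    else:
        heading, new_dir = avoid_coast((x, y), desired,
                                       turtle.avoidance_rotation_direction,
                                       landscape, params, lookahead_km=step_len)
        turtle.avoidance_rotation_direction = new_dir
        if heading is not None and heading != desired:
            turtle.wall_following = True
    if heading is None:
        return False  # fully enclosed; stay put
    turtle.heading = heading
    cu, cv = landscape.current_at(x, y) if use_currents else (0.0, 0.0)
    if heading == desired and d_target <= step_len:
        # final approach: land exactly on the target, compensating for the
        # local drift so the net displacement ends at the target
        mx, my = tx - x - cu * 0.5, ty - y - cv * 0.5
        m = math.hypot(mx, my)
        if m > step_len:
            mx, my = mx * step_len / m, my * step_len / m
    else:
        mx = step_len * math.cos(heading)
        my = step_len * math.sin(heading)
    # motor first (its ray is clear), then drift; the drift alone is
    # truncated at the coast so the current can pin a turtle against the
    # shore but never cancel its motor progress or push it onto land
    nx, ny = x + mx, y + my
    if landscape.is_land(nx, ny):
        nx, ny = _truncate_to_ocean(landscape, x, y, nx, ny)
    if cu != 0.0 or cv != 0.0:
        dx_, dy_ = nx + cu * 0.5, ny + cv * 0.5
        if landscape.is_land(dx_, dy_):
            dx_, dy_ = _truncate_to_ocean(landscape, nx, ny, dx_, dy_)
        nx, ny = dx_, dy_
    turtle.x, turtle.y = nx, ny
    return True
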