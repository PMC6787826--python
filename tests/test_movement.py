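import math

import numpy as np
import pytest

from chelonia.behavior import PRENESTING, Turtle
from chelonia.landscape import NestingSite, PatchLocation, distance
from chelonia.movement import (MovementParams, arrived, avoid_coast,
                               reset_rotation_direction, step_toward)
from conftest import make_landscape

PARAMS = MovementParams()  # 65 km/day, 15 deg, 7 km detection, 100 km sensing


def make_migrant(x, y, target, landscape=None, side=None):
    t = Turtle(turtle_id=1, x=x, y=y, nesting_site_id=1, current_patch_id=1)
    t.internal_state = PRENESTING
    t.migration_target = target
    t.avoidance_rotation_direction = side
    return t


class TestOpenWaterKinematics:
    def test_two_half_day_steps_cover_one_daily_ration(self, open_ocean):
        t = make_migrant(10.0, 10.0, (10.0, 200.0))
        for _ in range(2):
            step_toward(t, t.migration_target, open_ocean, PARAMS,
                        use_currents=False)
        assert distance((10.0, 10.0), (t.x, t.y)) == pytest.approx(65.0)
        assert t.x == pytest.approx(10.0)  # straight segment

    def test_each_step_costs_half_daily_migration_energy(self, open_ocean):
        t = make_migrant(10.0, 10.0, (10.0, 200.0))
        for k in range(1, 4):
            step_toward(t, t.migration_target, open_ocean, PARAMS,
                        use_currents=False)
            assert t.total_migration_cost == pytest.approx(
                k * PARAMS.migration_cost_per_day / 2)

    def test_final_approach_lands_exactly_on_target(self, open_ocean):
        t = make_migrant(10.0, 10.0, (10.0, 30.0))
        step_toward(t, t.migration_target, open_ocean, PARAMS,
                    use_currents=False)
        assert (t.x, t.y) == pytest.approx((10.0, 30.0))


class TestCurrents:
    def _world_with_current(self, u, v):
        n = 30
        uu = np.full((n, n), float(u))
        vv = np.full((n, n), float(v))
        return make_landscape(np.zeros((n, n), dtype=int),
                              sites=[NestingSite(1, "AAA", 10.0, 10.0, 1.0)],
                              patches=[PatchLocation(1, 150.0, 10.0),
                                       PatchLocation(2, 150.0, 150.0)],
                              u=uu, v=vv)

    def test_opposing_current_cancels_motor(self):
        ls = self._world_with_current(-65.0, 0.0)  # 32.5 km/step westward
        t = make_migrant(50.0, 50.0, (180.0, 50.0))
        step_toward(t, t.migration_target, ls, PARAMS, use_currents=True)
        assert (t.x, t.y) == pytest.approx((50.0, 50.0))

    def test_cross_current_displaces_diagonally(self):
        ls = self._world_with_current(0.0, 65.0)  # northward 32.5 km/step
        t = make_migrant(50.0, 50.0, (180.0, 50.0))
        step_toward(t, t.migration_target, ls, PARAMS, use_currents=True)
        assert (t.x, t.y) == pytest.approx((82.5, 82.5))

    def test_zero_current_field_equals_no_currents(self, open_ocean):
        a = make_migrant(10.0, 10.0, (150.0, 150.0))
        b = make_migrant(10.0, 10.0, (150.0, 150.0))
        for _ in range(5):
            step_toward(a, a.migration_target, open_ocean, PARAMS, True)
            step_toward(b, b.migration_target, open_ocean, PARAMS, False)
        assert (a.x, a.y) == (b.x, b.y)


class TestArrival:
    def test_exact_position(self):
        assert arrived((5.0, 5.0), (5.0, 5.0), 7.0)

    def test_closed_boundary(self):
        assert arrived((0.0, 0.0), (7.0, 0.0), 7.0)
        assert not arrived((0.0, 0.0), (7.0 + 1e-9, 0.0), 7.0)


class TestRotationMemory:
    @pytest.mark.parametrize("before,transition,after", [
        ("left", "start_postnesting", "right"),
        ("right", "start_postnesting", "left"),
        (None, "start_postnesting", None),
        ("right", "start_foraging_migration", None),
        ("left", "end_foraging_migration", None),
        ("left", "start_prenesting", None),
    ])
    def test_transitions(self, before, transition, after):
        t = make_migrant(0.0, 0.0, (1.0, 1.0), side=before)
        reset_rotation_direction(t, transition)
        assert t.avoidance_rotation_direction == after

    def test_unknown_transition_rejected(self):
        t = make_migrant(0.0, 0.0, (1.0, 1.0))
        with pytest.raises(ValueError):
            reset_rotation_direction(t, "hibernate")


class TestAvoidCoast:
    def _walled_world(self):
        # north-south wall at col 10 (x 70..77), gap above row 16
        n = 20
        mask = np.zeros((n, n), dtype=int)
        mask[:16, 10] = 1
        return make_landscape(mask,
                              sites=[NestingSite(1, "AAA", 10.0, 10.0, 1.0)],
                              patches=[PatchLocation(1, 130.0, 10.0),
                                       PatchLocation(2, 130.0, 130.0)])

    def test_clear_heading_untouched(self, open_ocean):
        h, side = avoid_coast((100.0, 100.0), 0.3, None, open_ocean, PARAMS,
                              lookahead_km=32.5)
        assert h == 0.3 and side is None

    def test_first_obstruction_picks_smaller_turn(self):
        ls = self._walled_world()
        # heading east into the wall from slightly south of the gap: turning
        # left (north, toward the gap at y>112) clears sooner than right
        h, side = avoid_coast((50.0, 100.0), 0.0, None, ls, PARAMS,
                              lookahead_km=32.5)
        assert side == "left"
        assert h > 0.0

    def test_memorized_side_respected(self):
        ls = self._walled_world()
        h, side = avoid_coast((50.0, 100.0), 0.0, "right", ls, PARAMS,
                              lookahead_km=32.5)
        assert side == "right"
        assert h < 0.0


class TestWallFollowing:
    def test_rounds_wall_and_reaches_target(self):
        # wall between turtle and target, with a gap at the north end
        n = 20
        mask = np.zeros((n, n), dtype=int)
        mask[:16, 10] = 1
        ls = make_landscape(mask,
                            sites=[NestingSite(1, "AAA", 10.0, 10.0, 1.0)],
                            patches=[PatchLocation(1, 130.0, 60.0),
                                     PatchLocation(2, 35.0, 60.0)])
        t = make_migrant(35.0, 60.0, (130.0, 60.0))
        start = (t.x, t.y)
        path = 0.0
        for _ in range(60):
            x0, y0 = t.x, t.y
            step_toward(t, t.migration_target, ls, PARAMS, use_currents=False)
            assert not ls.is_land(t.x, t.y)
            path += distance((x0, y0), (t.x, t.y))
            if arrived((t.x, t.y), t.migration_target,
                       PARAMS.detection_range_km):
                break
        assert arrived((t.x, t.y), t.migration_target,
                       PARAMS.detection_range_km)
        assert path > distance(start, t.migration_target)

    @pytest.mark.parametrize("shape", ["block", "diamond", "bar"])
    def test_reaches_target_behind_convex_obstacles(self, shape):
        n = 30
        mask = np.zeros((n, n), dtype=int)
        if shape == "block":
            mask[12:18, 12:18] = 1
        elif shape == "diamond":
            for r in range(30):
                for c in range(30):
                    if abs(r - 15) + abs(c - 15) <= 5:
                        mask[r, c] = 1
        else:
            mask[14:16, 8:22] = 1
        ls = make_landscape(mask,
                            sites=[NestingSite(1, "AAA", 105.0, 10.0, 1.0)],
                            patches=[PatchLocation(1, 105.0, 200.0),
                                     PatchLocation(2, 10.0, 10.0)])
        t = make_migrant(105.0, 10.0, (105.0, 200.0))
        for _ in range(80):
            step_toward(t, t.migration_target, ls, PARAMS, use_currents=False)
            assert not ls.is_land(t.x, t.y)
            if arrived((t.x, t.y), t.migration_target,
                       PARAMS.detection_range_km):
                break
        assert arrived((t.x, t.y), t.migration_target,
                       PARAMS.detection_range_km)

    def test_coast_hugging_target_is_reachable(self):
        # target patch one cell off a straight coast: the land behind the
        # patch must not make the approach look blocked
        n = 20
        mask = np.zeros((n, n), dtype=int)
        mask[:, 12:] = 1
        ls = make_landscape(mask,
                            sites=[NestingSite(1, "AAA", 10.0, 10.0, 1.0)],
                            patches=[PatchLocation(1, 80.0, 80.0),
                                     PatchLocation(2, 10.0, 80.0)])
        t = make_migrant(10.0, 80.0, (80.0, 80.0))
        for _ in range(10):
            step_toward(t, t.migration_target, ls, PARAMS, use_currents=False)
            assert not ls.is_land(t.x, t.y)
            if arrived((t.x, t.y), t.migration_target,
                       PARAMS.detection_range_km):
                break
        assert arrived((t.x, t.y), t.migration_target,
                       PARAMS.detection_range_km)

    def test_onshore_current_cannot_ground_or_pin(self):
        # strong onshore (eastward) current against a coastal wall: the
        # turtle neither lands nor loses its along-shore motor progress
        n = 20
        mask = np.zeros((n, n), dtype=int)
        mask[:, 12:] = 1
        u = np.full((n, n), 40.0)
        ls = make_landscape(mask,
                            sites=[NestingSite(1, "AAA", 10.0, 10.0, 1.0)],
                            patches=[PatchLocation(1, 80.0, 130.0),
                                     PatchLocation(2, 10.0, 80.0)],
                            u=u)
        t = make_migrant(80.0, 10.0, (80.0, 130.0))
        ys = [t.y]
        for _ in range(12):
            step_toward(t, t.migration_target, ls, PARAMS, use_currents=True)
            assert not ls.is_land(t.x, t.y)
            ys.append(t.y)
        assert ys[-1] > ys[0] + 100.0  # kept moving north along the shore
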