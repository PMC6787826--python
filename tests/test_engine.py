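import numpy as np
import pandas as pd
import pytest

from chelonia.behavior import FEEDING, LEGAL_TRANSITIONS
from chelonia.engine import (ExperimentDesign, SimulationConfig,
                             allocate_rookeries, build_experiment, initialize,
                             run_simulation, run_step, scaled_min_allocation)
from chelonia.landscape import REFERENCE_ROOKERY_WEIGHTS
from chelonia.observe import remigration_intervals

REF_WEIGHTS = [w for _, w in REFERENCE_ROOKERY_WEIGHTS]


class TestAllocation:
    def test_reference_allocation_totals_exactly(self):
        counts = allocate_rookeries(REF_WEIGHTS, 7_000, 45)
        assert sum(counts) == 7_000
        # the eight minor rookeries each hold exactly the minimum
        assert counts[6:] == [45] * 8
        # majors keep their proportions
        assert counts[0] == max(counts)
        assert counts[1] == counts[2] == counts[3]
        assert counts[4] == counts[5]

    def test_population_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            allocate_rookeries(REF_WEIGHTS, 100, 45)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            allocate_rookeries([0.0, 0.0], 10, 0)

    def test_single_site_gets_everything(self):
        assert allocate_rookeries([3.0], 123, 45) == [123]

    def test_min_allocation_scales_with_population(self):
        assert scaled_min_allocation(45, 7_000) == 45
        assert scaled_min_allocation(45, 500) == 3
        assert scaled_min_allocation(45, 14_000) == 90


class TestInitialize:
    def test_population_and_state(self, channel_landscape):
        cfg = SimulationConfig(n_turtles=100, steps_total=100,
                               steps_burn_in=10, min_allocation=1, seed=5)
        rng = np.random.default_rng(cfg.seed)
        state = initialize(cfg, channel_landscape, rng)
        assert len(state.turtles) == 100
        patch_ids = {p.patch_id for p in channel_landscape.feeding_patches}
        for t in state.turtles:
            assert t.internal_state == FEEDING
            assert t.current_patch_id in patch_ids
            p = channel_landscape.patch(t.current_patch_id)
            assert (t.x, t.y) == (p.x, p.y)
            assert 0.0 <= t.energy <= t.cycle_energy
        # occupancy bookkeeping matches the population
        assert sum(p.occupancy for p in state.patches.values()) == 100

    def test_initial_resource_uniform_or_full(self, minimal_landscape):
        cfg = SimulationConfig(n_turtles=10, steps_total=10, steps_burn_in=1,
                               min_allocation=1, seed=0)
        state = initialize(cfg, minimal_landscape,
                           np.random.default_rng(0))
        for p in state.patches.values():
            assert 0.0 <= p.phi <= cfg.phi_max
        cfg0 = SimulationConfig(n_turtles=10, steps_total=10, steps_burn_in=1,
                                min_allocation=1, seed=0, alpha=0.0)
        state0 = initialize(cfg0, minimal_landscape,
                            np.random.default_rng(0))
        assert all(p.phi == cfg0.phi_max for p in state0.patches.values())

    def test_single_site_world_shares_one_rookery(self, minimal_landscape):
        cfg = SimulationConfig(n_turtles=25, steps_total=10, steps_burn_in=1,
                               min_allocation=1, seed=1)
        state = initialize(cfg, minimal_landscape, np.random.default_rng(1))
        assert {t.nesting_site_id for t in state.turtles} == {1}


class TestRunStep:
    def test_turtle_count_conserved_and_transitions_legal(self,
                                                          channel_landscape):
        cfg = SimulationConfig(n_turtles=60, steps_total=600,
                               steps_burn_in=50, min_allocation=1, seed=11)
        rng = np.random.default_rng(cfg.seed)
        state = initialize(cfg, channel_landscape, rng)
        prev = {t.turtle_id: t.internal_state for t in state.turtles}
        for _ in range(600):
            run_step(state)
            assert len(state.turtles) == 60
            for t in state.turtles:
                if t.internal_state != prev[t.turtle_id]:
                    assert (prev[t.turtle_id], t.internal_state) in \
                        LEGAL_TRANSITIONS
                    prev[t.turtle_id] = t.internal_state

    def test_no_turtle_ever_on_land(self, channel_landscape):
        cfg = SimulationConfig(n_turtles=60, steps_total=800,
                               steps_burn_in=50, min_allocation=1, seed=13)
        state = initialize(cfg, channel_landscape,
                           np.random.default_rng(cfg.seed))
        for _ in range(800):
            run_step(state)
            for t in state.turtles:
                assert not channel_landscape.is_land(t.x, t.y)

    def test_same_seed_bit_identical_trajectories(self, channel_landscape):
        def run(seed):
            cfg = SimulationConfig(n_turtles=50, steps_total=400,
                                   steps_burn_in=50, min_allocation=1,
                                   seed=seed)
            state = initialize(cfg, channel_landscape,
                               np.random.default_rng(seed))
            for _ in range(400):
                run_step(state)
            return [(t.x, t.y, t.energy, t.internal_state)
                    for t in state.turtles]

        assert run(21) == run(21)
        assert run(21) != run(22)


class TestEnergyLedger:
    def test_ledger_closes_exactly(self, channel_landscape):
        cfg = SimulationConfig(n_turtles=40, steps_total=1200,
                               steps_burn_in=100, min_allocation=1, seed=31)
        state = initialize(cfg, channel_landscape,
                           np.random.default_rng(cfg.seed))
        initial = {t.turtle_id: t.energy for t in state.turtles}
        for _ in range(1200):
            run_step(state)
        for t in state.turtles:
            expected = (initial[t.turtle_id] + t.total_gain
                        - t.total_migration_cost - t.total_nesting_cost)
            assert t.energy == pytest.approx(expected, abs=1e-9)


class TestRunSimulation:
    def test_observation_window_excludes_burn_in(self, minimal_landscape):
        # a stayer population on saturated patches never migrates: usage
        # tallies count exactly the post-burn-in feeding turtle-steps
        cfg = SimulationConfig(n_turtles=10, steps_total=10, steps_burn_in=5,
                               min_allocation=1, seed=2, s_f=1.0,
                               alpha=0.0, delta_eps_n=1e9)
        out = run_simulation(cfg, minimal_landscape)
        assert out.patch_usage.time_usage.sum() == 10 * 5
        assert len(out.nesting_events) == 0

    def test_zero_current_scenario_two_equals_scenario_one(self,
                                                           minimal_landscape):
        def run(scenario):
            cfg = SimulationConfig(n_turtles=20, steps_total=1000,
                                   steps_burn_in=100, min_allocation=1,
                                   seed=17, scenario=scenario)
            return run_simulation(cfg, minimal_landscape)

        a, b = run(1), run(2)  # the minimal world has zero currents
        pd.testing.assert_frame_equal(a.nesting_events, b.nesting_events)
        pd.testing.assert_frame_equal(a.patch_usage, b.patch_usage)

    def test_higher_nesting_investment_lengthens_remigration(
            self, minimal_landscape):
        def grand_mean(s_n):
            cfg = SimulationConfig(n_turtles=30, steps_total=6000,
                                   steps_burn_in=200, min_allocation=1,
                                   seed=19, s_n=s_n)
            out = run_simulation(cfg, minimal_landscape)
            iv = remigration_intervals(out.nesting_events)
            return iv.mean_interval_years.mean()

        assert grand_mean(0.8) > grand_mean(0.2)


class TestExperiment:
    def test_default_design_enumerates_full_factorial(self):
        design = ExperimentDesign(base_seed=100)
        configs = build_experiment(design)
        assert len(configs) == 240
        assert len({c.seed for c in configs}) == 240
        assert {c.scenario for c in configs} == {1, 2, 3}

    def test_degenerate_design_single_run(self):
        design = ExperimentDesign(scenarios=(1,), s_f_grid=(0.5,),
                                  s_n_grid=(0.5,), replicates=1)
        assert len(build_experiment(design)) == 1

    def test_product_arithmetic(self):
        design = ExperimentDesign(scenarios=(1, 2), s_f_grid=(0.2, 0.8),
                                  s_n_grid=(0.2, 0.5, 0.8), replicates=4)
        assert len(build_experiment(design)) == 48

    def test_scenario_three_requires_perturbation(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario=3)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        from chelonia.seagrass import Perturbation
        cfg = SimulationConfig(n_turtles=123, scenario=3, s_f=0.3,
                               perturbation=Perturbation(-28.0, 0.2, 13.0),
                               seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()

    def test_scaling_preserves_proportions(self):
        cfg = SimulationConfig().scaled(500 / 7_000)
        assert cfg.n_turtles == 500
        assert cfg.min_allocation == 3
        assert cfg.steps_burn_in < cfg.steps_total

    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            SimulationConfig(steps_total=100, steps_burn_in=100)
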