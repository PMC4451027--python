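import math
from dataclasses import replace

import numpy as np
import pytest

from divlabsim import (
    GameSpec,
    IBMConfig,
    Strategy,
    classify_population,
    complementary_cost,
    detect_branching,
    initialize_population,
    make_fixtures,
    mean_payoff,
    play_generation,
    reproduce_and_mutate,
    run_simulation,
)


class TestConfig:
    def test_full_scale_defaults(self):
        cfg = IBMConfig()
        assert cfg.pop_size == 1000
        assert cfg.groups_per_generation == 1000
        assert cfg.bouts == 100
        assert cfg.mutation_prob == 0.1
        assert cfg.epsilon == 0.005
        assert cfg.generations == 150_000
        assert cfg.init_q == 0.5

    def test_expected_games_per_individual(self, game_I):
        cfg = IBMConfig()
        assert cfg.groups_per_generation * game_I.N / cfg.pop_size == 7.0

    def test_desk_scale_keeps_games_ratio(self, game_I):
        cfg = IBMConfig.desk_scale()
        assert cfg.groups_per_generation * game_I.N / cfg.pop_size == 7.0

    def test_validation(self):
        with pytest.raises(ValueError):
            IBMConfig(pop_size=1)
        with pytest.raises(ValueError):
            IBMConfig(mutation_prob=1.5)

    def test_init_c_defaults_to_singular_cost(self, game_I):
        cfg = IBMConfig()
        assert cfg.resolve_init_c(game_I) == pytest.approx(0.25 / 2 ** (1 / 0.15))

    def test_init_c_out_of_range(self, game_I):
        with pytest.raises(ValueError):
            IBMConfig(init_c=0.5).resolve_init_c(game_I)


class TestInitialize:
    def test_monomorphic_state(self, game_I, tiny_ibm_config):
        state = initialize_population(tiny_ibm_config, game_I)
        assert np.all(state.q == 0.5)
        assert np.all(state.c_A == tiny_ibm_config.resolve_init_c(game_I))
        assert state.q.var() == 0.0
        assert np.all(state.fitness == 0.0)
        assert np.all(state.games_played == 0)

    def test_seed_determinism(self, game_I, tiny_ibm_config):
        s1 = initialize_population(tiny_ibm_config, game_I)
        s2 = initialize_population(tiny_ibm_config, game_I)
        play_generation(s1, game_I, tiny_ibm_config)
        play_generation(s2, game_I, tiny_ibm_config)
        np.testing.assert_array_equal(s1.fitness, s2.fitness)

    def test_group_larger_than_population(self, game_I):
        with pytest.raises(ValueError):
            initialize_population(IBMConfig(pop_size=5), game_I)


class TestPlayGeneration:
    def test_pure_A_monomorphic_fitness_exact(self, game_I):
        cfg = IBMConfig.desk_scale(pop_size=60, groups_per_generation=30,
                                   generations=0, init_q=1.0, init_c=0.0, seed=1)
        state = initialize_population(cfg, game_I)
        play_generation(state, game_I, cfg)
        played = state.games_played > 0
        expected = game_I.beta_values()[7] / 7
        np.testing.assert_allclose(state.fitness[played], expected, rtol=1e-12)
        assert np.all(state.fitness[~played] == 0.0)

    def test_python_twin_matches_kernel(self, game_I, tiny_ibm_config):
        s1 = initialize_population(tiny_ibm_config, game_I)
        s2 = initialize_population(tiny_ibm_config, game_I)
        log = []
        play_generation(s1, game_I, tiny_ibm_config)
        play_generation(s2, game_I, tiny_ibm_config, record_groups=log)
        np.testing.assert_array_equal(s1.fitness, s2.fitness)
        np.testing.assert_array_equal(s1.games_played, s2.games_played)
        assert len(log) == tiny_ibm_config.groups_per_generation

    def test_per_group_payout_conservation_model_I(self, game_I, tiny_ibm_config):
        # equal sharing: every logged group pays out exactly beta(i) minus
        # the members' chosen-task costs
        state = initialize_population(replace(tiny_ibm_config, init_q=0.4), game_I)
        log = []
        play_generation(state, game_I, tiny_ibm_config, record_groups=log)
        t = game_I.trade_off
        for rec in log:
            assert len(set(rec["members"])) == game_I.N  # distinct individuals
            costs = sum(state.c_A[m] if task else complementary_cost(state.c_A[m], t)
                        for m, task in zip(rec["members"], rec["tasks"]))
            assert sum(rec["payouts"]) + costs == pytest.approx(rec["beta"], abs=1e-12)
            assert rec["i_A"] == sum(rec["tasks"])

    def test_per_subgroup_payout_conservation_model_II(self, game_II, tiny_ibm_config):
        # per-role sharing (1/2 dropped): each nonempty task subgroup splits
        # the whole beta(i) internally
        state = initialize_population(replace(tiny_ibm_config, init_q=0.4), game_II)
        log = []
        play_generation(state, game_II, tiny_ibm_config, record_groups=log)
        t = game_II.trade_off
        for rec in log:
            gross_a = sum(pay + state.c_A[m]
                          for m, task, pay in zip(rec["members"], rec["tasks"], rec["payouts"])
                          if task)
            gross_b = sum(pay + complementary_cost(state.c_A[m], t)
                          for m, task, pay in zip(rec["members"], rec["tasks"], rec["payouts"])
                          if not task)
            if rec["i_A"] >= 1:
                assert gross_a == pytest.approx(rec["beta"], abs=1e-12)
            if rec["i_A"] <= game_II.N - 1:
                assert gross_b == pytest.approx(rec["beta"], abs=1e-12)

    def test_fitness_is_per_game_average(self, game_I, tiny_ibm_config):
        state = initialize_population(tiny_ibm_config, game_I)
        log = []
        play_generation(state, game_I, tiny_ibm_config, record_groups=log)
        acc = np.zeros(state.size)
        games = np.zeros(state.size)
        for rec in log:
            for m, pay in zip(rec["members"], rec["payouts"]):
                acc[m] += pay
                games[m] += 1
        played = games > 0
        np.testing.assert_allclose(state.fitness[played], acc[played] / games[played],
                                   rtol=1e-12)


class TestReproduceAndMutate:
    def test_zero_epsilon_copies_parent(self, game_I):
        cfg = IBMConfig.desk_scale(pop_size=40, epsilon=0.0, seed=2)
        state = initialize_population(cfg, game_I)
        state.q[:] = np.linspace(0, 1, 40)
        reproduce_and_mutate(state, game_I, cfg)
        assert set(np.round(state.q, 12)) <= set(np.round(np.linspace(0, 1, 40), 12))

    def test_population_size_constant(self, game_I, tiny_ibm_config):
        state = initialize_population(tiny_ibm_config, game_I)
        play_generation(state, game_I, tiny_ibm_config)
        reproduce_and_mutate(state, game_I, tiny_ibm_config)
        assert state.size == tiny_ibm_config.pop_size

    def test_mutant_cost_from_zero_parent(self, game_I):
        # mutation is uniform in u = c**alpha, so one mutation step from a
        # zero-cost parent stays inside [0, epsilon**(1/alpha)]
        bound = 0.02 ** (1 / game_I.trade_off.alpha)
        mutated = []
        for seed in range(100):
            cfg = IBMConfig.desk_scale(pop_size=10, mutation_prob=1.0, bouts=1,
                                       epsilon=0.02, init_q=1.0, init_c=0.0,
                                       seed=seed)
            state = initialize_population(cfg, game_I)
            reproduce_and_mutate(state, game_I, cfg)
            assert np.all(state.c_A <= bound + 1e-15)
            mutated.append(state.c_A.max())
        assert max(mutated) > 0

    def test_trait_bounds_respected(self, game_I):
        cfg = IBMConfig.desk_scale(pop_size=40, mutation_prob=1.0, bouts=5000,
                                   epsilon=0.3, seed=4)
        state = initialize_population(cfg, game_I)
        reproduce_and_mutate(state, game_I, cfg)
        assert np.all((state.q >= 0) & (state.q <= 1))
        assert np.all((state.c_A >= 0) & (state.c_A <= game_I.trade_off.k + 1e-12))

    def test_neutral_drift_martingale(self, game_I):
        # equal fitness, no mutation: the two-strategy composition is a
        # martingale, so the replicate-mean composition stays at the start
        cfg = IBMConfig.desk_scale(pop_size=40, mutation_prob=0.0, bouts=40)
        fracs = []
        for seed in range(300):
            state = initialize_population(replace(cfg, seed=seed), game_I)
            state.q[:20] = 0.0
            state.q[20:] = 1.0
            reproduce_and_mutate(state, game_I, replace(cfg, seed=seed))
            fracs.append(np.mean(state.q < 0.5))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)


class TestRunSimulation:
    def test_zero_generations(self, game_I, tiny_ibm_config):
        traj = run_simulation(replace(tiny_ibm_config, generations=0), game_I)
        assert traj.records.shape[0] == 1
        assert traj.records[0, 0] == 0
        assert traj.verdict.outcome == "undecided"

    def test_bit_identical_replay(self, game_I, tiny_ibm_config):
        t1 = run_simulation(tiny_ibm_config, game_I)
        t2 = run_simulation(tiny_ibm_config, game_I)
        np.testing.assert_array_equal(t1.records, t2.records)
        np.testing.assert_array_equal(t1.final.q, t2.final.q)
        np.testing.assert_array_equal(t1.final.c_A, t2.final.c_A)

    def test_snapshots_reproduce_summaries(self, game_I):
        cfg = IBMConfig.desk_scale(pop_size=60, groups_per_generation=60,
                                   generations=100, record_every=25,
                                   store_snapshots=True, seed=5)
        traj = run_simulation(cfg, game_I)
        assert len(traj.snapshots) == traj.records.shape[0]
        for row, (gen, q, c) in zip(traj.records, traj.snapshots):
            assert row[0] == gen
            assert row[1] == pytest.approx(q.mean(), rel=1e-12)
            assert row[3] == pytest.approx(c.mean(), rel=1e-12)

    def test_monomorphic_fitness_matches_analytic(self, game_I):
        # mutation off: realised mean fitness estimates the analytic expected
        # payoff of the monomorphic strategy
        cfg = IBMConfig(pop_size=300, groups_per_generation=300, bouts=0,
                        mutation_prob=0.0, generations=0, seed=6)
        state = initialize_population(cfg, game_I)
        q0, c0 = 0.5, cfg.resolve_init_c(game_I)
        means = []
        for _ in range(150):
            play_generation(state, game_I, cfg)
            means.append(state.fitness[state.games_played > 0].mean())
        expected = mean_payoff(Strategy(q0, c0), q0, game_I)
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 3 * se


class TestDetectBranching:
    def test_monomorphic_is_not_branched(self):
        v = classify_population(np.full(100, 0.5))
        assert v.outcome == "undecided"

    def test_bimodal_is_branched(self):
        q = np.concatenate([np.full(50, 0.02), np.full(50, 0.98)])
        assert classify_population(q).outcome == "branched"

    def test_fixture_population(self):
        pop = make_fixtures("bimodal_population", seed=1)
        v = detect_branching(pop)
        assert v.outcome == "branched"
        assert v.mean_c_low == pytest.approx(0.25)
        assert v.mean_c_high == pytest.approx(0.0)

    def test_near_pure(self):
        q = np.random.default_rng(0).uniform(0.95, 1.0, 100)
        assert classify_population(q).outcome == "near_pure"

    def test_unbalanced_split_not_branched(self):
        q = np.concatenate([np.full(95, 0.02), np.full(5, 0.98)])
        assert classify_population(q).outcome == "near_pure"

    def test_wide_clusters_not_branched(self):
        q = np.concatenate([np.full(50, 0.4), np.full(50, 0.6)])
        assert classify_population(q).outcome == "undecided"

    def test_empty_population_error(self):
        with pytest.raises(ValueError):
            classify_population(np.array([]))

    def test_trajectory_persistence_required(self, game_I, tiny_ibm_config):
        traj = run_simulation(tiny_ibm_config, game_I)
        # hand the trajectory a branched final state but unbranched history
        traj.final.q[:30] = 0.01
        traj.final.q[30:] = 0.99
        v = detect_branching(traj)
        assert v.outcome == "undecided"


class TestBranchingDynamics:
    def test_reference_parameters_branch(self, game_I):
        # one desk-scale run at the branching-enabled parameter set; the full
        # 10-seed majorities live in the acceptance suite
        cfg = IBMConfig.desk_scale(seed=1)
        traj = run_simulation(cfg, game_I)
        assert traj.verdict.outcome == "branched"
        assert traj.verdict.mean_c_low > 0.2  # B-specialists carry c_A near k
        assert traj.verdict.mean_c_high < 0.05

    def test_corner_start_converges_to_corner(self, game_I):
        # inside the corner basin (beyond the unstable pair) the population
        # stays near the pure state
        cfg = IBMConfig.desk_scale(pop_size=200, groups_per_generation=200,
                                   generations=4000, init_q=0.001, init_c=0.25,
                                   seed=7)
        traj = run_simulation(cfg, game_I)
        assert traj.final.q.mean() < 0.1
        assert traj.verdict.outcome in ("near_pure", "undecided")
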