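import math

import numpy as np
import pytest

import ppistab as ps
from ppistab.evolution import build_organism, kimura_probability, organism_model


class TestFitness:
    def test_no_unfolded_load_gives_unit_fitness(self):
        model = ps.ProteomeModel([ps.ProteinRecord("A", 50.0, dG_fold=40.0)], [])
        state = ps.solve_equilibrium(model, ps.SolverOptions(stability_mode="explicit"))
        assert ps.fitness(state, c_scale=1.0) == pytest.approx(1.0, abs=1e-10)

    def test_closed_form(self):
        # a single protein with U = 0.1 nM at c = 1/nM
        model = ps.ProteomeModel([ps.ProteinRecord("A", 0.2, dG_fold=0.0)], [])
        state = ps.solve_equilibrium(model, ps.SolverOptions(stability_mode="explicit"))
        assert state.total_unfolded() == pytest.approx(0.1, rel=1e-8)
        assert ps.fitness(state, c_scale=1.0) == pytest.approx(math.exp(-0.1), rel=1e-8)

    def test_log_fitness_linear_in_load(self):
        # doubling every abundance doubles the unfolded load, so ln(fitness)
        # doubles as well
        logs = []
        for scale in (1.0, 2.0):
            model = ps.ProteomeModel(
                [ps.ProteinRecord("A", 10.0 * scale, dG_fold=1.0),
                 ps.ProteinRecord("B", 6.0 * scale, dG_fold=2.0)],
                [],
            )
            state = ps.solve_equilibrium(
                model, ps.SolverOptions(stability_mode="explicit")
            )
            logs.append(math.log(ps.fitness(state, c_scale=0.5)))
        assert logs[1] == pytest.approx(2.0 * logs[0], rel=1e-8)

    def test_infinite_stability_state_rejected(self):
        model = ps.ProteomeModel([ps.ProteinRecord("A", 10.0)], [])
        state = ps.solve_equilibrium(model)
        with pytest.raises(ValueError):
            ps.fitness(state, c_scale=1.0)


class TestAcceptanceProbability:
    def test_beneficial_always_accepted(self):
        assert ps.acceptance_probability(0.5, 0.9, nu=37.0) == 1.0

    def test_closed_form(self):
        assert ps.acceptance_probability(1.0, 0.99, nu=20.0) == pytest.approx(
            0.99**20, rel=1e-12
        )

    def test_neutral_limit(self):
        assert ps.acceptance_probability(0.9, 0.1, nu=0.0) == 1.0

    def test_invalid_fitness(self):
        with pytest.raises(ValueError):
            ps.acceptance_probability(0.0, 0.5, nu=1.0)

    def test_kimura_limits(self):
        assert kimura_probability(0.5, 0.9, nu=0.0) == 1.0
        # strongly beneficial: fixation approaches 1 - e^{-2s}
        p = kimura_probability(1.0, 1.5, nu=1000.0)
        assert p == pytest.approx(-math.expm1(-1.0), rel=1e-6)
        # deleterious mutations fix with vanishing probability at large nu
        assert kimura_probability(1.0, 0.9, nu=1000.0) < 1e-10


class TestProposeMutation:
    def make_model(self):
        cfg = ps.EvolutionConfig(n_proteins=6, seed=3)
        return organism_model(cfg), cfg

    def test_stability_only_mode_preserves_kds(self):
        model, _ = self.make_model()
        cfg = ps.EvolutionConfig(n_proteins=6, seed=3, p_stability=1.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            mutated = ps.propose_mutation(model, cfg, rng)
            assert [e.K_d for e in mutated.edges] == [e.K_d for e in model.edges]
            changed = [
                (a.id, a.dG_fold, b.dG_fold)
                for a, b in zip(model.proteins, mutated.proteins)
                if a.dG_fold != b.dG_fold
            ]
            assert len(changed) == 1

    def test_exactly_one_change_per_proposal(self):
        model, cfg = self.make_model()
        rng = np.random.default_rng(1)
        for _ in range(50):
            mutated = ps.propose_mutation(model, cfg, rng)
            dg_changes = sum(
                a.dG_fold != b.dG_fold
                for a, b in zip(model.proteins, mutated.proteins)
            )
            kd_changes = sum(
                a.K_d != b.K_d for a, b in zip(model.edges, mutated.edges)
            )
            assert dg_changes + kd_changes == 1

    def test_step_mean_matches_kernel(self):
        model, _ = self.make_model()
        cfg = ps.EvolutionConfig(
            n_proteins=6, seed=3, p_stability=1.0, dG_max=1e9, dG_min=-1e12
        )
        rng = np.random.default_rng(2)
        steps = []
        for _ in range(10_000):
            mutated = ps.propose_mutation(model, cfg, rng)
            for a, b in zip(model.proteins, mutated.proteins):
                if a.dG_fold != b.dG_fold:
                    steps.append(b.dG_fold - a.dG_fold)
        se = cfg.dG_step_sd / math.sqrt(len(steps))
        assert np.mean(steps) == pytest.approx(cfg.dG_step_mean, abs=3 * se)

    def test_reflecting_ceiling(self):
        cfg = ps.EvolutionConfig(n_proteins=2, seed=1, p_stability=1.0, dG_max=15.0)
        model = organism_model(cfg, dG=np.array([14.9, 14.9]))
        rng = np.random.default_rng(3)
        for _ in range(200):
            mutated = ps.propose_mutation(model, cfg, rng)
            assert all(p.dG_fold <= 15.0 for p in mutated.proteins)

    def test_no_edges_with_kd_mutations_is_config_error(self):
        model = ps.ProteomeModel(
            [ps.ProteinRecord("A", 10.0, dG_fold=5.0),
             ps.ProteinRecord("B", 10.0, dG_fold=5.0)],
            [],
        )
        cfg = ps.EvolutionConfig(n_proteins=2, seed=0, p_stability=0.5)
        with pytest.raises(ValueError):
            ps.propose_mutation(model, cfg, np.random.default_rng(0))


class TestRunEvolution:
    def test_same_seed_identical_trajectories(self):
        cfg = ps.EvolutionConfig(n_generations=500, nu=10.0, seed=4)
        a = ps.run_evolution(cfg)
        b = ps.run_evolution(cfg)
        np.testing.assert_array_equal(a.dG_fold, b.dG_fold)
        np.testing.assert_array_equal(a.fitness, b.fitness)

    def test_neutral_chain_accepts_everything(self):
        cfg = ps.EvolutionConfig(n_generations=400, nu=0.0, seed=5)
        traj = ps.run_evolution(cfg)
        assert traj.accepted.all()

    def test_neutral_stability_walk_drifts_at_kernel_velocity(self):
        # with nu = 0 and the ceiling pushed out of reach, dG_fold performs
        # a random walk whose mean step is the kernel mean
        cfg = ps.EvolutionConfig(
            n_generations=4000, nu=0.0, seed=6, p_stability=1.0, dG_max=1e9, dG_min=-1e12
        )
        traj = ps.run_evolution(cfg)
        total_drift = traj.dG_fold[-1].sum() - cfg.n_proteins * cfg.dG_init
        expected = cfg.n_generations * cfg.dG_step_mean
        sd = cfg.dG_step_sd * math.sqrt(cfg.n_generations)
        assert abs(total_drift - expected) < 4 * sd

    def test_selection_beats_drift(self):
        # short runs at small scale: strong selection holds stability far
        # above the neutral walk
        base = dict(n_generations=3000, n_proteins=8, seed=7)
        drift = ps.run_evolution(ps.EvolutionConfig(nu=0.0, **base))
        selected = ps.run_evolution(ps.EvolutionConfig(nu=1e4, **base))
        assert (
            selected.summary()["mean_dG_fold"] > drift.summary()["mean_dG_fold"]
        )

    def test_fitness_in_unit_interval(self):
        cfg = ps.EvolutionConfig(n_generations=300, nu=5.0, seed=8)
        traj = ps.run_evolution(cfg)
        assert np.all(traj.fitness > 0) and np.all(traj.fitness <= 1)

    def test_thinning_controls_recorded_length(self):
        cfg = ps.EvolutionConfig(n_generations=1000, nu=5.0, seed=9, thin=10)
        traj = ps.run_evolution(cfg)
        assert len(traj.generations) == 100

    def test_kimura_rule_runs_and_selects(self):
        cfg = ps.EvolutionConfig(
            n_generations=2000, n_proteins=8, nu=200.0, seed=10, fixation="kimura"
        )
        traj = ps.run_evolution(cfg)
        assert traj.summary()["mean_dG_fold"] > 0


class TestSweep:
    def test_single_nu_rejected(self):
        cfg = ps.EvolutionConfig(seed=0)
        with pytest.raises(ValueError):
            ps.population_size_sweep(cfg, [2.0], replicates=1)

    def test_organism_shared_across_runs(self):
        cfg = ps.EvolutionConfig(n_proteins=10, seed=11)
        edges, C = build_organism(cfg)
        edges2, C2 = build_organism(cfg)
        assert edges == edges2
        np.testing.assert_array_equal(C, C2)

    def test_sweep_table_shape(self):
        cfg = ps.EvolutionConfig(n_generations=300, n_proteins=6, seed=12)
        sweep = ps.population_size_sweep(cfg, [1.0, 100.0], replicates=2)
        assert list(sweep["nu"]) == [1.0, 100.0]
        assert (sweep["n_replicates"] == 2).all()
        assert np.isfinite(sweep["mean_dG_fold"]).all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_proteins": 1},
            {"nu": -1.0},
            {"burn_in_fraction": 0.0},
            {"dG_step_sd": 0.0},
            {"c_scale": 0.0},
            {"edges": [], "p_stability": 0.5},
            {"abundances": [1.0, 2.0], "n_proteins": 3},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ps.EvolutionConfig(**kwargs)
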