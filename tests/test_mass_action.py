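import math

import numpy as np
import pytest

import ppistab as ps
from conftest import small_random_model


class TestAssignKd:
    def test_fixed_rule(self, heterodimer):
        model = ps.assign_kd(heterodimer, rule="fixed", params={"K": 5.0})
        assert all(e.K_d == 5.0 for e in model.edges)

    def test_abundance_recipe_uses_limiting_partner(self):
        model = ps.ProteomeModel(
            [ps.ProteinRecord("A", 100.0), ps.ProteinRecord("B", 40.0)],
            [ps.InteractionEdge("A", "B")],
        )
        out = ps.assign_kd(model, rule="abundance_recipe", params={"alpha": 0.1})
        assert out.edges[0].K_d == pytest.approx(4.0)

    def test_lognormal_seed_determinism(self):
        model = small_random_model(seed=11, n=6)
        a = ps.assign_kd(model, rule="lognormal", seed=42)
        b = ps.assign_kd(model, rule="lognormal", seed=42)
        assert [e.K_d for e in a.edges] == [e.K_d for e in b.edges]

    @pytest.mark.parametrize(
        "rule,params",
        [("nope", {}), ("abundance_recipe", {"alpha": -1}), ("fixed", {"K": 0})],
    )
    def test_bad_arguments(self, heterodimer, rule, params):
        with pytest.raises(ValueError):
            ps.assign_kd(heterodimer, rule=rule, params=params)


class TestSolveEquilibrium:
    def test_heterodimer_closed_form(self, heterodimer, heterodimer_F):
        state = ps.solve_equilibrium(heterodimer)
        np.testing.assert_allclose(state.F, heterodimer_F, rtol=1e-6)
        np.testing.assert_allclose(state.D, [100.0 - heterodimer_F], rtol=1e-6)
        assert state.converged

    def test_isolated_protein_infinite_stability(self):
        model = ps.ProteomeModel([ps.ProteinRecord("A", 50.0)], [])
        state = ps.solve_equilibrium(model)
        assert state.F[0] == pytest.approx(50.0)
        assert state.U[0] == 0.0
        assert len(state.D) == 0

    def test_isolated_protein_marginal_stability_splits_mass(self):
        model = ps.ProteomeModel([ps.ProteinRecord("A", 50.0, dG_fold=0.0)], [])
        state = ps.solve_equilibrium(
            model, ps.SolverOptions(stability_mode="explicit")
        )
        assert state.F[0] == pytest.approx(25.0, rel=1e-8)
        assert state.U[0] == pytest.approx(25.0, rel=1e-8)

    def test_explicit_mode_requires_stabilities(self, heterodimer):
        with pytest.raises(ps.ValidationError, match="dG_fold"):
            ps.solve_equilibrium(
                heterodimer, ps.SolverOptions(stability_mode="explicit")
            )

    def test_missing_kd_rejected(self):
        model = ps.ProteomeModel(
            [ps.ProteinRecord("A", 10.0), ps.ProteinRecord("B", 10.0)],
            [ps.InteractionEdge("A", "B")],
        )
        with pytest.raises(ps.ValidationError, match="K_d"):
            ps.solve_equilibrium(model)

    def test_tight_binding_converges_via_damping(self):
        # equal abundances with K_d far below them make the undamped
        # iteration oscillate between near-0 and near-C
        model = ps.ProteomeModel(
            [ps.ProteinRecord("A", 100.0), ps.ProteinRecord("B", 100.0)],
            [ps.InteractionEdge("A", "B", K_d=1e-3)],
        )
        state = ps.solve_equilibrium(model)
        assert state.converged
        oracle = ps.brute_force_equilibrium(model)
        np.testing.assert_allclose(state.F, oracle.F, rtol=1e-6)

    def test_gauss_seidel_matches_jacobi(self, chain3):
        jac = ps.solve_equilibrium(chain3)
        gs = ps.solve_equilibrium(chain3, ps.SolverOptions(gauss_seidel=True))
        np.testing.assert_allclose(jac.F, gs.F, rtol=1e-6)

    def test_mass_conservation_on_random_networks(self):
        spec = ps.GeneratorSpec(
            n_proteins=50, abundance_log_sd=1.0, stability="normal", seed=0
        )
        for seed in range(20):
            model = ps.generate_proteome(
                ps.GeneratorSpec(
                    n_proteins=50, abundance_log_sd=1.0, stability="normal",
                    seed=seed,
                )
            )
            state = ps.solve_equilibrium(
                model, ps.SolverOptions(stability_mode="explicit")
            )
            assert state.mass_balance_error().max() < 1e-8


class TestBruteForceOracle:
    def test_heterodimer(self, heterodimer, heterodimer_F):
        state = ps.brute_force_equilibrium(heterodimer)
        np.testing.assert_allclose(state.F, heterodimer_F, rtol=1e-8)

    def test_single_protein(self):
        model = ps.ProteomeModel([ps.ProteinRecord("A", 7.0)], [])
        state = ps.brute_force_equilibrium(model)
        assert state.F[0] == pytest.approx(7.0)

    def test_chain_agreement(self, chain3):
        a = ps.solve_equilibrium(chain3)
        b = ps.brute_force_equilibrium(chain3)
        np.testing.assert_allclose(a.F, b.F, rtol=1e-6)

    @pytest.mark.parametrize("stability", ["infinite", "normal"])
    def test_small_random_networks(self, stability):
        mode = "infinite" if stability == "infinite" else "explicit"
        options = ps.SolverOptions(stability_mode=mode)
        for seed in range(25):
            model = small_random_model(seed=seed, n=5, stability=stability)
            a = ps.solve_equilibrium(model, options)
            b = ps.brute_force_equilibrium(model, options)
            np.testing.assert_allclose(a.F, b.F, rtol=1e-6)


class TestMonotonicity:
    def test_weakening_bond_raises_free_concentrations(self, heterodimer):
        F_prev = None
        for kd in (1.0, 5.0, 25.0, 125.0):
            model = ps.assign_kd(heterodimer, rule="fixed", params={"K": kd})
            F = ps.solve_equilibrium(model).F
            if F_prev is not None:
                assert np.all(F > F_prev)
            F_prev = F

    def test_raising_partner_abundance_lowers_own_free_pool(self, star4):
        # sweep the hub's partner S1 abundance upward; hub F must not rise
        F_prev = None
        for c in (50.0, 100.0, 200.0, 400.0):
            proteins = [
                ps.ProteinRecord("H", 100.0),
                ps.ProteinRecord("S1", c),
                *[ps.ProteinRecord(f"S{i}", 100.0) for i in (2, 3, 4)],
            ]
            model = ps.ProteomeModel(proteins, star4.edges)
            F_hub = ps.solve_equilibrium(model).F[0]
            if F_prev is not None:
                assert F_hub < F_prev
            F_prev = F_hub


class TestSolverOptions:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rel_tol": 0.0},
            {"rel_tol": 2.0},
            {"max_iter": 0},
            {"damping": 0.0},
            {"damping": 1.5},
            {"stability_mode": "magic"},
        ],
    )
    def test_invalid_options(self, kwargs):
        with pytest.raises(ValueError):
            ps.SolverOptions(**kwargs)

    def test_nonconvergence_carries_state(self, heterodimer):
        with pytest.raises(ps.ConvergenceError) as err:
            ps.solve_equilibrium(
                heterodimer, ps.SolverOptions(max_iter=2, rel_tol=1e-12)
            )
        assert err.value.state is not None
        assert math.isfinite(err.value.residual)


class TestStabilityModes:
    def test_chain_length_mode(self):
        model = ps.ProteomeModel(
            [ps.ProteinRecord("A", 50.0, length=100)], []
        )
        options = ps.SolverOptions(
            stability_mode="chain_length", chain_intercept=0.0, chain_slope=0.02
        )
        state = ps.solve_equilibrium(model, options)
        # dG = 2 k_BT -> U/F = e^-2
        assert state.U[0] / state.F[0] == pytest.approx(math.exp(-2.0), rel=1e-8)

    def test_minimal_mode_floor_zero_splits_mass(self):
        model = ps.ProteomeModel([ps.ProteinRecord("A", 10.0)], [])
        state = ps.solve_equilibrium(model, ps.SolverOptions(stability_mode="minimal"))
        assert state.F[0] == pytest.approx(5.0, rel=1e-8)
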