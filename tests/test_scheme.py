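import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from breedopt.genome import dosage_matrix, simulate_founders
from breedopt.scheme import (
    Constraints,
    SchemeParams,
    allocate_progeny,
    derive_resources,
    finalize_progeny_allocation,
    fit_genomic_prediction,
    n_selected,
    order_matings,
    run_breeding_scheme,
    weighted_distance,
)
from breedopt.trait import PhenoModel, genotypic_values, make_pheno_model, sample_qtn_effects


class TestNSelected:
    @pytest.mark.parametrize(
        "n_i,intensity,expected",
        [
            (100, 0.05, 5),
            (10, 0.01, 1),  # 0.1 rounds to 0, clamped to strictly positive
            (7, 0.5, 4),  # 3.5 rounds half-up
            (10, 1.0, 10),
            (1, 0.5, 1),
        ],
    )
    def test_examples(self, n_i, intensity, expected):
        assert n_selected(n_i, intensity) == expected

    @settings(max_examples=100, deadline=None)
    @given(n_i=st.integers(1, 500), intensity=st.floats(0.001, 1.0))
    def test_always_in_range(self, n_i, intensity):
        k = n_selected(n_i, intensity)
        assert 1 <= k <= n_i


class TestDeriveResources:
    def test_even_budget_split(self, rng):
        c = Constraints(B=1000, C_p=1, C_n=1, n_gen=5)
        p = SchemeParams(i_init=0.1, i=0.1, b_rep=0.5, pheno_p=1)
        plan = derive_resources(c, p, rng)
        assert plan.n_new_tot == 500
        assert plan.n_P_tot == 500

    def test_phenotyping_generations_period_three(self, rng):
        c = Constraints(B=1000, C_p=1, C_n=1, n_gen=10)
        p = SchemeParams(i_init=0.1, i=0.1, b_rep=0.5, pheno_p=3)
        plan = derive_resources(c, p, rng)
        assert plan.pheno_generations == [1, 4, 7, 10]
        assert np.all(plan.n_P_t[[2, 3, 5, 6, 8, 9]] == 0)

    def test_remainder_distribution(self):
        # 10 plots over 4 phenotyping generations -> permutation of (3,3,2,2)
        c = Constraints(B=20, C_p=1, C_n=1, n_gen=10)
        p = SchemeParams(i_init=0.1, i=0.1, b_rep=0.5, pheno_p=3)
        plan = derive_resources(c, p, np.random.default_rng(0))
        counts = sorted(plan.n_P_t[plan.pheno_generations], reverse=True)
        assert counts == [3, 3, 2, 2]

    def test_first_generation_raised_to_three(self):
        # tiny phenotyping budget: n_P_1 must still be >= 3
        c = Constraints(B=100, C_p=1, C_n=1, n_gen=10)
        p = SchemeParams(i_init=0.1, i=0.1, b_rep=0.93, pheno_p=1)
        for seed in range(10):
            plan = derive_resources(c, p, np.random.default_rng(seed))
            assert plan.n_P_t[1] >= 3
            # compensation keeps the planned total
            assert plan.n_P_t.sum() == plan.n_P_tot

    def test_budget_invariant_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            B = float(rng.uniform(100, 5000))
            c = Constraints(B=B, C_p=float(rng.uniform(0.5, 3)),
                            C_n=float(rng.uniform(0.5, 3)), n_gen=int(rng.integers(1, 12)))
            p = SchemeParams(
                i_init=float(rng.uniform(0.01, 0.9)),
                i=float(rng.uniform(0.01, 0.9)),
                b_rep=float(rng.uniform(0.05, 0.95)),
                pheno_p=int(rng.integers(1, c.n_gen + 1)),
            )
            plan = derive_resources(c, p, rng)
            assert plan.B_eff <= B + 1e-9
            assert B - plan.B_eff < c.C_p + 1e-9

    def test_finalize_progeny_allocation(self, rng):
        c = Constraints(B=1000, C_p=1, C_n=1, n_gen=5)
        p = SchemeParams(i_init=0.1, i=0.1, b_rep=0.5, pheno_p=1)
        plan = derive_resources(c, p, rng)
        finalize_progeny_allocation(plan, 10, rng)
        assert plan.n_new_t[1] == 10
        assert plan.n_new_t[1:].sum() == plan.n_new_tot
        assert plan.n_new_t[2:].max() - plan.n_new_t[2:].min() <= 1


class TestGenomicPrediction:
    def test_ranking_recovery_on_noiseless_data(self):
        # held-out ranking of 50 individuals from noiseless training data;
        # markers are simulated independent (no LD), so near-perfect
        # recovery needs n_train > n_snp
        genome, pop = simulate_founders(650, 5, 500, seed=0)
        arch = sample_qtn_effects(genome, 100, seed=1)
        dos = dosage_matrix(pop).astype(float)
        g = dos @ arch.beta
        model = fit_genomic_prediction(dos[:600], g[:600])
        rho = spearmanr(model.predict(dos[600:]), g[600:]).statistic
        assert rho >= 0.95

    def test_monomorphic_markers_get_zero_effect(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(20, 5)).astype(float)
        X[:, 2] = 2.0  # constant column
        y = rng.normal(size=20)
        model = fit_genomic_prediction(X, y)
        assert model.beta[2] == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_rows_equal_weighted_rows(self):
        # normal-equation oracle on a tiny system, fixed penalty
        X = np.array([[0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
        y = np.array([1.0, 2.0, 3.0])
        dup = fit_genomic_prediction(
            np.vstack([X, X[0]]), np.append(y, y[0]), alpha=1.0
        )
        wtd = fit_genomic_prediction(X, y, sample_weight=np.array([2.0, 1.0, 1.0]), alpha=1.0)
        np.testing.assert_allclose(dup.beta, wtd.beta, atol=1e-8)
        assert dup.intercept == pytest.approx(wtd.intercept, abs=1e-8)
        # independent check against the penalised normal equations
        Xa = np.vstack([X, X[0]])
        ya = np.append(y, y[0])
        xm = Xa.mean(axis=0)
        Xc = Xa - xm
        beta_oracle = np.linalg.solve(Xc.T @ Xc + 1.0 * np.eye(2), Xc.T @ (ya - ya.mean()))
        np.testing.assert_allclose(dup.beta, beta_oracle, atol=1e-8)

    def test_degenerate_targets_yield_zero_model(self):
        X = np.eye(3)
        model = fit_genomic_prediction(X, np.array([2.0, 2.0, 2.0]))
        np.testing.assert_array_equal(model.beta, np.zeros(3))
        assert model.intercept == 2.0

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            fit_genomic_prediction(np.eye(2), np.array([1.0, 2.0]))


class TestWeightedDistance:
    def test_identical_is_zero(self):
        g = np.array([0.0, 2.0, 1.0])
        assert weighted_distance(g, g, np.array([1.0, 2.0, 3.0])) == 0.0

    def test_hand_arithmetic(self):
        d = weighted_distance(np.array([0.0, 2.0]), np.array([2.0, 2.0]), np.array([1.0, 2.0]))
        assert d == pytest.approx(2.0)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b, w = rng.normal(size=(3, 6))
            assert weighted_distance(a, b, w) == pytest.approx(weighted_distance(b, a, w))


class TestOrderMatings:
    def test_single_parent_selfs(self, rng):
        table = order_matings(["p"], np.zeros((1, 4)), np.zeros(4), rng)
        assert table.mothers == ["p"] and table.fathers == ["p"]

    def test_three_parents_all_pairs(self, rng):
        table = order_matings(["a", "b", "c"], np.eye(3), np.ones(3), rng)
        pairs = {frozenset(p) for p in zip(table.mothers, table.fathers)}
        assert pairs == {frozenset("ab"), frozenset("ac"), frozenset("bc")}
        assert table.n_crosses == 3

    def test_two_parents_one_cross(self, rng):
        table = order_matings(["a", "b"], np.eye(2), np.ones(2), rng)
        assert table.n_crosses == 1

    def test_tsp_within_five_percent_of_optimum(self, rng):
        # exhaustive-permutation oracle over all 6-city tours
        n, m = 6, 10
        dosages = rng.integers(0, 3, size=(n, m)).astype(float)
        beta = rng.normal(size=m)
        ids = [f"p{k}" for k in range(n)]
        table = order_matings(ids, dosages, beta, rng)
        assert table.n_crosses == n

        weighted = dosages * beta
        D = np.linalg.norm(weighted[:, None] - weighted[None, :], axis=2)
        W = 1.0 / np.clip(D, 1e-12, None)

        def tour_cost(order):
            return sum(W[order[k], order[(k + 1) % n]] for k in range(n))

        best = min(tour_cost(perm) for perm in itertools.permutations(range(n)))
        got_order = [ids.index(mid) for mid in table.mothers]
        assert tour_cost(got_order) <= 1.05 * best

    def test_large_tsp_beats_random_order(self, rng):
        n, m = 30, 20
        dosages = rng.integers(0, 3, size=(n, m)).astype(float)
        beta = rng.normal(size=m)
        ids = [str(k) for k in range(n)]
        weighted = dosages * beta
        D = np.linalg.norm(weighted[:, None] - weighted[None, :], axis=2)
        W = 1.0 / np.clip(D, 1e-12, None)
        table = order_matings(ids, dosages, beta, rng)
        got_order = np.array([ids.index(mid) for mid in table.mothers])
        got = W[got_order, np.roll(got_order, -1)].sum()
        random_costs = []
        for _ in range(50):
            perm = rng.permutation(n)
            random_costs.append(W[perm, np.roll(perm, -1)].sum())
        assert got <= np.median(random_costs)


class TestAllocateProgeny:
    @pytest.mark.parametrize(
        "n_c,n_new,expected_sorted",
        [(3, 10, [3, 3, 4]), (5, 5, [1, 1, 1, 1, 1]), (4, 2, [0, 0, 1, 1])],
    )
    def test_examples(self, n_c, n_new, expected_sorted, rng):
        counts = allocate_progeny(n_c, n_new, rng)
        assert sorted(counts) == expected_sorted
        assert counts.sum() == n_new


def _study(seed=0, h2=0.7, n_ind=60, n_snp=120, n_qtn=40, n_chr=4):
    genome, founders = simulate_founders(n_ind, n_chr, n_snp, seed=seed)
    arch = sample_qtn_effects(genome, n_qtn, seed=seed + 1)
    g0 = genotypic_values(founders, arch)
    return genome, founders, arch, make_pheno_model(g0, h2), g0


class TestRunBreedingScheme:
    def test_same_seed_bit_identical(self):
        genome, founders, arch, pm, _ = _study()
        c = Constraints(B=400, C_p=1, C_n=1, n_gen=3)
        p = SchemeParams(i_init=0.2, i=0.2, b_rep=0.5, pheno_p=1)
        r1 = run_breeding_scheme(c, p, genome, founders, arch, pm, seed=99)
        r2 = run_breeding_scheme(c, p, genome, founders, arch, pm, seed=99)
        assert r1.u == r2.u
        assert r1.trajectory == r2.trajectory
        np.testing.assert_array_equal(
            r1.final_population.haplotypes, r2.final_population.haplotypes
        )

    def test_selection_gains_with_zero_noise(self):
        # noiseless phenotypes + meaningful selection should improve the mean
        genome, founders, arch, _, g0 = _study(seed=4)
        pm = PhenoModel(sigma_e2=0.0, target_H2=0.99)
        c = Constraints(B=500, C_p=1, C_n=1, n_gen=5)
        p = SchemeParams(i_init=0.1, i=0.2, b_rep=0.5, pheno_p=1)
        wins = 0
        for seed in range(30):
            r = run_breeding_scheme(c, p, genome, founders, arch, pm, seed=seed)
            wins += r.u > g0.mean()
        assert wins >= 28

    def test_objective_equals_final_population_mean(self):
        genome, founders, arch, pm, _ = _study(seed=7)
        c = Constraints(B=300, C_p=1, C_n=1, n_gen=3)
        p = SchemeParams(i_init=0.3, i=0.3, b_rep=0.6, pheno_p=2)
        r = run_breeding_scheme(c, p, genome, founders, arch, pm, seed=1)
        recomputed = float(np.mean(dosage_matrix(r.final_population) @ arch.beta))
        assert r.u == recomputed

    def test_trajectory_length(self):
        genome, founders, arch, pm, _ = _study(seed=8)
        c = Constraints(B=400, C_p=1, C_n=1, n_gen=4)
        p = SchemeParams(i_init=0.2, i=0.2, b_rep=0.5, pheno_p=1)
        r = run_breeding_scheme(c, p, genome, founders, arch, pm, seed=2)
        if not r.terminated_early:
            assert len(r.trajectory) == c.n_gen + 1

    def test_generation_one_progeny_equals_cross_count(self):
        genome, founders, arch, pm, _ = _study(seed=9)
        c = Constraints(B=600, C_p=1, C_n=1, n_gen=3)
        p = SchemeParams(i_init=0.2, i=0.2, b_rep=0.5, pheno_p=1)
        r = run_breeding_scheme(c, p, genome, founders, arch, pm, seed=3)
        # n_S_1 = 12 parents -> TSP tour -> 12 crosses -> 12 gen-1 offspring
        assert r.plan.n_new_t[1] == r.plan.n_S_t[1]

    def test_tiny_new_budget_terminates_early(self):
        genome, founders, arch, pm, _ = _study(seed=10)
        c = Constraints(B=200, C_p=1, C_n=1, n_gen=5)
        # nearly all budget on phenotyping: few new individuals
        p = SchemeParams(i_init=0.9, i=0.9, b_rep=0.05, pheno_p=1)
        r = run_breeding_scheme(c, p, genome, founders, arch, pm, seed=4)
        assert len(r.trajectory) >= 1
        assert np.isfinite(r.u)

    def test_selected_parents_beat_population_mean_under_zero_noise(self):
        # with perfect phenotypes the top-predicted set has above-average truth
        genome, founders, arch, _, g0 = _study(seed=11)
        pm = PhenoModel(sigma_e2=0.0, target_H2=0.99)
        c = Constraints(B=400, C_p=1, C_n=1, n_gen=2)
        p = SchemeParams(i_init=0.1, i=0.1, b_rep=0.5, pheno_p=1)
        r = run_breeding_scheme(c, p, genome, founders, arch, pm, seed=5)
        assert r.trajectory[1] > g0.mean()
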