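"""Step operators: replicator, MWU, linkage, diploid, Baum–Eagon."""

import math

import numpy as np
import pytest

import repdyn as rd
from repdyn.replicator_dynamics import StepSizeError
from conftest import random_distribution, random_profile


class TestAsexualStep:
    def test_two_genotype_hand_example(self):
        space = rd.GenotypeSpace((2,))
        w = rd.FitnessLandscape(space, np.array([0.8, 0.4]))
        d = rd.GenotypeDistribution(space, np.array([0.5, 0.5]))
        out = rd.asexual_step(d, w)
        assert np.allclose(out.weights, [2 / 3, 1 / 3], atol=1e-15)

    def test_constant_fitness_is_a_fixed_point(self, space_2x2):
        w = rd.FitnessLandscape(space_2x2, np.full(4, 0.3))
        rng = np.random.default_rng(0)
        d = random_distribution(space_2x2, rng)
        assert np.allclose(rd.asexual_step(d, w).weights, d.weights, atol=1e-15)

    def test_point_masses_are_fixed_points(self, rainy):
        for g in rainy.space.genotypes():
            d = rd.GenotypeDistribution.point_mass(rainy.space, g)
            assert np.allclose(rd.asexual_step(d, rainy).weights, d.weights)

    def test_zero_fitness_support_vanishes(self):
        space = rd.GenotypeSpace((2,))
        w = rd.FitnessLandscape(space, np.array([1.0, 0.0]))
        d = rd.GenotypeDistribution(space, np.array([0.5, 0.5]))
        assert np.allclose(rd.asexual_step(d, w).weights, [1.0, 0.0])

    def test_extinction_raises(self):
        space = rd.GenotypeSpace((2,))
        w = rd.FitnessLandscape(space, np.array([0.0, 1.0]))
        d = rd.GenotypeDistribution.point_mass(space, (0,))
        with pytest.raises(rd.ExtinctionError):
            rd.asexual_step(d, w)


class TestMWU:
    def test_parameter_free_on_fitness_is_the_replicator(self, rainy):
        rng = np.random.default_rng(2)
        d = random_distribution(rainy.space, rng)
        via_mwu = rd.mwu_polynomial_step(d.weights, rainy.values, "parameter-free")
        via_replicator = rd.asexual_step(d, rainy).weights
        assert np.allclose(via_mwu, via_replicator, atol=1e-15)

    def test_hand_example_eta_one(self):
        out = rd.mwu_polynomial_step([0.5, 0.5], [1.0, 0.0], 1.0)
        assert np.allclose(out, [2 / 3, 1 / 3], atol=1e-15)

    def test_small_eta_barely_perturbs(self):
        d = np.array([0.4, 0.6])
        out = rd.mwu_polynomial_step(d, [1.0, -1.0], 1e-9)
        assert np.max(np.abs(out - d)) < 1e-8

    def test_too_large_eta_raises(self):
        with pytest.raises(StepSizeError):
            rd.mwu_polynomial_step([0.5, 0.5], [-2.0, 1.0], 1.0)

    def test_hedge_on_log_fitness_is_the_replicator(self, rainy):
        rng = np.random.default_rng(4)
        d = random_distribution(rainy.space, rng)
        eta = 0.7
        ell = np.log(rainy.values) / eta
        via_hedge = rd.mwu_exponential_step(d.weights, ell, eta)
        assert np.allclose(via_hedge, rd.asexual_step(d, rainy).weights, atol=1e-12)

    def test_hedge_constant_payoffs_are_identity(self):
        d = np.array([0.2, 0.3, 0.5])
        assert np.allclose(rd.mwu_exponential_step(d, [5.0, 5.0, 5.0], 2.0), d)

    def test_hedge_is_shift_invariant(self):
        d = np.array([0.2, 0.8])
        ell = np.array([3.0, -1.0])
        a = rd.mwu_exponential_step(d, ell, 0.5)
        b = rd.mwu_exponential_step(d, ell + 1000.0, 0.5)
        assert np.allclose(a, b, atol=1e-15)


class TestHaploidStep:
    def test_uniform_rainy_one_step_locus_frequencies(self, rainy):
        q = rd.AllelicProfile.uniform(rainy.space)
        out = rd.haploid_step(q, rainy)
        wbar = 4.99 / 9
        expect0 = np.array([0.60, 1.78 / 3, 0.47]) / 3 / wbar
        expect1 = np.array([0.36, 1.66 / 3, 0.75]) / 3 / wbar
        assert np.allclose(out.freqs[0], expect0, atol=1e-12)
        assert np.allclose(out.freqs[1], expect1, atol=1e-12)

    def test_point_mass_profile_is_fixed(self, rainy):
        q = rd.AllelicProfile.point_mass(rainy.space, (1, 1))
        out = rd.haploid_step(q, rainy)
        for a, b in zip(out.freqs, q.freqs):
            assert np.allclose(a, b)

    def test_single_locus_reduces_to_asexual(self):
        space = rd.GenotypeSpace((4,))
        w = rd.random_landscape(space, seed=9)
        rng = np.random.default_rng(9)
        d = random_distribution(space, rng)
        q = rd.project_rho(d)
        assert np.allclose(
            rd.haploid_step(q, w).freqs[0], rd.asexual_step(d, w).weights, atol=1e-14
        )


class TestT1Step:
    def test_output_is_in_linkage_equilibrium(self, rainy):
        rng = np.random.default_rng(1)
        d = random_distribution(rainy.space, rng)
        assert rd.linkage_deviation(rd.t1_step(d, rainy)) < 1e-14

    def test_composition_of_projection_haploid_lift(self, rainy):
        d = rd.GenotypeDistribution.uniform(rainy.space)
        expected = rd.lift_rho_inverse(
            rd.haploid_step(rd.project_rho(d), rainy)
        )
        assert np.allclose(rd.t1_step(d, rainy).weights, expected.weights, atol=1e-15)


class TestLinkagePartitions:
    @pytest.mark.parametrize("seed", range(5))
    def test_coarsest_partition_is_asexual(self, seed):
        space = rd.GenotypeSpace((2, 3, 2))
        w = rd.random_landscape(space, seed=seed)
        rng = np.random.default_rng(seed)
        d = random_distribution(space, rng)
        lam = rd.Partition.coarsest(3)
        assert np.allclose(
            rd.lambda_step(d, w, lam).weights, rd.asexual_step(d, w).weights, atol=1e-14
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_finest_partition_is_free_recombination_from_linkage_equilibrium(self, seed):
        # the identity with ρ⁻¹∘τ∘ρ holds on linkage-equilibrium states,
        # where the lift's marginal fitnesses are the distribution's own
        space = rd.GenotypeSpace((2, 3, 2))
        w = rd.random_landscape(space, seed=seed)
        rng = np.random.default_rng(seed + 100)
        d = rd.lift_rho_inverse(random_profile(space, rng))
        lam = rd.Partition.finest(3)
        assert np.allclose(
            rd.lambda_step(d, w, lam).weights, rd.t1_step(d, w).weights, atol=1e-14
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_one_step_allelic_marginals_are_linkage_independent(self, seed):
        # block marginalisation commutes with locus marginalisation, so the
        # post-step allele frequencies agree across all partitions
        space = rd.GenotypeSpace((2, 2, 3))
        w = rd.random_landscape(space, seed=seed)
        rng = np.random.default_rng(seed)
        d = random_distribution(space, rng)
        partitions = [
            rd.Partition.coarsest(3),
            rd.Partition.finest(3),
            rd.Partition(((0, 1), (2,))),
            rd.Partition(((0, 2), (1,))),
        ]
        reference = rd.project_rho(rd.lambda_step(d, w, partitions[0]))
        for lam in partitions[1:]:
            q = rd.project_rho(rd.lambda_step(d, w, lam))
            for a, b in zip(q.freqs, reference.freqs):
                assert np.max(np.abs(a - b)) < 1e-12

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            rd.Partition(((0, 1), (1, 2)))  # overlapping
        with pytest.raises(ValueError):
            rd.Partition(((0,), (2,)))  # gap


class TestRecombinationTuple:
    def test_degenerate_tuple_is_t1(self, rainy):
        rng = np.random.default_rng(0)
        d = rd.lift_rho_inverse(random_profile(rainy.space, rng))
        r = rd.RecombinationTuple({rd.Partition.finest(2): 1.0})
        assert np.allclose(
            rd.recombination_tuple_step(d, rainy, r).weights,
            rd.t1_step(d, rainy).weights,
            atol=1e-15,
        )

    @pytest.mark.parametrize("rate", [0.0, 0.25, 0.5, 1.0])
    def test_two_point_tuple_matches_convex_combination(self, rainy, rate):
        rng = np.random.default_rng(3)
        d = rd.lift_rho_inverse(random_profile(rainy.space, rng))
        tup = rd.RecombinationTuple.two_point(2, rate)
        combo = rate * rd.t1_step(d, rainy).weights + (1 - rate) * rd.asexual_step(d, rainy).weights
        assert np.allclose(rd.recombination_tuple_step(d, rainy, tup).weights, combo, atol=1e-14)

    def test_half_rate_on_linked_start_constant_fitness(self, space_2x2):
        w = rd.FitnessLandscape(space_2x2, np.ones(4))
        d = rd.GenotypeDistribution(space_2x2, np.array([0.5, 0.0, 0.0, 0.5]))
        tup = rd.RecombinationTuple.two_point(2, 0.5)
        out = rd.recombination_tuple_step(d, w, tup)
        assert np.allclose(out.weights, [0.375, 0.125, 0.125, 0.375], atol=1e-15)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            rd.RecombinationTuple({rd.Partition.finest(2): 0.5})


class TestDiploidSingle:
    def test_constant_matrix_is_identity(self):
        W = rd.DiploidLandscape(np.full((3, 3), 0.4))
        p = np.array([0.2, 0.3, 0.5])
        assert np.allclose(rd.diploid_single_step(p, W), p, atol=1e-15)

    def test_heterozygote_advantage_jumps_to_interior_equilibrium(self, hetero):
        out = rd.diploid_single_step(np.array([0.8, 0.2]), hetero)
        assert np.allclose(out, [0.5, 0.5], atol=1e-15)

    def test_symmetric_unstable_fixed_point(self):
        W = rd.DiploidLandscape(np.eye(2))
        assert np.allclose(rd.diploid_single_step(np.array([0.5, 0.5]), W), [0.5, 0.5])

    def test_equilibrium_finder_on_heterozygote_advantage(self, hetero):
        eqs = rd.diploid_equilibria(hetero, seed=0)
        stable = [e for e in eqs if e["stability"] == "stable"]
        assert len(stable) == 1
        assert np.allclose(stable[0]["p"], [0.5, 0.5], atol=1e-12)
        assert stable[0]["kind"] == "mixed"

    def test_equilibrium_finder_on_dominant_homozygote(self):
        W = rd.DiploidLandscape(np.array([[1.0, 0.5], [0.5, 0.2]]))
        eqs = rd.diploid_equilibria(W, seed=0)
        stable = [e for e in eqs if e["stability"] == "stable"]
        assert len(stable) == 1
        assert np.allclose(stable[0]["p"], [1.0, 0.0])


class TestDiploidTwoLocus:
    @pytest.fixture
    def gamete_space(self):
        return rd.GenotypeSpace((2, 2))

    def test_no_recombination_equals_gamete_level_replicator(self, gamete_space):
        rng = np.random.default_rng(8)
        W = rd.DiploidLandscape(rng.random((4, 4)))
        x = rng.dirichlet(np.ones(4))
        state = rd.GameteState(gamete_space, x, W)
        nxt, D = rd.diploid_two_locus_step(state, 0.0)
        Wg = W.values @ x
        expect = x * Wg / (x @ Wg)
        assert np.allclose(nxt.frequencies, expect, atol=1e-14)
        assert np.max(np.abs(D)) < 1e-15

    def test_neutral_linkage_equilibrium_is_fixed_for_any_rate(self, gamete_space):
        W = rd.DiploidLandscape(np.ones((4, 4)))
        q = rd.AllelicProfile(gamete_space, (np.array([0.3, 0.7]), np.array([0.6, 0.4])))
        x = rd.lift_rho_inverse(q).weights
        for r in (0.0, 0.3, 1.0):
            nxt, _ = rd.diploid_two_locus_step(rd.GameteState(gamete_space, x, W), r)
            assert np.allclose(nxt.frequencies, x, atol=1e-14)

    def test_full_recombination_neutral_gives_product_of_marginals(self, gamete_space):
        W = rd.DiploidLandscape(np.ones((4, 4)))
        state = rd.GameteState(gamete_space, np.array([0.5, 0.0, 0.0, 0.5]), W)
        nxt, D = rd.diploid_two_locus_step(state, 1.0)
        assert np.allclose(nxt.frequencies, [0.25, 0.25, 0.25, 0.25], atol=1e-15)
        assert D[0] == pytest.approx(0.25, abs=1e-15)

    @pytest.mark.parametrize("r", [0.1, 0.5, 0.9])
    def test_neutral_linkage_deviation_decays_geometrically(self, gamete_space, r):
        W = rd.DiploidLandscape(np.ones((4, 4)))
        x = np.array([0.5, 0.0, 0.0, 0.5])
        dev = rd.linkage_deviation(rd.GenotypeDistribution(gamete_space, x))
        for _ in range(5):
            state = rd.GameteState(gamete_space, x, W)
            state, _ = rd.diploid_two_locus_step(state, r)
            x = state.frequencies
            new_dev = rd.linkage_deviation(rd.GenotypeDistribution(gamete_space, x))
            assert new_dev == pytest.approx((1 - r) * dev, abs=1e-13)
            dev = new_dev


class TestBaumEagon:
    def test_multilinear_mean_fitness_polynomial_is_haploid_step(self, rainy):
        rng = np.random.default_rng(3)
        q = random_profile(rainy.space, rng)
        U = rd.mean_fitness_polynomial(rainy)
        via_be = rd.baum_eagon_step(q, U)
        via_haploid = rd.haploid_step(q, rainy)
        for a, b in zip(via_be.freqs, via_haploid.freqs):
            assert np.max(np.abs(a - b)) < 1e-13

    def test_quadratic_diploid_polynomial_is_diploid_step(self, hetero):
        W = rd.DiploidLandscape(np.array([[0.2, 1.0], [1.0, 0.4]]))
        U = rd.diploid_mean_fitness_polynomial(W)
        p = np.array([0.7, 0.3])
        via_be = rd.baum_eagon_step((p,), U)[0]
        assert np.allclose(via_be, rd.diploid_single_step(p, W), atol=1e-14)

    def test_linear_polynomial_is_asexual_step(self):
        space = rd.GenotypeSpace((3,))
        w = rd.FitnessLandscape(space, np.array([0.3, 0.9, 0.6]))
        U = rd.mean_fitness_polynomial(w)
        d = np.array([0.2, 0.5, 0.3])
        out = rd.baum_eagon_step((d,), U)[0]
        expect = rd.asexual_step(rd.GenotypeDistribution(space, d), w).weights
        assert np.allclose(out, expect, atol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_polynomial_never_decreases_along_updates(self, seed):
        space = rd.GenotypeSpace((3, 2))
        w = rd.random_landscape(space, seed=seed)
        U = rd.mean_fitness_polynomial(w)
        rng = np.random.default_rng(seed)
        q = random_profile(space, rng)
        freqs = q.freqs
        prev = U.value(freqs)
        for _ in range(50):
            freqs = rd.baum_eagon_step(freqs, U)
            val = U.value(freqs)
            assert val >= prev - 1e-12
            prev = val
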