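"""Bayes factors, configuration priors, the unexplored-mass DP, the adaptive
search and signal clustering."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from famfine.conditional_genotypes import FactorCoding
from famfine.dapg import (
    PriorSpec,
    adaptive_dap,
    build_clusters,
    log10_bf,
    log10_esp,
    log10sumexp,
    model_log10_prior,
    unexplored_mass,
)
from famfine.fbat_score import ZPanel
from famfine.simulate import simulate_summary_panel


def make_panel(z, R):
    z = np.asarray(z, dtype=float)
    p = len(z)
    return ZPanel(
        factors=[FactorCoding(f"v{i + 1}", "additive") for i in range(p)],
        names=[f"v{i + 1}:add:B" for i in range(p)],
        z=z,
        R=np.asarray(R, dtype=float),
        n_informative=np.zeros(p, dtype=int),
        U=np.full(p, np.nan),
        V=np.full(p, np.nan),
        p_values=np.full(p, np.nan),
    )


def random_correlation(rng, p):
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T + 0.5 * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def gaussian_density_ratio_oracle(z, R, S, phi2, weights):
    """BF as the explicit ratio of the two zero-mean Gaussian densities of
    the full z vector, mixing over the effect-variance grid."""
    p = len(z)
    null = multivariate_normal(mean=np.zeros(p), cov=R, allow_singular=True)
    bfs = []
    for p2 in phi2:
        cols = R[:, S]
        alt_cov = R + p2 * cols @ cols.T
        alt = multivariate_normal(mean=np.zeros(p), cov=alt_cov, allow_singular=True)
        bfs.append((alt.logpdf(z) - null.logpdf(z)) / math.log(10.0))
    return log10sumexp(np.log10(weights) + np.array(bfs))


class TestBayesFactor:
    def test_null_subset_is_zero(self):
        panel = make_panel([1.0, 2.0], np.eye(2))
        assert log10_bf([], panel, PriorSpec.default(2)) == 0.0

    def test_single_factor_z0_closed_form(self):
        panel = make_panel([0.0, 1.0], np.eye(2))
        prior = PriorSpec.default(2, phi2=1.0)
        expected = -0.5 * math.log10(2.0)
        assert log10_bf([0], panel, prior) == pytest.approx(expected, abs=1e-12)

    def test_two_factor_example_against_density_ratio(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        panel = make_panel([5.0, 4.0], R)
        prior = PriorSpec.default(2, phi2=0.64)
        oracle = gaussian_density_ratio_oracle(
            panel.z, R, [0, 1], prior.phi2, prior.phi2_weights
        )
        assert log10_bf([0, 1], panel, prior) == pytest.approx(oracle, abs=1e-9)

    def test_random_subsets_match_density_ratio(self, rng):
        """Random (z, R, φ²) draws: closed form equals the direct
        two-Gaussian log-density ratio, including grid mixing."""
        for _ in range(30):
            p = int(rng.integers(2, 7))
            R = random_correlation(rng, p)
            z = rng.normal(0, 2, p)
            panel = make_panel(z, R)
            k = int(rng.integers(1, p + 1))
            S = sorted(rng.choice(p, size=k, replace=False))
            if rng.random() < 0.5:
                prior = PriorSpec.default(p, phi2=float(rng.uniform(0.05, 2.0)))
            else:
                prior = PriorSpec.default(p)
            oracle = gaussian_density_ratio_oracle(
                z, R, S, prior.phi2, prior.phi2_weights
            )
            assert log10_bf(S, panel, prior) == pytest.approx(oracle, abs=1e-9)


class TestModelPrior:
    def test_singleton_default_prior(self):
        prior = PriorSpec.default(10)
        expected = math.log10(0.1) + 9 * math.log10(0.9)
        assert model_log10_prior([3], prior) == pytest.approx(expected, abs=1e-12)

    def test_null_default_prior(self):
        prior = PriorSpec.default(10)
        assert model_log10_prior([], prior) == pytest.approx(
            10 * math.log10(0.9), abs=1e-12
        )

    def test_factor_specific_prior_hand_computation(self):
        pi = np.array([0.2, 0.05, 0.5])
        prior = PriorSpec(pi, np.array([0.1]))
        expected = (
            math.log10(0.2) + math.log10(1 - 0.05) + math.log10(0.5)
        )
        assert model_log10_prior([0, 2], prior) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(np.array([0.5, 1.0]), np.array([0.1]))


class TestUnexploredMass:
    def test_all_size1_explored_gives_no_mass(self, rng):
        phi = rng.uniform(-1, 2, 5)
        explored = [frozenset((i,)) for i in range(5)]
        assert unexplored_mass(1, phi, explored, 0.0) == -np.inf

    def test_size1_equals_excluded_sum(self, rng):
        phi = rng.uniform(-1, 2, 5)
        explored = [frozenset((0,)), frozenset((3,))]
        expected = log10sumexp([phi[1], phi[2], phi[4]])
        assert unexplored_mass(1, phi, explored, 0.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_pairs_match_bruteforce(self, rng):
        phi = rng.uniform(-2, 3, 6)
        explored = [frozenset((0, 1)), frozenset((2, 3))]
        brute = log10sumexp(
            [
                phi[i] + phi[j]
                for i, j in itertools.combinations(range(6), 2)
                if frozenset((i, j)) not in explored
            ]
        )
        assert unexplored_mass(2, phi, explored, -0.3) == pytest.approx(
            brute - 0.3, abs=1e-9
        )

    def test_k_above_p_is_empty(self, rng):
        phi = rng.uniform(0, 1, 3)
        assert unexplored_mass(4, phi, [], 0.0) == -np.inf

    def test_dp_matches_bruteforce_up_to_k3(self, rng):
        """Elementary-symmetric DP equals exhaustive subset enumeration for
        p <= 10, k <= 3 (log-space agreement)."""
        for p in (4, 7, 10):
            phi = rng.uniform(-3, 3, p)
            esp = log10_esp(phi, 3)
            for k in (1, 2, 3):
                brute = log10sumexp(
                    [
                        float(sum(phi[list(c)]))
                        for c in itertools.combinations(range(p), k)
                    ]
                )
                assert esp[k] == pytest.approx(brute, abs=1e-9)


class TestAdaptiveSearch:
    def test_single_factor_closed_form(self):
        panel = make_panel([3.0], np.eye(1))
        prior = PriorSpec(np.array([0.1]), np.array([0.5]))
        res = adaptive_dap(panel, prior, k_max=1)
        bf = 10.0 ** log10_bf([0], panel, prior)
        expected = 0.1 * bf / (0.1 * bf + 0.9)
        assert res.pips[0] == pytest.approx(expected, abs=1e-12)

    def test_invalid_lambda(self):
        panel = make_panel([1.0, 2.0], np.eye(2))
        with pytest.raises(ValueError):
            adaptive_dap(panel, lambda_=0.0)
        with pytest.raises(ValueError):
            adaptive_dap(panel, lambda_=-1.0)

    def test_deterministic(self):
        panel, _ = simulate_summary_panel(10, 1, seed=5)
        r1 = adaptive_dap(panel)
        r2 = adaptive_dap(panel)
        assert np.array_equal(r1.pips, r2.pips)
        assert [m.factor_index_set for m in r1.models] == [
            m.factor_index_set for m in r2.models
        ]

    def test_monotone_exploration_in_lambda(self):
        """Explored-model sets are nested across λ = 0.097 ⊂ 1.3 ⊂ 2.0."""
        for seed in range(8):
            panel, _ = simulate_summary_panel(15, 2, seed=seed, effect_scale=4.0)
            sets = []
            for lam in (0.097, 1.3, 2.0):
                res = adaptive_dap(panel, lambda_=lam, k_max=4)
                sets.append({m.factor_index_set for m in res.models})
            assert sets[0] <= sets[1] <= sets[2]

    def test_proxy_symmetry(self):
        """Two factors with identical columns (r = 1) receive equal PIPs."""
        R = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]])
        from famfine.fbat_score import regularize_correlation

        Rreg = regularize_correlation(R)
        panel = make_panel([4.0, 4.0, 0.5], Rreg)
        res = adaptive_dap(panel, lambda_=3.0)
        assert res.pips[0] == pytest.approx(res.pips[1], abs=1e-9)

    def test_null_panel_dominated_by_null_model(self):
        p = 8
        panel = make_panel(np.zeros(p), np.eye(p))
        prior = PriorSpec.default(p, phi2=1.0)
        res = adaptive_dap(panel, prior)
        best = res.models[0]
        assert best.factor_index_set == ()
        bf_max = max(10.0 ** m.log10_bf for m in res.models if len(m.factor_index_set) == 1)
        assert bf_max <= 1.0
        # with identity R the posterior factorizes: each PIP is the exact
        # two-model posterior, which is < pi (shrinkage toward the null)
        pi = 1.0 / p
        bound = pi * bf_max / (pi * bf_max + 1.0 - pi)
        assert np.all(res.pips <= bound + 1e-9)
        assert np.all(res.pips < pi)

    def test_normalization_of_explored_plus_approximated(self):
        """Explored posterior mass plus the approximated unexplored mass is
        the normalizing constant (probabilities sum to 1)."""
        panel, _ = simulate_summary_panel(12, 2, seed=9)
        res = adaptive_dap(panel, lambda_=2.0, k_max=3)
        explored = log10sumexp([m.log10_weight for m in res.models])
        total = log10sumexp([explored] + list(res.log10_unexplored))
        assert total == pytest.approx(res.log10_nc, abs=1e-9)
        posterior = 10.0 ** (explored - res.log10_nc) + sum(
            10.0 ** (u - res.log10_nc) for u in res.log10_unexplored
        )
        assert posterior == pytest.approx(1.0, abs=1e-9)

    def test_unexplored_mass_matches_plain_product_dp_when_all_candidates(self):
        """When every factor is a candidate (high λ) the unexplored mass
        reduces to the plain product-approximation DP over never-evaluated
        subsets."""
        panel, _ = simulate_summary_panel(10, 1, seed=13)
        prior = PriorSpec.default(10)
        res = adaptive_dap(panel, prior, lambda_=6.0, k_max=3)
        phi = np.array(
            [
                next(m.log10_bf for m in res.models if m.factor_index_set == (i,))
                for i in range(10)
            ]
        ) + prior._log10_odds
        explored_sets = [frozenset(m.factor_index_set) for m in res.models]
        for k in (1, 2, 3):
            expected = unexplored_mass(k, phi, explored_sets, prior._log10_null)
            got = res.log10_unexplored[k - 1]
            # fully enumerated sizes leave only cancellation residue in
            # either formulation; compare only genuine mass
            if expected < res.log10_nc - 12:
                assert got < res.log10_nc - 12
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_approximated_mass_close_to_truth_on_small_panel(self):
        """With K_max = p the adaptive normalizing constant is within 10^-λ
        relative error of the exact full enumeration."""
        from famfine.exhaustive import exhaustive_posterior

        panel, _ = simulate_summary_panel(8, 1, seed=21)
        lam = 2.0
        res = adaptive_dap(panel, lambda_=lam, k_max=8)
        exact = exhaustive_posterior(panel, K=8)
        rel_err = abs(10.0 ** (res.log10_nc - exact.log10_nc) - 1.0)
        assert rel_err < 10.0 ** (-lam)


class TestClusters:
    def test_perfect_proxies_share_one_cluster(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        clusters = build_clusters(np.array([0.5, 0.5]), R, 0.25, 0.01)
        assert len(clusters) == 1
        assert clusters[0].members == [0, 1]
        assert clusters[0].cluster_pip == pytest.approx(1.0)

    def test_uncorrelated_factors_singletons(self):
        clusters = build_clusters(np.array([0.4, 0.3, 0.2]), np.eye(3), 0.25, 0.01)
        assert [c.members for c in clusters] == [[0], [1], [2]]

    def test_complete_linkage_excludes_chained_factor(self):
        """a-b r²=0.9, b-c r²=0.9, a-c r²=0.1: c cannot join {a, b}."""
        r_ab = math.sqrt(0.9)
        r_bc = math.sqrt(0.9)
        r_ac = math.sqrt(0.1)
        R = np.array(
            [[1.0, r_ab, r_ac], [r_ab, 1.0, r_bc], [r_ac, r_bc, 1.0]]
        )
        pips = np.array([0.5, 0.4, 0.3])
        clusters = build_clusters(pips, R, 0.25, 0.01)
        assert clusters[0].members == [0, 1]
        assert clusters[1].members == [2]
        assert clusters[0].min_r2 == pytest.approx(0.9)

    def test_pip_floor_skips_low_seeds(self):
        clusters = build_clusters(np.array([0.005, 0.002]), np.eye(2), 0.25, 0.01)
        assert clusters == []
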