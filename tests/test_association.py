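"""Per-pair linear association, module counts and the bootstrap module test."""

import numpy as np
import pytest
from scipy import stats

from mirmod import (
    SyntheticSpec,
    bootstrap_module_test,
    fit_pair,
    generate,
    generate_null,
    identify_modules,
    module_assoc_count,
    pairwise_association,
)


def normal_equations_oracle(v, u):
    """Independent OLS oracle: solve X'X b = X'y directly, then the t-test."""
    X = np.column_stack([np.ones_like(v), v])
    coef = np.linalg.solve(X.T @ X, X.T @ u)
    resid = u - X @ coef
    df = len(v) - 2
    sigma2 = resid @ resid / df
    se_beta = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = coef[1] / se_beta
    return coef[0], coef[1], t, 2 * stats.t.sf(abs(t), df)


class TestFitPair:
    def test_exact_line_recovered(self):
        res = fit_pair([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], direction="two_sided")
        assert res.beta_hat == pytest.approx(-1.0)
        assert res.alpha_hat == pytest.approx(6.0)
        assert res.p_value == pytest.approx(0.0)  # perfect fit

    def test_matches_normal_equations_oracle(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        u = np.array([0.9, 2.2, 2.8, 4.1, 5.0])
        res = fit_pair(v, u, direction="two_sided")
        a, b, t, p = normal_equations_oracle(v, u)
        assert res.alpha_hat == pytest.approx(a, rel=1e-10)
        assert res.beta_hat == pytest.approx(b, rel=1e-10)
        assert res.t_stat == pytest.approx(t, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(0)
        for alternative, direction in [("two-sided", "two_sided"), ("less", "negative"), ("greater", "positive")]:
            v = rng.standard_normal(6)
            u = 1.5 - 0.8 * v + 0.3 * rng.standard_normal(6)
            res = fit_pair(v, u, direction=direction)
            ref = stats.linregress(v, u, alternative=alternative)
            assert res.beta_hat == pytest.approx(ref.slope, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_constant_mirna_profile_inestimable(self):
        res = fit_pair([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        assert not res.estimable and not res.associated
        assert np.isnan(res.beta_hat)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            fit_pair([1.0, 2.0], [1.0, 2.0])

    def test_null_p_values_uniform(self):
        """Under independence the two-sided p is Uniform(0,1): rejection rate
        at 0.05 within binomial tolerance over 4000 simulated pairs."""
        rng = np.random.default_rng(11)
        n = 4000
        rejections = sum(
            fit_pair(rng.standard_normal(5), rng.standard_normal(5),
                     direction="two_sided").p_value < 0.05
            for _ in range(n)
        )
        rate = rejections / n
        tol = 4 * np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= tol

    def test_negative_direction_never_accepts_positive_slope(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            v = rng.standard_normal(5)
            u = rng.standard_normal(5)
            res = fit_pair(v, u, direction="negative", alpha_level=0.5)
            if res.associated:
                assert res.beta_hat < 0


class TestPairwiseAssociation:
    def test_matches_fit_pair_elementwise(self):
        truth = generate(SyntheticSpec(
            y=15, x=6, t=5, n_modules=1,
            module_mirna_sizes=(2,), module_mrna_sizes=(5,), seed=3,
        ))
        pw = pairwise_association(
            truth.mirna_expr, truth.mrna_expr, truth.map_matrix, direction="negative"
        )
        for j in range(15):
            for i in range(6):
                single = fit_pair(
                    truth.mirna_expr.values[i],
                    truth.mrna_expr.values[j],
                    direction="negative",
                    predicted=bool(truth.map_matrix.values[j, i]),
                )
                assert pw.beta_hat[j, i] == pytest.approx(single.beta_hat, rel=1e-10)
                assert pw.p_value[j, i] == pytest.approx(single.p_value, rel=1e-10)
                assert bool(pw.associated[j, i]) == single.associated

    def test_assoc_count_monotone_in_alpha(self):
        truth = generate(SyntheticSpec(seed=5))
        idx_m = np.arange(3)
        idx_g = np.arange(30)
        counts = []
        for alpha in (0.2, 0.05, 0.01):
            pw = pairwise_association(
                truth.mirna_expr, truth.mrna_expr, truth.map_matrix,
                direction="negative", alpha_level=alpha,
            )
            counts.append(module_assoc_count(pw, idx_m, idx_g))
        assert counts[0] >= counts[1] >= counts[2]

    def test_planted_module_pairs_mostly_associated(self):
        """At default noise the planted module should keep >= 0.8 of its
        predicted pairs significant (simulation oracle)."""
        ratios = []
        for seed in range(10):
            truth = generate(SyntheticSpec(seed=seed))
            pw = pairwise_association(
                truth.mirna_expr, truth.mrna_expr, truth.map_matrix, direction="negative"
            )
            planted = ~np.isnan(truth.true_beta) & truth.map_matrix.values.astype(bool)
            ratios.append(pw.associated[planted].sum() / planted.sum())
        assert np.mean(ratios) >= 0.8


class TestModuleCounts:
    def _pairwise(self, seed=0):
        truth = generate(SyntheticSpec(seed=seed))
        pw = pairwise_association(
            truth.mirna_expr, truth.mrna_expr, truth.map_matrix, direction="negative"
        )
        return truth, pw

    def test_no_predicted_pairs_count_zero(self):
        truth, pw = self._pairwise()
        # module-1 miRNAs vs module-2 mRNAs: essentially no predicted pairs
        count = module_assoc_count(pw, np.arange(3), np.arange(30, 60))
        assert count <= 3

    def test_perfect_antilinear_block_is_maximal(self):
        spec = SyntheticSpec(
            y=20, x=4, t=5, n_modules=1,
            module_mirna_sizes=(2,), module_mrna_sizes=(6,),
            in_module_target_prob=1.0, background_target_prob=0.0,
            noise_sd=1e-12, seed=2,
        )
        truth = generate(spec)
        pw = pairwise_association(
            truth.mirna_expr, truth.mrna_expr, truth.map_matrix, direction="negative"
        )
        assert module_assoc_count(pw, np.arange(2), np.arange(6)) == 12


class TestBootstrapModuleTest:
    def test_zero_observed_count_never_significant(self):
        truth = generate_null(y=40, x=6, t=5, target_prob=0.3, seed=0)
        pw = pairwise_association(
            truth.mirna_expr, truth.mrna_expr, truth.map_matrix, direction="negative"
        )
        w2, p, sig = bootstrap_module_test(
            pw, np.arange(2), observed_count=0, n_gene=5, B=60,
            rng=np.random.default_rng(0),
        )
        assert w2 == 60 and p == 1.0 and not sig

    def test_unattainable_count_always_significant(self):
        truth = generate_null(y=40, x=6, t=5, target_prob=0.3, seed=0)
        pw = pairwise_association(
            truth.mirna_expr, truth.mrna_expr, truth.map_matrix, direction="negative"
        )
        w2, p, sig = bootstrap_module_test(
            pw, np.arange(2), observed_count=10**6, n_gene=5, B=60,
            rng=np.random.default_rng(0),
        )
        assert w2 == 0 and p == 0.0 and sig

    def test_null_significance_rate_near_alpha(self):
        """Over 200 null module tests the rejection rate stays within
        binomial tolerance of alpha = 0.05."""
        rejections = 0
        n_tests = 200
        for k in range(n_tests):
            null = generate_null(y=200, x=20, t=5, target_prob=0.5, seed=1000 + k)
            pw = pairwise_association(
                null.mirna_expr, null.mrna_expr, null.map_matrix,
                direction="two_sided", alpha_level=0.3,
            )
            rng = np.random.default_rng(5000 + k)
            mirna_idx = rng.choice(20, size=5, replace=False)
            mrna_idx = rng.choice(200, size=40, replace=False)
            observed = module_assoc_count(pw, mirna_idx, mrna_idx)
            _, _, sig = bootstrap_module_test(
                pw, mirna_idx, observed, 40, B=100, alpha=0.05, rng=rng
            )
            rejections += sig
        assert 0.01 <= rejections / n_tests <= 0.09


class TestIdentifyModules:
    def test_candidate_count_is_product_of_cluster_counts(self):
        truth = generate(SyntheticSpec(seed=1))
        mir = [(k + 1, truth.mirna_modules[k]) for k in range(3)]
        gene = [(k + 1, truth.mrna_modules[k]) for k in range(3)]
        modules = identify_modules(
            mir, gene, truth.map_matrix, truth.mirna_expr, truth.mrna_expr,
            B=30, rng=np.random.default_rng(0),
        )
        assert len(modules) == 9

    def test_majority_targeting_filter(self):
        truth = generate(SyntheticSpec(seed=1))
        mir = [(1, truth.mirna_modules[0])]
        gene = [(1, truth.mrna_modules[0])]
        strict = identify_modules(
            mir, gene, truth.map_matrix, truth.mirna_expr, truth.mrna_expr,
            majority_threshold=0.99, B=50, rng=np.random.default_rng(0),
        )[0]
        lax = identify_modules(
            mir, gene, truth.map_matrix, truth.mirna_expr, truth.mrna_expr,
            majority_threshold=0.5, B=50, rng=np.random.default_rng(0),
        )[0]
        assert lax.significant and strict.significant
        assert lax.regulatory and not strict.regulatory  # each miRNA targets ~95%

    def test_planted_module_recovered_with_strong_negative_coupling(self):
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            truth = generate(SyntheticSpec(seed=seed))
            mir = [(k + 1, truth.mirna_modules[k]) for k in range(3)]
            gene = [(k + 1, truth.mrna_modules[k]) for k in range(3)]
            modules = identify_modules(
                mir, gene, truth.map_matrix, truth.mirna_expr, truth.mrna_expr,
                B=100, rng=np.random.default_rng(seed),
            )
            diag = [m for m in modules if m.mirna_cluster_label == m.mrna_cluster_label]
            hits += all(m.regulatory for m in diag)
        assert hits / n_seeds >= 0.9

    def test_bit_reproducible_under_fixed_seed(self):
        truth = generate(SyntheticSpec(seed=4))
        mir = [(k + 1, truth.mirna_modules[k]) for k in range(3)]
        gene = [(k + 1, truth.mrna_modules[k]) for k in range(3)]
        runs = [
            identify_modules(
                mir, gene, truth.map_matrix, truth.mirna_expr, truth.mrna_expr,
                B=50, rng=np.random.default_rng(99),
            )
            for _ in range(2)
        ]
        assert [m.to_dict() for m in runs[0]] == [m.to_dict() for m in runs[1]]
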