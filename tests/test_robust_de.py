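"""Huber-IRLS regression, FDR procedures and hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from somno import (
    CountMatrix,
    bh_adjust,
    huber_irls,
    hypergeom_enrich,
    normalize_log2cpm,
    pca_qc,
    run_de,
    storey_pi0,
    storey_q,
)
from somno.simulate import CountsSimParams, gen_counts

MAD_SCALE = 1.4826
K = 1.345


def huber_psi(u, k=K):
    return np.clip(u, -k, k)


def grid_search_huber(y, x, k=K, span=3.0, step=0.005):
    """Brute-force M-estimation oracle: scan a (b0, b1) grid for the point
    that best solves the Huber estimating equations
    sum psi(r/s) = 0 and sum x*psi(r/s) = 0, with the scale s taken as
    1.4826*MAD of the residuals at that grid point — the same defining
    conditions the IRLS fixed point satisfies."""
    ols = np.polyfit(x, y, 1)  # slope, intercept
    b0s = np.arange(ols[1] - span, ols[1] + span, step)
    b1s = np.arange(ols[0] - span, ols[0] + span, step)
    best, best_q = None, np.inf
    for b0 in b0s:
        r = y - b0 - np.outer(b1s, x)  # (n_b1, n)
        med = np.median(r, axis=1, keepdims=True)
        s = MAD_SCALE * np.median(np.abs(r - med), axis=1)
        s = np.maximum(s, 1e-12)
        psi = huber_psi(r / s[:, None], k)
        score = psi.sum(axis=1) ** 2 + (psi @ x) ** 2
        i = int(np.argmin(score))
        if score[i] < best_q:
            best_q, best = score[i], (b0, b1s[i])
    return best


class TestNormalize:
    def test_zero_count_maps_to_zero(self):
        counts = np.array([[0, 10], [5, 5]])
        norm = normalize_log2cpm(counts)
        assert norm[0, 0] == 0.0

    def test_direct_evaluation(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 1000
        counts[1, 0] = 10**6 - 1000
        norm = normalize_log2cpm(counts)
        assert norm[0, 0] == pytest.approx(math.log2(1001))

    def test_library_scale_invariance(self):
        rng = np.random.default_rng(41)
        counts = rng.poisson(50, size=(20, 3))
        doubled = counts.copy()
        doubled[:, 1] *= 2
        np.testing.assert_allclose(
            normalize_log2cpm(counts)[:, 1], normalize_log2cpm(doubled)[:, 1]
        )

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            normalize_log2cpm(np.array([[1, 0], [2, 0]]))


class TestPcaQc:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(42)
        base = rng.normal(5, 1, size=(50, 2))
        mat = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 1]])
        coords, frac = pca_qc(mat)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-9)
        np.testing.assert_allclose(coords[2], coords[3], atol=1e-9)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(43)
        _, frac = pca_qc(rng.normal(size=(30, 6)))
        assert frac.sum() == pytest.approx(1.0)

    def test_pc1_separates_planted_groups(self):
        matrix, _ = gen_counts(
            CountsSimParams(n_genes=300, n_per_genotype=4, n_de=60,
                            lfc_values=(2.0, -2.0)), seed=44
        )
        coords, _ = pca_qc(normalize_log2cpm(matrix.counts))
        pc1 = coords[:, 0]
        g = matrix.genotype
        gap = abs(pc1[g == 0].mean() - pc1[g == 1].mean())
        spread = max(pc1[g == 0].std(), pc1[g == 1].std())
        assert gap > 2 * spread

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_qc(np.zeros((10, 2)))


class TestHuberIrls:
    def test_equals_ols_when_weights_saturate(self):
        # residuals built so max|r| < k * 1.4826 * MAD: every weight is 1
        x = np.repeat([0.0, 1.0], 4)
        r = np.array([0.01, -0.01, 0.012, -0.012, 0.009, -0.009, 0.011, -0.011])
        y = 2.0 + 1.5 * x + r
        fit = huber_irls(y, x)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.beta1 == pytest.approx(slope, abs=1e-10)
        assert fit.beta0 == pytest.approx(intercept, abs=1e-10)

    def test_constant_y_degenerate(self):
        x = np.repeat([0.0, 1.0], 3)
        fit = huber_irls(np.full(6, 3.0), x)
        assert fit.beta1 == 0.0 and fit.p == 1.0 and fit.degenerate

    def test_outlier_resistance_vs_ols_and_grid_oracle(self):
        """One 20x-inflated sample among 8: the Huber fit lands nearer the
        true slope than OLS and agrees with the brute-force grid oracle."""
        rng = np.random.default_rng(46)
        x = np.repeat([0.0, 1.0], 4)
        true_b1 = 1.0
        y = 3.0 + true_b1 * x + rng.normal(0, 0.1, size=8)
        y[5] += math.log2(20)  # a 20-fold count inflation on the log2 scale
        fit = huber_irls(y, x)
        ols_b1 = np.polyfit(x, y, 1)[0]
        assert abs(fit.beta1 - true_b1) < abs(ols_b1 - true_b1)
        _, grid_b1 = grid_search_huber(y, x)
        assert fit.beta1 == pytest.approx(grid_b1, abs=0.02)

    def test_agrees_with_statsmodels_rlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(47)
        x = np.repeat([0.0, 1.0], 5)
        y = 1.0 - 0.8 * x + rng.normal(0, 0.3, size=10)
        y[2] += 6.0
        fit = huber_irls(y, x)
        X = sm.add_constant(x)
        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=K)).fit(scale_est="mad")
        assert fit.beta1 == pytest.approx(rlm.params[1], abs=0.05)

    def test_breakdown_single_huge_outlier(self):
        rng = np.random.default_rng(48)
        x = np.repeat([0.0, 1.0], 4)
        y_clean = 2.0 + 0.5 * x + rng.normal(0, 0.1, size=8)
        clean_b1 = huber_irls(y_clean, x).beta1
        y = y_clean.copy()
        y[0] += 1e4
        robust_shift = abs(huber_irls(y, x).beta1 - clean_b1)
        ols_shift = abs(np.polyfit(x, y, 1)[0] - np.polyfit(x, y_clean, 1)[0])
        assert robust_shift < ols_shift

    def test_constant_design_rejected(self):
        with pytest.raises(ValueError):
            huber_irls(np.arange(6.0), np.ones(6))


class TestBhStorey:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_direct_evaluation(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(49)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(50)
        p = rng.uniform(size=100) ** 2
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_storey_equals_bh_when_pi0_is_one(self):
        p = np.array([0.6, 0.7, 0.8, 0.9, 0.95])  # all above lambda
        assert storey_pi0(p) == 1.0
        np.testing.assert_allclose(storey_q(p), bh_adjust(p))

    def test_pi0_cap(self):
        assert storey_pi0(np.array([0.9] * 10)) == 1.0

    def test_pi0_near_one_under_uniform_null(self):
        rng = np.random.default_rng(51)
        good = 0
        for _ in range(100):
            p = rng.uniform(size=1000)
            if 0.9 <= storey_pi0(p) <= 1.0:
                good += 1
        assert good >= 95


class TestHypergeomEnrich:
    def test_small_exact_case(self):
        # N=10, K=5, n=4 hits, k=4 in set -> p = C(5,4)*C(5,0)/C(10,4)
        universe = [f"g{i}" for i in range(10)]
        sets = {"s": universe[:5]}
        hits = universe[:4]
        res = hypergeom_enrich(hits, universe, sets)[0]
        assert res.k == 4 and res.K == 5 and res.n == 4 and res.N == 10
        expected = math.comb(5, 4) * math.comb(5, 0) / math.comb(10, 4)
        assert res.p_hyper == pytest.approx(expected)

    def test_zero_hits_in_set(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeom_enrich(universe[5:7], universe, {"s": universe[:5]})[0]
        assert res.k == 0 and res.p_hyper == pytest.approx(1.0)

    def test_empty_set_after_intersection_skipped(self):
        universe = ["a", "b"]
        assert hypergeom_enrich(["a"], universe, {"s": ["zz"]}) == []

    def test_tail_formula_equals_enumeration(self):
        """P(X >= k) matches brute-force enumeration of all draws, N <= 20."""
        rng = np.random.default_rng(52)
        for _ in range(10):
            N = int(rng.integers(5, 21))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            hits = list(rng.choice(universe, size=n, replace=False))
            res = hypergeom_enrich(hits, universe, {"s": universe[:K]})[0]
            k_obs = res.k
            # enumeration over all C(N, n) possible hit draws
            count = sum(
                1
                for combo in itertools.combinations(range(N), n)
                if sum(1 for i in combo if i < K) >= k_obs
            )
            assert res.p_hyper == pytest.approx(count / math.comb(N, n), abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich([], [], {"s": ["a"]})


class TestRunDe:
    def test_planted_sign_accuracy(self):
        """Detected planted genes carry the correct fold-change sign."""
        params = CountsSimParams(n_genes=400, n_per_genotype=4, n_de=40,
                                 lfc_values=(2.0, -2.0), outlier_prob=0.02)
        matrix, truth = gen_counts(params, seed=53)
        table = run_de(matrix)
        lfc = dict(zip(matrix.genes, truth["lfc"]))
        detected = table[table["direction"] != "ns"]
        planted_detected = detected[detected["gene"].map(lfc) != 0]
        assert len(planted_detected) > 10
        signs_ok = np.sign(planted_detected["log2FC"]) == np.sign(
            planted_detected["gene"].map(lfc)
        )
        assert signs_ok.all()

    def test_up_down_partition(self):
        matrix, _ = gen_counts(
            CountsSimParams(n_genes=300, n_de=60, lfc_values=(1.5, -1.5)), seed=54
        )
        table = run_de(matrix)
        n_sig = int((table["direction"] != "ns").sum())
        n_up = int((table["direction"] == "up").sum())
        n_down = int((table["direction"] == "down").sum())
        assert n_up + n_down == n_sig > 0

    def test_all_zero_genes_excluded(self):
        counts = np.array([[5, 6, 7, 8], [0, 0, 0, 0], [3, 2, 4, 5]])
        m = CountMatrix(["a", "b", "c"], list("wxyz"), counts,
                        genotype=np.array([0, 0, 1, 1]))
        table = run_de(m)
        assert set(table["gene"]) == {"a", "c"}

    def test_robust_beats_ols_under_contamination(self):
        """RMSE of the planted log2 fold change: Huber fits beat per-gene OLS
        on outlier-contaminated counts."""
        err_rob, err_ols = [], []
        for seed in range(10):
            params = CountsSimParams(n_genes=120, n_per_genotype=4, n_de=40,
                                     lfc_values=(1.5, -1.5), outlier_prob=0.05)
            matrix, truth = gen_counts(params, seed=600 + seed)
            norm = normalize_log2cpm(matrix.counts)
            x = matrix.genotype.astype(float)
            for gi in np.flatnonzero(truth["is_de"]):
                fit = huber_irls(norm[gi], x)
                ols_b1 = np.polyfit(x, norm[gi], 1)[0]
                err_rob.append((fit.beta1 - truth["lfc"][gi]) ** 2)
                err_ols.append((ols_b1 - truth["lfc"][gi]) ** 2)
        assert np.sqrt(np.mean(err_rob)) < np.sqrt(np.mean(err_ols))
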