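"""NB differential expression: size factors, dispersion estimation, the
conditioned exact test, multiple-testing adjustment, DE calls, display
normalization and clustering."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from crossde.counting import CountMatrix
from crossde.de import (
    DISPERSION_FLOOR,
    adjust_pvalues,
    call_de,
    estimate_dispersions,
    estimate_size_factors,
    hierarchical_cluster,
    nbinom_exact_test,
    run_de,
    zscore_rows,
)


def make_matrix(values, conditions=None):
    frame = pd.DataFrame(values)
    frame.index = [f"g{i}" for i in range(len(frame))]
    if conditions is None:
        conditions = {c: "a" for c in frame.columns}
    return CountMatrix(frame, conditions)


def median_of_ratios_oracle(frame):
    """Independent median-of-ratios computation with plain Python loops."""
    rows = [
        row
        for _, row in frame.iterrows()
        if all(v > 0 for v in row)
    ]
    factors = {}
    for sample in frame.columns:
        ratios = []
        for row in rows:
            geomean = np.exp(np.mean([np.log(v) for v in row]))
            ratios.append(row[sample] / geomean)
        factors[sample] = statistics.median(ratios)
    return factors


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        matrix = make_matrix({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        np.testing.assert_allclose(estimate_size_factors(matrix).factors, [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        # every gene in B is 2x A: geometric-mean reference gives (1/sqrt2, sqrt2)
        a = [10, 50, 3, 200]
        matrix = make_matrix({"A": a, "B": [2 * v for v in a]})
        np.testing.assert_allclose(
            estimate_size_factors(matrix).factors,
            [1 / np.sqrt(2), np.sqrt(2)],
            rtol=1e-12,
        )

    def test_matches_independent_oracle(self, rng):
        frame = pd.DataFrame(
            rng.poisson(50, size=(200, 4)), columns=list("abcd")
        )
        frame.iloc[rng.integers(0, 200, 30), rng.integers(0, 4, 30)] = 0
        frame.index = [f"g{i}" for i in range(200)]
        sf = estimate_size_factors(make_matrix(frame))
        oracle = median_of_ratios_oracle(frame)
        for sample in frame.columns:
            assert sf[sample] == pytest.approx(oracle[sample], rel=1e-12)

    def test_no_common_gene_raises(self):
        matrix = make_matrix({"s1": [5, 0], "s2": [0, 5]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(matrix)

    def test_scaling_one_sample_rescales_only_its_factor(self, rng):
        frame = pd.DataFrame(rng.poisson(100, size=(300, 3)) + 1, columns=list("abc"))
        frame.index = [f"g{i}" for i in range(300)]
        base = estimate_size_factors(make_matrix(frame)).factors
        scaled = frame.copy()
        scaled["c"] = scaled["c"] * 4
        new = estimate_size_factors(make_matrix(scaled)).factors
        # reference geomean gains 4^(1/3) for every gene
        shift = 4.0 ** (1 / 3)
        np.testing.assert_allclose(new["a"], base["a"] / shift, rtol=1e-12)
        np.testing.assert_allclose(new["b"], base["b"] / shift, rtol=1e-12)
        np.testing.assert_allclose(new["c"], base["c"] * 4 / shift, rtol=1e-12)


TWO_GROUPS = {"s1": "a", "s2": "a", "s3": "a", "s4": "a",
              "s5": "b", "s6": "b", "s7": "b", "s8": "b"}


class TestDispersions:
    def test_poisson_counts_shrink_to_floor(self, rng):
        counts = pd.DataFrame(
            rng.poisson(np.tile(rng.uniform(50, 500, size=(1000, 1)), (1, 8))),
            columns=list(TWO_GROUPS),
        )
        counts.index = [f"g{i}" for i in range(1000)]
        matrix = CountMatrix(counts, TWO_GROUPS)
        fit = estimate_dispersions(matrix, estimate_size_factors(matrix))
        assert np.median(fit.final) < 0.01

    def test_nb_dispersion_recovered_from_trend(self, rng):
        # alpha = 0.2 at high means: the trend asymptote recovers it
        mu = rng.uniform(500, 5000, size=2000)
        alpha = 0.2
        counts = pd.DataFrame(
            rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu[:, None]), size=(2000, 8)),
            columns=list(TWO_GROUPS),
        )
        counts.index = [f"g{i}" for i in range(2000)]
        matrix = CountMatrix(counts, TWO_GROUPS)
        fit = estimate_dispersions(matrix, estimate_size_factors(matrix))
        assert fit.trend_a1 == pytest.approx(0.2, abs=0.05)

    def test_constant_gene_clamped_to_floor(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(50, 8)), columns=list(TWO_GROUPS))
        counts.iloc[0] = 77  # identical counts in every replicate
        counts.index = [f"g{i}" for i in range(50)]
        matrix = CountMatrix(counts, TWO_GROUPS)
        fit = estimate_dispersions(matrix, estimate_size_factors(matrix))
        assert fit.raw.iloc[0] <= 0
        assert fit.final.iloc[0] >= DISPERSION_FLOOR
        assert fit.final.iloc[0] == max(DISPERSION_FLOOR, fit.fitted.iloc[0])

    def test_single_replicates_rejected(self):
        matrix = make_matrix({"s1": [5, 10], "s2": [6, 9]}, {"s1": "a", "s2": "b"})
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(matrix, estimate_size_factors(matrix))


def exact_test_oracle(k_a, k_b, sf_a, sf_b, alpha):
    """Exhaustive-enumeration oracle in plain probability space."""
    total = k_a + k_b
    if total == 0:
        return 1.0
    s_a, s_b = sum(sf_a), sum(sf_b)
    mu = total / (s_a + s_b)

    def pmf(k, mean, var):
        if var <= mean * (1 + 1e-6):
            return sps.poisson.pmf(k, mean)
        return sps.nbinom.pmf(k, mean**2 / (var - mean), mean / var)

    var_a = s_a * mu + alpha * mu**2 * sum(f**2 for f in sf_a)
    var_b = s_b * mu + alpha * mu**2 * sum(f**2 for f in sf_b)
    probs = [pmf(a, s_a * mu, var_a) * pmf(total - a, s_b * mu, var_b) for a in range(total + 1)]
    observed = probs[k_a]
    return sum(p for p in probs if p <= observed * (1 + 1e-8)) / sum(probs)


class TestExactTest:
    def test_symmetric_split_is_mode(self):
        assert nbinom_exact_test(20, 20, np.ones(4), np.ones(4), 0.1) == 1.0

    def test_zero_total_is_one_by_convention(self):
        assert nbinom_exact_test(0, 0, np.ones(4), np.ones(4), 0.1) == 1.0

    def test_small_split_matches_enumeration(self):
        sf = np.ones(2)
        p = nbinom_exact_test(3, 7, sf, sf, DISPERSION_FLOOR)
        assert p == pytest.approx(exact_test_oracle(3, 7, sf, sf, DISPERSION_FLOOR), rel=1e-9)

    @pytest.mark.parametrize("alpha", [DISPERSION_FLOOR, 0.05, 0.4])
    @pytest.mark.parametrize("sfs", [(np.ones(3), np.ones(3)),
                                     (np.array([0.7, 1.1, 1.4]), np.array([0.9, 1.0, 1.3]))])
    def test_matches_oracle_across_splits(self, alpha, sfs):
        sf_a, sf_b = sfs
        for total in (1, 4, 9, 17):
            for k_a in range(total + 1):
                p = nbinom_exact_test(k_a, total - k_a, sf_a, sf_b, alpha)
                assert p == pytest.approx(
                    exact_test_oracle(k_a, total - k_a, list(sf_a), list(sf_b), alpha),
                    rel=1e-8,
                ), (total, k_a, alpha)

    def test_label_swap_symmetry(self):
        sf_a = np.array([0.8, 1.0, 1.2, 0.9])
        sf_b = np.array([1.1, 0.95, 1.05, 1.0])
        p1 = nbinom_exact_test(13, 41, sf_a, sf_b, 0.1)
        p2 = nbinom_exact_test(41, 13, sf_b, sf_a, 0.1)
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_p_in_unit_interval_and_never_zero(self):
        p = nbinom_exact_test(0, 100000, np.ones(4), np.ones(4), DISPERSION_FLOOR)
        assert 0 < p <= 1


def bh_oracle(pvalues):
    """Brute-force BH step-up: q_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * pvalues[i] / rank))
        q[i] = running
    return q


class TestAdjustPvalues:
    def test_single_pvalue_unchanged(self):
        assert adjust_pvalues([0.04], "bh")[0] == pytest.approx(0.04)

    def test_hand_computed_bh_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.005, 0.01, 0.03, 0.04], "bh"),
            [0.02, 0.02, 0.04, 0.04],
        )

    def test_bonferroni(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.3, 0.5, 0.2, 0.04], "bonferroni"),
            [0.05, 1.0, 1.0, 1.0, 0.2],
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm")

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_bh_matches_brute_force_step_up(self, pvalues):
        np.testing.assert_allclose(adjust_pvalues(pvalues, "bh"), bh_oracle(pvalues), atol=1e-12)
        assert (adjust_pvalues(pvalues, "bh") >= np.asarray(pvalues) - 1e-15).all()


class TestCallDE:
    @pytest.mark.parametrize(
        "q,log2fc,expected_sig,expected_dir",
        [
            (0.04, 1.0, True, "up"),        # 2-fold, q passes
            (0.04, np.log2(1.2), False, "none"),  # fails fold filter
            (0.06, np.log2(3.0), False, "none"),  # fails q filter
            (0.01, -1.5, True, "down"),
        ],
    )
    def test_call_thresholds(self, q, log2fc, expected_sig, expected_dir):
        res = pd.DataFrame({"q": [q], "log2fc": [log2fc]}, index=["g"])
        out = call_de(res)
        assert bool(out["significant"].iloc[0]) is expected_sig
        assert out["direction"].iloc[0] == expected_dir

    def test_min_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            call_de(pd.DataFrame({"q": [0.1], "log2fc": [0.0]}), min_fold=0.5)


class TestDisplayOps:
    def test_zscore_example_and_constant_row(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        z = zscore_rows(frame)
        np.testing.assert_allclose(z.iloc[0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(z.iloc[1], [0.0, 0.0, 0.0])

    def test_zscore_defining_property(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 6)))
        z = zscore_rows(frame)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_cluster_merges_closest_pair_first(self):
        frame = pd.DataFrame([[0.0], [1.0], [11.0]])
        row_order, _ = hierarchical_cluster(frame)
        pos = {r: i for i, r in enumerate(row_order)}
        assert abs(pos[0] - pos[1]) == 1  # the distance-1 pair is adjacent
        dup = pd.DataFrame([[5.0, 1.0], [0.0, 9.0], [5.0, 1.0]])
        order, _ = hierarchical_cluster(dup)
        pos = {r: i for i, r in enumerate(order)}
        assert abs(pos[0] - pos[2]) == 1  # duplicates merge first

    def test_cluster_single_row_and_empty(self):
        assert hierarchical_cluster(pd.DataFrame([[1.0, 2.0]])) == ([0], [0, 1])
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame())


class TestRunDE:
    def test_condition_swap_negates_log2fc(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.poisson(100, size=(100, 8)), columns=list(TWO_GROUPS))
        counts.index = [f"g{i}" for i in range(100)]
        matrix = CountMatrix(counts, TWO_GROUPS)
        fwd = run_de(matrix, "a", "b")
        rev = run_de(matrix, "b", "a")
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-9)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-9, atol=1e-12)

    def test_power_positive_and_increasing_in_effect_size(self):
        """Detection power among planted genes grows with the fold change."""
        rng = np.random.default_rng(99)
        alpha = 0.05
        n_null, n_de = 500, 100
        rates = []
        for lfc in (0.6, 1.2, 2.0):
            mu = rng.uniform(50, 500, size=(n_null + n_de, 1))
            mean = np.tile(mu, (1, 8))
            mean[n_null:, 4:] *= 2.0 ** lfc
            counts = pd.DataFrame(
                rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mean)),
                columns=list(TWO_GROUPS),
            )
            counts.index = [f"g{i}" for i in range(len(counts))]
            res = run_de(CountMatrix(counts, TWO_GROUPS), "a", "b")
            rates.append(res["significant"].iloc[n_null:].mean())
        assert rates[0] > 0
        assert rates[0] < rates[1] < rates[2]

    def test_zero_mean_uses_pseudocount(self):
        counts = pd.DataFrame(
            {"s1": [0, 50], "s2": [0, 60], "s3": [40, 55], "s4": [38, 52]},
            index=["g0", "g1"],
        )
        matrix = CountMatrix(counts, {"s1": "a", "s2": "a", "s3": "b", "s4": "b"})
        res = run_de(matrix, "a", "b")
        expected = np.log2((res.loc["g0", "mean_b"] + 1) / (0 + 1))
        assert res.loc["g0", "log2fc"] == pytest.approx(expected)
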