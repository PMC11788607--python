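import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from reachbias.bias_stats import (
    BiasResult,
    bias_ci,
    compare_blocks,
    decision_bias,
    spearman_rho,
    summarize_parameters,
    wilcoxon_signed_rank,
)
from reachbias.psychfit import PsychometricFit


def _fit(threshold, ci=None, converged=True):
    ci95 = {"threshold": ci} if ci else None
    return PsychometricFit(
        threshold=threshold, width=50.0, lapse=0.01, n_trials=150,
        converged=converged, nll=0.0, ci95=ci95,
    )


def brute_force_wilcoxon(d):
    """Exhaustive two-tailed signed-rank p over all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    n = len(d)
    for signs in itertools.product([1, -1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
        w_minus = ranks.sum() - w_plus
        if min(w_plus, w_minus) <= w_obs + 1e-12:
            count += 1
    return count / 2 ** n


class TestDecisionBias:
    def test_table_arithmetic_motion_control(self):
        res = decision_bias(_fit(-5.4), _fit(-2.3))
        assert res.bias == pytest.approx(-3.1)

    def test_table_arithmetic_orientation_main(self):
        res = decision_bias(_fit(3.8), _fit(10.8))
        assert res.bias == pytest.approx(-7.0)

    def test_identical_fits_zero_bias(self):
        assert decision_bias(_fit(1.5), _fit(1.5)).bias == 0.0

    def test_antisymmetric(self):
        a, b = _fit(-8.7), _fit(1.1)
        assert decision_bias(a, b).bias == pytest.approx(-decision_bias(b, a).bias)

    def test_nonconverged_input_flagged(self):
        res = decision_bias(_fit(0.0, converged=False), _fit(1.0))
        assert res.flagged


class TestBiasCi:
    def test_three_four_five(self):
        r = _fit(0.0, ci=(-3.0, 3.0))
        l = _fit(0.0, ci=(-4.0, 4.0))
        lo, hi = bias_ci(r, l)
        assert lo == pytest.approx(-5.0)
        assert hi == pytest.approx(5.0)

    def test_zero_width_side_passes_through(self):
        r = _fit(2.0, ci=(2.0, 2.0))
        l = _fit(0.0, ci=(-4.0, 4.0))
        lo, hi = bias_ci(r, l)
        assert lo == pytest.approx(2.0 - 4.0)
        assert hi == pytest.approx(2.0 + 4.0)

    def test_symmetric_inputs_centre_on_bias(self):
        r = _fit(-5.0, ci=(-7.0, -3.0))
        l = _fit(1.0, ci=(-1.0, 3.0))
        lo, hi = bias_ci(r, l)
        assert (lo + hi) / 2 == pytest.approx(-6.0)

    def test_missing_ci_rejected(self):
        with pytest.raises(ValueError):
            bias_ci(_fit(0.0), _fit(0.0, ci=(-1.0, 1.0)))


class TestWilcoxon:
    def test_exact_p_matches_exhaustive_enumeration_n6(self):
        d = [1.0, -2.0, 3.0, -4.0, 5.0, -6.0]
        res = wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=-1000, max_value=1000).filter(lambda v: v != 0),
            min_size=5, max_size=10, unique_by=abs,
        )
    )
    def test_exact_p_matches_enumeration_tie_free(self, d):
        res = wilcoxon_signed_rank([float(v) for v in d])
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)
        assert res.w_plus + res.w_minus == pytest.approx(len(d) * (len(d) + 1) / 2)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(20):
            d = rng.normal(size=12)
            res = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, method="exact")
            assert res.W == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_printed_rank_biserial_n22_W10(self):
        # reconstruct from (n, min rank sum, sign of dominant side)
        n, W = 22, 10.0
        total = n * (n + 1) / 2
        r_rb = (W - (total - W)) / total
        assert r_rb == pytest.approx(-0.92, abs=0.005)

    @pytest.mark.parametrize(
        "n,W,printed",
        [
            (22, 10, -0.92),
            (23, 0, -1.0),
            (22, 55, -0.56),
            (22, 51, -0.59),
            (23, 81, -0.41),
            (23, 12, -0.91),
        ],
    )
    def test_all_printed_triplets_consistent(self, n, W, printed):
        total = n * (n + 1) / 2
        r_rb = (W - (total - W)) / total
        assert r_rb == pytest.approx(printed, abs=0.01)

    def test_one_sided_dominance_gives_unit_effect_size(self):
        res = wilcoxon_signed_rank([-1.0, -2.5, -3.0, -4.0, -0.5, -7.0])
        assert res.W == 0.0
        assert res.r_rb == -1.0
        res = wilcoxon_signed_rank([1.0, 2.5, 3.0, 4.0, 0.5, 7.0])
        assert res.r_rb == 1.0

    def test_balanced_ranks_zero_effect_size(self):
        # |d| ranks 1,2,4,7 positive vs 3,5,6 negative: 14 each
        res = wilcoxon_signed_rank([1.0, 2.0, -3.0, 4.0, -5.0, -6.0, 7.0])
        assert res.w_plus == res.w_minus
        assert res.r_rb == 0.0
        assert res.p == 1.0

    def test_ties_fall_back_to_normal_approximation(self):
        d = [1.0, 1.0, -1.0, 2.0, -2.0, 3.0]
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal"
        ref = scipy_wilcoxon(d, method="approx", correction=False)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, -1.0, 2.0, 3.0])

    def test_zeros_dropped_before_ranking(self):
        a = wilcoxon_signed_rank([0.0, 1.0, -2.0, 3.0, -4.0, 5.0, 0.0])
        b = wilcoxon_signed_rank([1.0, -2.0, 3.0, -4.0, 5.0])
        assert (a.W, a.p, a.n) == (b.W, b.p, b.n)


class TestCompareBlocks:
    def test_identical_vectors_degenerate(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        with pytest.raises(ValueError):
            compare_blocks(v, v)

    def test_sign_of_median_difference(self):
        main = np.array([-10.0, -12.0, -8.0, -11.0, -9.0, -10.5])
        control = np.zeros(6)
        res = compare_blocks(main, control)
        assert res.median < 0

    def test_unmatched_participants_rejected(self):
        a = pd.Series([1.0] * 6, index=range(6))
        b = pd.Series([0.0] * 6, index=range(1, 7))
        with pytest.raises(ValueError):
            compare_blocks(a, b)


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = rng.normal(size=12)
        rho, _ = spearman_rho(x, 3 * x + 1, n_perm=200, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(x, -x, n_perm=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_null_distribution_centred_on_zero(self, rng):
        rhos = [
            spearman_rho(rng.normal(size=22), rng.normal(size=22), n_perm=50, seed=0)[0]
            for _ in range(200)
        ]
        assert abs(np.mean(rhos)) < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(6), np.arange(6.0))

    def test_permutation_p_detects_strong_association(self, rng):
        x = np.arange(22.0)
        y = x + rng.normal(scale=2.0, size=22)
        _, p = spearman_rho(x, y, n_perm=2000, seed=3)
        assert p < 0.01


class TestSummaries:
    def test_identical_participants_zero_sd(self):
        fits = pd.DataFrame(
            {
                "participant_id": [0, 1, 0, 1],
                "task": ["motion"] * 4,
                "block": ["main"] * 4,
                "condition": ["left_closer", "left_closer", "right_closer", "right_closer"],
                "threshold": [1.1, 1.1, -8.7, -8.7],
                "width": [96.0, 96.0, 98.0, 98.0],
                "lapse": [0.01, 0.01, 0.01, 0.01],
            }
        )
        out = summarize_parameters(fits)
        assert (out["threshold_std"] == 0).all()
        assert set(out.columns) >= {
            "threshold_mean", "threshold_std", "width_mean",
            "width_std", "lapse_mean", "lapse_std",
        }
        assert len(out) == 2  # one row per condition within the block
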