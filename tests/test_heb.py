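"""Homeolog expression bias: statistic, LRTs, FDR and summaries."""

import numpy as np
import pytest
from scipy import stats

from homeobias.errors import ExcludedPairError
from homeobias.heb import (
    HEBResult,
    HomeologCounts,
    apply_fdr,
    bh_fdr,
    delta_heb,
    delta_heb_lrt,
    fold_change,
    heb_lrt,
    heb_statistic,
    heb_test,
    summarize_bias,
)


class TestHebStatistic:
    def test_equal_vectors_zero_bias(self):
        assert heb_statistic([4.2, 1.0, 7.7], [4.2, 1.0, 7.7]) == 0.0

    def test_eightfold_is_three(self):
        assert heb_statistic([8, 8, 8], [1, 1, 1]) == pytest.approx(3.0)
        assert heb_statistic([1, 1, 1], [8, 8, 8]) == pytest.approx(-3.0)

    def test_zero_side_excluded(self):
        with pytest.raises(ExcludedPairError):
            heb_statistic([0, 0, 0], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(10))
    def test_parent_relabel_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.exponential(10, 3) + 0.1
        b = rng.exponential(10, 3) + 0.1
        assert heb_statistic(a, b) == pytest.approx(-heb_statistic(b, a))


class TestFoldChange:
    def test_anchors(self):
        assert fold_change(3.0) == pytest.approx(8.0)
        assert fold_change(0.0) == pytest.approx(1.0)
        assert round(fold_change(2.21), 1) == 4.6

    def test_sign_free(self):
        assert fold_change(-1.7) == fold_change(1.7)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fold_change(float("inf"))


def binom_lrt_oracle(x_spt, x_spc, len_spt=1.0, len_spc=1.0):
    """Direct binomial log-likelihood evaluation via scipy's pmf."""
    n = x_spt + x_spc
    pi0 = len_spt / (len_spt + len_spc)
    pi1 = x_spt / n
    l1 = stats.binom.logpmf(x_spt, n, pi1)
    l0 = stats.binom.logpmf(x_spt, n, pi0)
    return 2 * (l1 - l0)


class TestHebLrt:
    def test_balanced_counts_null(self):
        lrt, p = heb_lrt(50, 50)
        assert lrt == 0.0 and p == pytest.approx(1.0)

    def test_eighty_twenty(self):
        lrt, p = heb_lrt(80, 20)
        expected = 2 * (80 * np.log(80 / 50) + 20 * np.log(20 / 50))
        assert lrt == pytest.approx(expected)  # ~38.55
        assert p < 1e-3

    def test_length_adjusted_null(self):
        # counts exactly at the length-expected proportion 2/3
        lrt, p = heb_lrt(20, 10, len_spt=2000, len_spc=1000)
        assert lrt == pytest.approx(0.0, abs=1e-12)

    def test_zero_total_excluded(self):
        with pytest.raises(ExcludedPairError):
            heb_lrt(0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            heb_lrt(-1, 5)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]).tolist() == [pytest.approx(0.03)]

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        # second hand-computed vector: q_(i) = min_{j>=i} p_(j) m / j
        np.testing.assert_allclose(
            bh_fdr([0.001, 0.008, 0.039, 0.041, 0.9]),
            [0.005, 0.02, 0.05125, 0.05125, 0.9],
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_fdr(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        assert (bh_fdr(p) >= p - 1e-15).all()


class TestDeltaHeb:
    def test_identity_and_antisymmetry(self):
        assert delta_heb(1.5, 1.5) == 0.0
        assert delta_heb(-1.0, 2.55) == pytest.approx(3.55)
        assert round(fold_change(delta_heb(-1.0, 2.55)), 1) == 11.7
        assert delta_heb(0.3, 2.0) == -delta_heb(2.0, 0.3)


def g_test_oracle(table):
    """Independent 2x2 G statistic from cell expectations under margins."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    exp = row * col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / exp), 0.0)
    return 2 * terms.sum()


class TestDeltaHebLrt:
    def test_identical_tables_null(self):
        lrt, p = delta_heb_lrt(40, 10, 40, 10)
        assert lrt == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_crossover_table_matches_g_oracle(self):
        lrt, _ = delta_heb_lrt(80, 20, 20, 80)
        assert lrt == pytest.approx(g_test_oracle([[80, 20], [20, 80]]))

    def test_zero_row_total_excluded(self):
        with pytest.raises(ExcludedPairError):
            delta_heb_lrt(0, 0, 5, 5)

    def test_monte_carlo_calibration(self):
        """Constant true bias across conditions: rejection at alpha = 0.05
        stays near nominal (Poisson counts, the model's own regime)."""
        rng = np.random.default_rng(314159)
        n = 10_000
        x1s = rng.poisson(350, n)
        x1c = rng.poisson(150, n)
        x2s = rng.poisson(700, n)
        x2c = rng.poisson(300, n)
        ok = (x1s + x1c > 0) & (x2s + x2c > 0)
        _, p = delta_heb_lrt(x1s[ok], x1c[ok], x2s[ok], x2c[ok])
        assert 0.04 < (p < 0.05).mean() < 0.06


class TestResultAssembly:
    def _results(self, bs, ps, condition="C"):
        return [
            HEBResult(pair_id=f"p{i}", condition=condition, b=b,
                      lrt_stat=0.0, p_value=p)
            for i, (b, p) in enumerate(zip(bs, ps))
        ]

    def test_heb_test_wraps_statistic_and_lrt(self):
        h = HomeologCounts(
            pair_id="x", condition="C",
            spt_counts=[40, 30, 30], spc_counts=[5, 5, 0],
            spt_rpkm=[8.0, 6.0, 6.0], spc_rpkm=[1.0, 1.0, 0.0],
            len_spt=1000, len_spc=1000,
        )
        r = heb_test(h)
        assert r.b == pytest.approx(np.log2(np.mean([8, 6, 6]) / np.mean([1, 1, 0])))
        lrt, p = heb_lrt(100, 10)
        assert (r.lrt_stat, r.p_value) == (pytest.approx(lrt), pytest.approx(p))

    def test_apply_fdr_directions(self):
        res = self._results([2.0, -3.0, 0.5], [1e-6, 1e-8, 0.9])
        apply_fdr(res, 0.05)
        assert [r.direction for r in res] == ["toward_P1", "toward_P2", "none"]
        assert all(r.q_value >= r.p_value for r in res)

    def test_summary_arithmetic(self):
        res = self._results([2.0, 2.0, -1.0, 0.2], [1e-5, 1e-5, 1e-5, 0.8])
        apply_fdr(res, 0.05)
        s = summarize_bias(res)
        assert (s.n_toward_p1, s.n_toward_p2) == (2, 1)
        assert s.mean_b_toward_p1 == pytest.approx(2.0)
        assert s.fold_toward_p1 == pytest.approx(4.0)
        assert s.mean_b_toward_p2 == pytest.approx(-1.0)
        assert s.fold_toward_p2 == pytest.approx(2.0)
        assert s.pct_biased == pytest.approx(75.0)

    def test_summary_without_significant_pairs(self):
        res = self._results([0.5, -0.5], [0.8, 0.9])
        apply_fdr(res, 0.05)
        s = summarize_bias(res)
        assert s.n_significant == 0
        assert s.mean_b_toward_p1 is None and s.fold_toward_p1 is None

    def test_summary_rejects_empty_and_mixed_conditions(self):
        with pytest.raises(ValueError):
            summarize_bias([])
        mixed = self._results([1.0], [0.5]) + self._results([1.0], [0.5], "D")
        with pytest.raises(ValueError, match="conditions"):
            summarize_bias(mixed)
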