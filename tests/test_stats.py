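"""Normality screen, Welch tests, BH adjustment and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cephalomorph import ProportionVector, bh_adjust, compare_groups, ks_normality, welch_t
from cephalomorph.stats import normality_report


def bh_step_up_oracle(p):
    """Literal step-up definition: adj(i) = min_{j >= i} min(1, p(j) m / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank_i in range(m):
        adj_sorted[rank_i] = min(
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_i, m)
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestKSNormality:
    def test_perfect_normal_scores_fit_well(self):
        x = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        D, p = ks_normality(x)
        assert D < 0.05
        assert p > 0.05

    def test_statistic_matches_ecdf_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 60))
            D, _ = ks_normality(x)
            xs = np.sort(x)
            F = sps.norm.cdf(xs, loc=x.mean(), scale=x.std(ddof=1))
            n = len(x)
            d_plus = np.max(np.arange(1, n + 1) / n - F)
            d_minus = np.max(F - np.arange(0, n) / n)
            assert D == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_gross_misfit_detected_at_large_n(self):
        x = np.random.default_rng(7).uniform(0, 1, size=500)
        _, p = ks_normality(x)
        assert p < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality([2.0, 2.0, 2.0, 2.0])


class TestWelchT:
    def test_identical_samples(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_formula(self):
        # means 2.5 and 3.5, both variances 5/3, n = 4 each
        t, df, p = welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        expected_t = -1.0 / np.sqrt(5 / 3 / 4 + 5 / 3 / 4)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert df == pytest.approx(6.0, abs=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), 6), abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=12), rng.normal(loc=0.4, size=9)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert df1 == pytest.approx(df2, abs=1e-12)

    def test_constant_equal_samples_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            welch_t([3.0, 3.0], [3.0, 3.0])

    def test_null_type_one_error_rate_is_calibrated(self):
        """Empirical size at alpha=0.05 over 2000 null comparisons."""
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(2000):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            _, _, p = welch_t(a, b)
            rejections += p < 0.05
        assert 0.035 <= rejections / 2000 <= 0.065


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.04, 0.03]), [0.015, 0.04, 0.04], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), bh_step_up_oracle(p), atol=1e-12)

    def test_monotone_and_unit_stable(self, rng):
        p = rng.uniform(size=8)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        sorted_adj = np.array(adj)[np.argsort(p)]
        assert np.all(np.diff(sorted_adj) >= -1e-15)
        np.testing.assert_array_equal(bh_adjust(np.ones(8)), np.ones(8))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=20,
        )
    )
    def test_property_matches_step_up_definition(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_step_up_oracle(p), atol=1e-12)
        assert np.all((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0))


def _props_from_matrix(M):
    return [ProportionVector(*row) for row in M]


class TestCompareGroups:
    def test_identical_groups_nothing_significant(self, rng):
        M = rng.normal(loc=1.5, scale=0.1, size=(15, 8))
        table = compare_groups(_props_from_matrix(M), _props_from_matrix(M.copy()))
        assert table.n_significant == 0
        assert np.all(table.table["adj_p"] >= table.alpha)

    def test_planted_shifts_are_exactly_recovered(self, rng):
        base = rng.normal(loc=2.0, scale=0.05, size=(40, 8))
        shifted = rng.normal(loc=2.0, scale=0.05, size=(40, 8))
        planted = [1, 4, 6]
        null = [j for j in range(8) if j not in planted]
        shifted[:, null] = base[:, null]  # no effect at all off the planted set
        shifted[:, planted] += 1.0  # shift >> noise
        table = compare_groups(_props_from_matrix(base), _props_from_matrix(shifted))
        sig = set(np.nonzero(table.table["significant"].to_numpy())[0])
        assert sig == set(planted)

    def test_fdr_controlled_on_planted_signal_simulation(self):
        """Empirical FDR <= alpha + 0.03 with m=8, 3 true effects, 500 reps."""
        rng = np.random.default_rng(2023)
        fdp = []
        true = {0, 3, 7}
        for _ in range(500):
            a = rng.normal(size=(20, 8))
            b = rng.normal(size=(20, 8))
            for j in true:
                b[:, j] += 1.2
            table = compare_groups(_props_from_matrix(a), _props_from_matrix(b))
            sig = set(np.nonzero(table.table["significant"].to_numpy())[0])
            if sig:
                fdp.append(len(sig - true) / len(sig))
            else:
                fdp.append(0.0)
        assert np.mean(fdp) <= 0.05 + 0.03

    def test_text_report_layout_round_trips(self, rng):
        M = rng.normal(loc=1.5, scale=0.1, size=(10, 8))
        table = compare_groups(
            _props_from_matrix(M), _props_from_matrix(M + 0.05),
            label_a="female", label_b="male",
        )
        text = table.to_text()
        lines = text.splitlines()
        assert lines[0].split() == ["Proportion", "female", "male", "Adj.", "p"]
        assert len(lines) == 9
        # numbers in the text equal the table rounded to 3 decimals
        for line, (_, row) in zip(lines[1:], table.table.iterrows()):
            vals = line.split()
            assert float(vals[1]) == pytest.approx(round(row["mean_a"], 3))
            assert float(vals[3]) == pytest.approx(round(row["adj_p"], 3))

    def test_normality_report_shape(self, rng):
        groups = {
            "female": _props_from_matrix(rng.normal(1.5, 0.1, (12, 8))),
            "male": _props_from_matrix(rng.normal(1.6, 0.1, (14, 8))),
        }
        rep = normality_report(groups)
        assert len(rep) == 16
        assert rep["D"].between(0, 1).all()
        assert rep["normal_assumed"].all()  # gaussian data should pass the screen
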