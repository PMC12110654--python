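"""Pooled t/Cohen's d, Mann-Whitney, Pearson, leave-one-out, AQ summary."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import syncphase as sp
from syncphase.exceptions import DegenerateSignalError, ValidationError
from syncphase.group_stats import Summary, holm_correction


class TestTAndD:
    def test_printed_summary_mode(self):
        # temporal-variability contrast from published group summaries
        r = sp.t_and_d(Summary(311.1, 51.8, 18), Summary(384.4, 86.1, 18),
                       metric_name="sd_ms")
        assert r.t_stat == pytest.approx(-3.10, abs=0.01)
        assert r.cohens_d == pytest.approx(-1.03, abs=0.01)
        assert r.df == 34
        assert r.p_two_sided == pytest.approx(0.0039, abs=0.0005)

    def test_tuple_summaries_accepted(self):
        r = sp.t_and_d((10.0, 2.0, 12), (8.0, 2.0, 12))
        assert r.cohens_d == pytest.approx(1.0)

    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=30),
           st.lists(st.floats(-10, 10), min_size=4, max_size=30))
    def test_raw_equals_summary_mode(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        if np.std(a, ddof=1) + np.std(b, ddof=1) < 1e-9:
            return
        raw = sp.t_and_d(a, b)
        summ = sp.t_and_d(
            Summary(a.mean(), a.std(ddof=1), len(a)),
            Summary(b.mean(), b.std(ddof=1), len(b)),
        )
        assert raw.t_stat == pytest.approx(summ.t_stat, abs=1e-12)
        assert raw.cohens_d == pytest.approx(summ.cohens_d, abs=1e-12)

    def test_sign_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1.5, 20)
        f, r = sp.t_and_d(a, b), sp.t_and_d(b, a)
        assert f.t_stat == pytest.approx(-r.t_stat)
        assert f.cohens_d == pytest.approx(-r.cohens_d)
        assert f.p_two_sided == pytest.approx(r.p_two_sided)

    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = sp.t_and_d(a, a)
        assert r.t_stat == 0.0
        assert r.cohens_d == 0.0

    def test_zero_variance_error(self):
        with pytest.raises(DegenerateSignalError):
            sp.t_and_d([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_welch_equal_variance_agrees_on_t(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        pooled, welch = sp.t_and_d(a, b), sp.t_and_d(a, b, welch=True)
        # equal n: identical t, df differs unless variances match exactly
        assert welch.t_stat == pytest.approx(pooled.t_stat, abs=1e-12)
        assert welch.df <= pooled.df

    def test_p_values_uniform_under_null(self, rng):
        # 2000 null replicates of an 18-vs-18 comparison; the p-value
        # ECDF must stay within the DKW band around uniform
        reps, n = 2000, 18
        a = rng.normal(size=(reps, n))
        b = rng.normal(size=(reps, n))
        ps = np.array([sp.t_and_d(a[i], b[i]).p_two_sided for i in range(reps)])
        ecdf_dev = np.max(np.abs(np.sort(ps) - (np.arange(1, reps + 1) / reps)))
        eps = math.sqrt(math.log(2 / 1e-3) / (2 * reps))  # alpha = 0.001
        assert ecdf_dev < eps


class TestMannWhitney:
    def test_complete_separation(self):
        r = sp.mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u_stat == 0.0
        assert r.test == "mann_whitney"

    def test_identical_samples_p_one(self):
        r = sp.mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.p_two_sided == pytest.approx(1.0)

    @given(st.lists(st.integers(1, 5), min_size=18, max_size=18),
           st.lists(st.integers(1, 5), min_size=18, max_size=18))
    def test_u_matches_pair_counting_oracle(self, a, b):
        r = sp.mann_whitney(a, b)
        u_oracle = sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )
        assert r.u_stat == pytest.approx(u_oracle)

    def test_empty_sample_error(self):
        with pytest.raises(ValidationError):
            sp.mann_whitney([], [1.0])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r = sp.pearson(x, 2 * x + 1)
        assert r.r == pytest.approx(1.0)
        assert r.n == 10

    def test_orthogonal_residuals_give_zero(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y_perp = y - (np.dot(x - x.mean(), y) / np.dot(x - x.mean(), x - x.mean())) * (x - x.mean())
        y_perp = y_perp - y_perp.mean() + 0.0
        # re-orthogonalize exactly against centered x
        xc = x - x.mean()
        y_perp = y_perp - (np.dot(xc, y_perp) / np.dot(xc, xc)) * xc
        assert sp.pearson(x, y_perp).r == pytest.approx(0.0, abs=1e-12)

    def test_fixed_table_against_sum_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert sp.pearson(x, y).r == pytest.approx(r_oracle, abs=1e-12)

    def test_constant_input_error(self):
        with pytest.raises(ValidationError):
            sp.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLeaveOneOut:
    @pytest.fixture
    def table(self, rng):
        rows = []
        for g, loc in (("TD", 10.0), ("ASD", 4.0)):
            for k in range(18):
                rows.append({"dyad_id": f"{g}{k}", "group": g,
                             "density_per_min": rng.normal(loc, 1.0)})
        return pd.DataFrame(rows)

    def test_df_drops_by_one(self, table):
        full = sp.compare_groups(table, ["density_per_min"])["density_per_min"]
        loo = sp.leave_one_out(table, "density_per_min", "ASD3")
        assert full.df == 34
        assert loo.df == 33
        assert loo.n_b == 17

    def test_excluding_mean_value_leaves_mean(self, rng):
        df = pd.DataFrame({
            "dyad_id": list("abcdef"),
            "group": ["TD"] * 3 + ["ASD"] * 3,
            "m": [1.0, 2.0, 3.0, 5.0, 6.0, 7.0],
        })
        r = sp.leave_one_out(df, "m", "b")  # value 2.0 equals TD mean
        assert r.mean_a == pytest.approx(2.0)

    def test_unknown_dyad_error(self, table):
        with pytest.raises(ValidationError):
            sp.leave_one_out(table, "density_per_min", "nope")

    def test_large_effect_stable_under_any_single_exclusion(self, table):
        # large simulated effect: the significance pattern must survive
        # every possible single-dyad exclusion
        for dyad in table["dyad_id"]:
            r = sp.leave_one_out(table, "density_per_min", dyad)
            assert r.p_two_sided < 0.01


class TestAqSummary:
    def test_single_value(self):
        mean, sd = sp.aq_summary([10])
        assert mean == 10.0
        assert math.isnan(sd)

    def test_all_equal(self):
        mean, sd = sp.aq_summary([7, 7, 7])
        assert (mean, sd) == (7.0, 0.0)


def test_holm_correction():
    raw = [0.01, 0.04, 0.03, 0.005]
    adj = holm_correction(raw)
    assert all(a >= p for a, p in zip(adj, raw))
    assert max(adj) <= 1.0
    # smallest raw p gets the full Bonferroni factor
    assert adj[3] == pytest.approx(0.02)


def test_compare_groups_requires_two_levels():
    df = pd.DataFrame({"group": ["A", "B", "C"], "m": [1.0, 2.0, 3.0]})
    with pytest.raises(ValidationError):
        sp.compare_groups(df, ["m"])
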