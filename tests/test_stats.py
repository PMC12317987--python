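"""Group statistics: behavioral summaries, repeated-measures ANOVA,
normality-routed paired tests, Spearman matrices and BH-FDR."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ncreann as nc
from ncreann.containers import ValidationError
from ncreann.stats import AnovaEffect, asymmetry_tests


def brute_force_bh(p_values, q):
    """Test every candidate threshold; reject at the best admissible one."""
    p = np.asarray(p_values)
    m = p.size
    best = 0.0
    for candidate in p:
        k = int(np.sum(p <= candidate))
        if candidate <= k / m * q:
            best = max(best, candidate)
    return p <= best if best > 0 else np.zeros(m, dtype=bool), best


def make_behavior_table(hit_matrix, rt=500.0):
    """Build a trial table whose per-cell hit rates match ``hit_matrix``
    (n_subjects x 4 cells as fractions over 10 trials)."""
    cells = [(r, o) for r in ("repetition", "alternation")
             for o in ("no overlap", "full overlap")]
    rows = []
    for s, cell_rates in enumerate(hit_matrix):
        trial = 0
        for (resp, ov), rate in zip(cells, cell_rates):
            n_correct = int(round(rate * 10))
            for k in range(10):
                correct = k < n_correct
                rows.append({"subject": s, "trial": trial,
                             "response_relation": resp, "overlap": ov,
                             "correct_r1": True, "correct_r2": correct,
                             "rt_ms": rt if correct else np.nan})
                trial += 1
    return pd.DataFrame(rows)


class TestSummarizeBehavior:
    def test_hit_rate_arithmetic(self):
        table = make_behavior_table([[0.9, 1.0, 0.5, 0.0]])
        out = nc.summarize_behavior(table)
        got = dict(zip(zip(out.response_relation, out.overlap), out.hit_rate_pct))
        assert got[("repetition", "no overlap")] == pytest.approx(90.0)
        assert got[("repetition", "full overlap")] == pytest.approx(100.0)
        assert got[("alternation", "no overlap")] == pytest.approx(50.0)
        assert got[("alternation", "full overlap")] == pytest.approx(0.0)

    def test_zero_correct_cell_reports_missing_rt(self):
        table = make_behavior_table([[0.9, 1.0, 0.5, 0.0]])
        out = nc.summarize_behavior(table)
        empty = out[(out.response_relation == "alternation") & (out.overlap == "full overlap")]
        assert np.isnan(empty["mean_rt_ms"].iloc[0])

    def test_missing_cell_rejected_with_subject_name(self):
        table = make_behavior_table([[0.9, 1.0, 0.5, 0.2]])
        table = table[~((table.response_relation == "alternation") &
                        (table.overlap == "full overlap"))]
        with pytest.raises(ValidationError, match="subject 0"):
            nc.summarize_behavior(table)


class TestRmAnova2x2:
    def test_identical_cells_give_null_result(self):
        y = np.tile(np.array([[1.0, 1.0], [1.0, 1.0]]), (8, 1, 1))
        y += np.arange(8)[:, None, None]  # subject offsets only
        out = nc.rm_anova_2x2(y)
        for effect in out.values():
            assert effect.F == pytest.approx(0.0, abs=1e-20)
            assert effect.p == pytest.approx(1.0)

    def test_interaction_f_equals_squared_paired_t(self, rng):
        """Algebraic identity: the 1-df interaction F is the square of the
        paired t on the per-subject difference of differences."""
        for _ in range(50):
            y = rng.normal(size=(12, 2, 2))
            dod = (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])
            t, p_t = sps.ttest_1samp(dod, 0.0)
            out = nc.rm_anova_2x2(y)["interaction"]
            assert out.F == pytest.approx(t**2, abs=1e-8 * max(1.0, t**2))
            assert out.p == pytest.approx(p_t, abs=1e-10)

    def test_partial_eta_squared_identity(self, rng):
        y = rng.normal(size=(10, 2, 2))
        for effect in nc.rm_anova_2x2(y).values():
            expected = effect.F / (effect.F + effect.df2)
            assert effect.partial_eta_sq == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(size=(9, 2, 2))
        rows = []
        for s in range(9):
            for a, resp in enumerate(("repetition", "alternation")):
                for b, ov in enumerate(("none", "full")):
                    rows.append({"subject": s, "response": resp, "overlap": ov,
                                 "y": y[s, a, b]})
        df = pd.DataFrame(rows)
        ref = pingouin.rm_anova(data=df, dv="y", within=["response", "overlap"],
                                subject="subject", detailed=True)
        ours = nc.rm_anova_2x2(y)
        for name, key in (("response", "response"), ("overlap", "overlap"),
                          ("interaction", "response * overlap")):
            row = ref[ref.Source == key].iloc[0]
            assert ours[name].F == pytest.approx(row["F"], rel=1e-6)
            assert ours[name].p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError, match="3 subjects"):
            nc.rm_anova_2x2(np.zeros((2, 2, 2)))


class TestPairedCompare:
    def test_identical_samples_give_t_zero_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = nc.paired_compare(a, a)
        assert res.test == "t" and res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_t_statistic(self):
        d = np.array([1.0, 2, 3, 2, 1, 2, 3, 2, 1, 2])
        res = nc.paired_compare(d, np.zeros_like(d))
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        if res.test == "t":
            assert res.statistic == pytest.approx(expected, abs=5e-5)
        else:  # routed to Wilcoxon by the normality screen; check the t branch directly
            res_t = nc.paired_compare(d, np.zeros_like(d), alpha_normality=0.0)
            assert res_t.statistic == pytest.approx(expected, abs=5e-5)

    def test_skewed_differences_route_to_wilcoxon(self):
        rng = np.random.default_rng(0)
        routed = 0
        for _ in range(100):
            d = rng.exponential(1.0, size=30) ** 2
            res = nc.paired_compare(d, np.zeros_like(d))
            routed += res.test == "wilcoxon"
        assert routed >= 90

    def test_normal_differences_route_to_t(self):
        rng = np.random.default_rng(1)
        routed = 0
        for _ in range(100):
            d = rng.normal(0.5, 1.0, size=30)
            res = nc.paired_compare(d, np.zeros_like(d))
            routed += res.test == "t"
        assert routed >= 85  # Lilliefors alpha=.05: ~5% of normal samples flagged

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match=">= 5"):
            nc.paired_compare(np.arange(4.0), np.zeros(4))


class TestSpearmanMatrix:
    def test_monotone_pairs_have_unit_magnitude_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6],
                           "y": [2.0, 4, 9, 16, 30, 55],
                           "z": [10.0, 8, 5, 4, 2, 1]})
        r, _, n = nc.spearman_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)
        assert (n.loc["x", "y"], n.loc["x", "z"]) == (6, 6)

    def test_worked_example_rs_0_7(self):
        # ranks d = [0, 0, -1, -1, 2], sum d^2 = 6: r_s = 1 - 36/120 = 0.7
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0, 2, 4, 5, 3]})
        r, p, n = nc.spearman_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(0.7, abs=1e-12)
        assert n.loc["x", "y"] == 5

    def test_invariant_to_strictly_monotone_transforms(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        df1 = pd.DataFrame({"x": x, "y": y})
        df2 = pd.DataFrame({"x": np.exp(x), "y": y**3})
        r1, p1, _ = nc.spearman_matrix(df1)
        r2, p2, _ = nc.spearman_matrix(df2)
        assert r1.loc["x", "y"] == pytest.approx(r2.loc["x", "y"], abs=1e-12)
        assert p1.loc["x", "y"] == pytest.approx(p2.loc["x", "y"], abs=1e-12)

    def test_pairwise_complete_missing_handling(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, np.nan, 7],
                           "y": [2.0, 3, 4, 5, 6, 7, np.nan],
                           "z": [1.0, 2, 3, 4, 5, 6, 7]})
        r, _, n = nc.spearman_matrix(df)
        assert n.loc["x", "y"] == 5
        assert n.loc["x", "z"] == 6
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_sparse_pair_reported_missing_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, np.nan, np.nan, np.nan],
                           "y": [np.nan, np.nan, np.nan, 1.0, 2, 3],
                           "z": np.arange(6.0)})
        with pytest.warns(UserWarning, match="complete subjects"):
            r, p, n = nc.spearman_matrix(df)
        assert np.isnan(r.loc["x", "y"]) and n.loc["x", "y"] == 0


class TestBhFdr:
    def test_step_up_enumeration_by_hand(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.05])
        rejected, critical = nc.bh_fdr(p, q=0.05)
        assert rejected.all()
        assert critical == pytest.approx(0.05)

    def test_all_ones_rejects_nothing(self):
        rejected, critical = nc.bh_fdr(np.ones(7), q=0.05)
        assert not rejected.any() and critical == 0.0

    def test_single_p_reduces_to_alpha_test(self):
        rejected, critical = nc.bh_fdr(np.array([0.04]), q=0.05)
        assert rejected[0] and critical == pytest.approx(0.04)

    def test_agrees_with_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            got_mask, got_crit = nc.bh_fdr(p, q=0.05)
            ref_mask, ref_crit = brute_force_bh(p, 0.05)
            assert np.array_equal(got_mask, ref_mask)
            assert got_crit == pytest.approx(ref_crit)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            nc.bh_fdr(np.array([]))


class TestAsymmetryTests:
    def test_detects_strong_directional_asymmetry(self, rng):
        mats = np.abs(rng.normal(0.1, 0.02, size=(40, 2, 2)))
        mats[:, 0, 1] += 0.2  # 0 -> 1 consistently stronger
        out = asymmetry_tests(mats)
        assert len(out) == 1
        assert out.iloc[0]["p"] < 0.001
        assert out.iloc[0]["forward_mean"] > out.iloc[0]["reverse_mean"]

    def test_symmetric_null_is_usually_not_significant(self, rng):
        hits = 0
        for _ in range(20):
            mats = np.abs(rng.normal(0.1, 0.02, size=(15, 2, 2)))
            hits += asymmetry_tests(mats).iloc[0]["p"] < 0.05
        assert hits <= 4
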