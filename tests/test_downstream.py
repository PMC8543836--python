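import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tpsc import (
    ExpressionMatrix,
    ModulePartition,
    ValidationError,
    bh_fdr,
    eigengene,
    logrank_test,
    module_survival_table,
    overlap_fisher,
    overlap_matrix,
    split_by_eigengene,
)


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestEigengene:
    def test_identical_copies_are_rank_one(self):
        v = np.array([1.0, 4.0, 2.0, 6.0, 3.0])
        expr = _expr(np.vstack([v, 2 * v + 1, 0.5 * v - 3]))
        eig = eigengene(expr)
        assert eig.explained_variance_fraction == pytest.approx(1.0)
        z = (v - v.mean()) / v.std(ddof=1)
        corr = np.corrcoef(eig.values, z)[0, 1]
        assert corr == pytest.approx(1.0)  # sign convention: aligned with mean

    def test_recovers_shared_factor_under_noise(self):
        rng = np.random.default_rng(1)
        factor = rng.standard_normal(40)
        X = np.vstack([factor + 0.05 * rng.standard_normal(40) for _ in range(30)])
        eig = eigengene(_expr(X))
        assert abs(np.corrcoef(eig.values, factor)[0, 1]) > 0.99

    def test_global_sign_flip_flips_eigengene(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 20))
        e1 = eigengene(_expr(X))
        e2 = eigengene(_expr(-X))
        assert np.allclose(e1.values, -e2.values, atol=1e-10)

    def test_zero_variance_gene_dropped(self):
        v = np.array([1.0, 4.0, 2.0, 6.0])
        X = np.vstack([v, np.full(4, 3.0)])
        eig = eigengene(_expr(X))
        assert eig.explained_variance_fraction == pytest.approx(1.0)

    def test_unit_norm(self):
        rng = np.random.default_rng(3)
        eig = eigengene(_expr(rng.standard_normal((6, 15))))
        assert np.linalg.norm(eig.values) == pytest.approx(1.0)


class TestSplitByEigengene:
    def _surv(self, ids):
        return pd.DataFrame(
            {"time": np.arange(1.0, len(ids) + 1), "event": 1},
            index=pd.Index(ids),
        )

    def _eig(self, ids, values):
        from tpsc.downstream import Eigengene

        return Eigengene("M1", list(ids), np.asarray(values, float), 1.0)

    def test_sign_split(self):
        ids = ["s1", "s2", "s3", "s4"]
        up, down = split_by_eigengene(self._eig(ids, [0.5, -0.2, 0.1, -0.9]),
                                      self._surv(ids))
        assert up == ["s1", "s3"] and down == ["s2", "s4"]

    def test_all_positive_raises(self):
        ids = ["s1", "s2"]
        with pytest.raises(ValidationError, match="one group"):
            split_by_eigengene(self._eig(ids, [0.5, 0.2]), self._surv(ids))

    def test_exact_zero_goes_down(self):
        ids = ["s1", "s2", "s3"]
        up, down = split_by_eigengene(self._eig(ids, [0.5, 0.0, -0.1]),
                                      self._surv(ids))
        assert "s2" in down


class TestLogrank:
    def _table(self, times, events, ids=None):
        ids = ids or [f"s{i}" for i in range(len(times))]
        return pd.DataFrame({"time": times, "event": events}, index=pd.Index(ids))

    def test_identical_groups_null(self):
        surv = self._table([3, 5, 7, 3, 5, 7], [1, 0, 1, 1, 0, 1])
        res = logrank_test(["s0", "s1", "s2"], ["s3", "s4", "s5"], surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        # group A: (1,+),(4,+),(6,cens); group B: (2,+),(3,cens),(5,+)
        # hand O-E = 1/2 - 2/5 + 1/3 - 1/2 = -1/15
        # hand variance = 1/4 + 6/25 + 2/9 + 1/4 = 433/450
        # chi-square = (1/225) / (433/450) = 2/433
        surv = self._table([1, 4, 6, 2, 3, 5], [1, 1, 0, 1, 0, 1])
        res = logrank_test(["s0", "s1", "s2"], ["s3", "s4", "s5"], surv)
        assert res.statistic == pytest.approx(2 / 433, abs=1e-10)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(2 / 433, 1)),
                                            abs=1e-12)

    def test_time_scaling_invariance(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(1, 20)
        events = rng.integers(0, 2, 20)
        events[0] = 1
        ga = [f"s{i}" for i in range(10)]
        gb = [f"s{i}" for i in range(10, 20)]
        r1 = logrank_test(ga, gb, self._table(times, events))
        r2 = logrank_test(ga, gb, self._table(times * 37.5, events))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_no_events_raises(self):
        surv = self._table([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValidationError, match="no observed events"):
            logrank_test(["s0", "s1"], ["s2", "s3"], surv)

    def test_agrees_with_lifelines_on_random_data(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(11)
        for _ in range(100):
            na, nb = rng.integers(4, 15, 2)
            times = rng.exponential(1, na + nb).round(2)  # force some ties
            events = rng.integers(0, 2, na + nb)
            if events.sum() == 0:
                events[0] = 1
            surv = self._table(times, events)
            ga = [f"s{i}" for i in range(na)]
            gb = [f"s{i}" for i in range(na, na + nb)]
            mine = logrank_test(ga, gb, surv)
            ref = lifelines_stats.logrank_test(
                times[:na], times[na:], events[:na], events[na:]
            )
            assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-10)


class TestBHFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_step_up_arithmetic(self):
        # p*m/rank with cumulative minimum from the largest rank down
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p_and_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        ref = sm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)


class TestOverlapFisher:
    def test_complete_overlap_closed_form(self):
        genes = [f"g{i}" for i in range(10)]
        universe = [f"g{i}" for i in range(100)]
        t = overlap_fisher(genes, genes, universe)
        assert t.p_value == pytest.approx(1 / math.comb(100, 10), rel=1e-12)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        t = overlap_fisher(universe[:5], universe[5:10], universe)
        assert t.overlap_count == 0
        assert t.p_value == pytest.approx(1.0)

    def test_brute_force_hypergeometric_tail(self):
        # 2x2 table (5,5,5,85): overlap 5, |a|=|b|=10, universe 100
        universe = [f"g{i}" for i in range(100)]
        a = universe[:10]
        b = universe[5:15]
        t = overlap_fisher(a, b, universe)
        expected = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10)
            for k in range(5, 11)
        )
        assert t.p_value == pytest.approx(expected, rel=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(50)]
        a = list(rng.choice(universe, 12, replace=False))
        b = list(rng.choice(universe, 20, replace=False))
        assert overlap_fisher(a, b, universe).p_value == pytest.approx(
            overlap_fisher(b, a, universe).p_value, rel=1e-12
        )

    def test_empty_set_raises(self):
        with pytest.raises(ValidationError):
            overlap_fisher([], ["g1"], ["g1", "g2"])


class TestModuleSummaries:
    def test_survival_screen_table(self):
        rng = np.random.default_rng(8)
        factor = rng.standard_normal(30)
        X = np.vstack(
            [factor + 0.2 * rng.standard_normal(30) for _ in range(6)]
            + [rng.standard_normal(30) for _ in range(6)]
        )
        expr = _expr(X)
        part = ModulePartition(expr.gene_ids, [1] * 6 + [2] * 6, k=2)
        surv = pd.DataFrame(
            {"time": rng.exponential(1, 30), "event": 1},
            index=pd.Index(expr.sample_ids),
        )
        table = module_survival_table(expr, part, surv)
        assert list(table["module"]) == ["M1", "M2"]
        ok = table["p_value"].notna()
        assert np.all(table.loc[ok, "q_value"] >= table.loc[ok, "p_value"] - 1e-15)

    def test_overlap_matrix_shape(self):
        pa = ModulePartition(list("abcd"), [1, 1, 2, 2], k=2)
        pb = ModulePartition(list("abcd"), [1, 2, 1, 2], k=2)
        df = overlap_matrix(pa, pb)
        assert len(df) == 4
        assert set(df.columns) == {"module_a", "module_b", "overlap", "p_value"}
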