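import math

import numpy as np
import pandas as pd
import pytest

from mirnorm import errors, preprocess as pp, stability as st
from mirnorm.io import FamilyMap

from conftest import make_annotation, make_rq

SD0123 = math.sqrt(5.0 / 3.0)  # sample SD of {0,1,2,3}


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

class TestGeNorm:
    def test_worked_example(self, genorm_example):
        res = st.genorm(genorm_example)
        # A and B are exactly proportional, C is constant
        assert res.stepwise_m["C"] == pytest.approx(SD0123, abs=1e-12)
        assert res.stepwise_m["A"] == 0.0 and res.stepwise_m["B"] == 0.0
        assert res.elimination_order[0] == "C"
        assert res.final_pair == ("A", "B")
        # full-set round M values
        first = res.rounds[0]
        assert first["A"] == pytest.approx(SD0123 / 2, abs=1e-12)
        assert first["B"] == pytest.approx(SD0123 / 2, abs=1e-12)
        assert first["C"] == pytest.approx(SD0123, abs=1e-12)

    def test_proportional_detectors_have_zero_pairwise_v(self):
        rq = make_rq([[1, 2, 3], [5, 10, 15], [1, 4, 2]], detectors=["A", "B", "C"])
        res = st.genorm(rq)
        assert res.final_pair == ("A", "B")
        assert res.stepwise_m["A"] == pytest.approx(0.0, abs=1e-12)

    def test_sample_scaling_leaves_result_unchanged(self, genorm_example):
        scaled = genorm_example.copy()
        scaled.rq.iloc[:, 1] *= 7.0
        a, b = st.genorm(genorm_example), st.genorm(scaled)
        assert a.elimination_order == b.elimination_order
        pd.testing.assert_series_equal(a.stepwise_m, b.stepwise_m, atol=1e-10, rtol=0)

    def test_tie_removes_lexicographically_larger_id(self):
        # two identical constant rows tie at the highest M
        rq = make_rq([[1, 2, 4], [2, 4, 8], [1, 1, 1], [1, 1, 1]],
                     detectors=["A", "B", "Cz", "Ca"])
        res = st.genorm(rq)
        assert res.elimination_order[0] == "Cz"

    def test_requires_three_detectors_and_completeness(self):
        with pytest.raises(errors.InputError):
            st.genorm(make_rq([[1, 2], [2, 4]]))
        with pytest.raises(errors.InputError):
            st.genorm(make_rq([[1, 2], [2, np.nan], [1, 1]]))


def brute_force_genorm(frame):
    """Independent oracle: pure-python pairwise SDs and elimination."""
    import statistics

    logs = {d: [math.log2(v) for v in frame.loc[d]] for d in frame.index}
    remaining = list(frame.index)
    stepwise, order = {}, []
    while True:
        m_vals = {}
        for a in remaining:
            vs = []
            for b in remaining:
                if a == b:
                    continue
                ratios = [x - y for x, y in zip(logs[a], logs[b])]
                vs.append(statistics.stdev(ratios))
            m_vals[a] = sum(vs) / len(vs)
        if len(remaining) == 2:
            for d in remaining:
                stepwise[d] = m_vals[d]
            order.extend(sorted(remaining, reverse=True))
            return stepwise, order
        worst = max(remaining, key=lambda d: (m_vals[d], d))
        stepwise[worst] = m_vals[worst]
        order.append(worst)
        remaining.remove(worst)


def test_genorm_matches_brute_force_on_random_matrices(random_rq):
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        m, n = rng.integers(4, 9), rng.integers(3, 9)
        rq = random_rq(int(m), int(n), seed=200 + seed)
        res = st.genorm(rq)
        exp_m, exp_order = brute_force_genorm(rq.rq)
        assert res.elimination_order == exp_order
        for d, val in exp_m.items():
            assert res.stepwise_m[d] == pytest.approx(val, abs=1e-10)


class TestPairwiseV:
    def test_zero_when_added_detector_equals_current_nf(self):
        rng = np.random.default_rng(0)
        two = np.exp2(rng.normal(size=(2, 5)))
        nf = np.exp2(np.log2(two).mean(axis=0))
        rq = make_rq(np.vstack([two, nf]), detectors=["a", "b", "c"])
        v = st.genorm_pairwise_v(rq, ranking=["a", "b", "c"])
        assert v[2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_when_nfs_differ_by_constant_factor(self):
        rq = make_rq([[1, 2, 4], [4, 8, 16], [2, 4, 8]], detectors=["a", "b", "c"])
        v = st.genorm_pairwise_v(rq, ranking=["a", "b", "c"])
        assert v[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_recomputation_on_fixture(self, random_rq):
        rq = random_rq(4, 6, seed=42)
        ranking = st.genorm(rq).ranking
        v = st.genorm_pairwise_v(rq, ranking)
        logx = np.log2(rq.rq.loc[ranking].to_numpy())
        for n in (2, 3):
            nf_n = logx[:n].mean(axis=0)
            nf_n1 = logx[: n + 1].mean(axis=0)
            assert v[n] == pytest.approx(np.std(nf_n - nf_n1, ddof=1), abs=1e-12)

    def test_rejects_non_permutation_ranking(self, random_rq):
        rq = random_rq(4, 5, seed=1)
        with pytest.raises(errors.InputError):
            st.genorm_pairwise_v(rq, ranking=["d00", "d01"])


# ---------------------------------------------------------------------------
# Normfinder-style estimator
# ---------------------------------------------------------------------------

class TestNormfinder:
    def test_exactly_additive_data_gives_zero_rho(self):
        # y = a_i + b_gj: residuals and group effects vanish
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([0.5, -0.2, 0.1, 0.9, -0.6, 0.3])
        y = a[:, None] + b[None, :]
        rq = make_rq(np.exp2(y), samples=[f"s{j+1}" for j in range(6)])
        ann = make_annotation(["A"] * 3 + ["B"] * 3, samples=rq.sample_ids)
        rho = st.normfinder(rq, ann)
        assert rho.abs().max() < 1e-10

    def test_group_shift_increases_rho_of_shifted_twin(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 0.3, size=(6, 12))
        y[1] = y[0].copy()       # twins
        y[1, 6:] += 1.5          # group-mean shift on the twin
        rq = make_rq(np.exp2(y))
        ann = make_annotation(["A"] * 6 + ["B"] * 6, samples=rq.sample_ids)
        rho = st.normfinder(rq, ann)
        assert rho.iloc[1] > rho.iloc[0]

    def test_single_group_rho_is_intragroup_sd(self, random_rq):
        rq = random_rq(6, 8, seed=4)
        ann = make_annotation(["all"] * 8, samples=rq.sample_ids)
        rho = st.normfinder(rq, ann)
        assert (rho >= 0).all()

    def test_single_group_equal_variance_spread_shrinks_with_n(self):
        # all detectors share one true variance; the rho spread across
        # detectors shrinks roughly like 1/sqrt(n)
        rng = np.random.default_rng(77)
        spreads = {}
        for n in (10, 160):
            reps = []
            for _ in range(30):
                y = rng.normal(0, 1, size=(1, n)) + rng.normal(0, 0.4, size=(8, n))
                rq = make_rq(np.exp2(y), samples=[f"s{j}" for j in range(n)])
                ann = make_annotation(["all"] * n, samples=rq.sample_ids)
                rho = st.normfinder(rq, ann)
                reps.append(rho.std())
            spreads[n] = np.mean(reps)
        assert spreads[160] < spreads[10] / 2  # expected factor 4

    def test_small_group_rejected(self, random_rq):
        rq = random_rq(4, 5, seed=2)
        ann = make_annotation(["A"] * 4 + ["B"], samples=rq.sample_ids)
        with pytest.raises(errors.InputError, match="B"):
            st.normfinder(rq, ann)


# ---------------------------------------------------------------------------
# CV score
# ---------------------------------------------------------------------------

class TestCvScore:
    def test_constant_shares_give_zero(self):
        rq = make_rq([[1.0, 2.0], [3.0, 6.0]], detectors=["A", "B"])
        cv = st.cv_score(rq)
        assert cv["A"] == pytest.approx(0.0, abs=1e-12)
        assert cv["B"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        rq = make_rq([[1.0, 2.0], [3.0, 2.0]], detectors=["A", "B"])
        cv = st.cv_score(rq)
        assert cv["A"] == pytest.approx(0.47140452, abs=1e-7)
        assert cv["B"] == pytest.approx(0.28284271, abs=1e-7)

    def test_invariant_to_column_scaling(self, random_rq):
        rq = random_rq(6, 7, seed=15)
        scaled = rq.copy()
        scaled.rq.iloc[:, 2] *= 9.5
        pd.testing.assert_series_equal(st.cv_score(rq), st.cv_score(scaled),
                                       atol=1e-12, rtol=0)

    def test_pseudo_rows_scored_but_not_in_denominator(self):
        rq = pp.add_pseudo_detectors(make_rq([[1.0, 2.0], [3.0, 6.0]], detectors=["A", "B"]))
        cv = st.cv_score(rq)
        # real detectors have constant shares; so do all central tendencies
        assert cv.abs().max() < 1e-12
        assert set(cv.index) == {"A", "B", "pseudo_mean", "pseudo_geomean", "pseudo_median"}


# ---------------------------------------------------------------------------
# SSS, selection, platform combination
# ---------------------------------------------------------------------------

def series(d):
    return pd.Series(d, dtype=float)


class TestSSS:
    def test_three_four_five(self):
        tab = st.sss(series({"A": 0.3}), series({"A": 0.4}), series({"A": 0.0}))
        assert tab.table.loc["A", "sss"] == pytest.approx(0.5, abs=1e-15)

    def test_zero_scores_rank_first(self):
        tab = st.sss(series({"A": 0.0, "B": 1.0}), series({"A": 0.0, "B": 1.0}),
                     series({"A": 0.0, "B": 1.0}))
        assert tab.table.loc["A", "sss"] == 0.0
        assert tab.table.loc["A", "rank"] == 1

    def test_input_order_irrelevant(self):
        m = {"A": 0.2, "B": 0.5, "C": 0.1}
        t1 = st.sss(series(m), series(m), series(m))
        t2 = st.sss(series(dict(reversed(m.items()))), series(m), series(m))
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_mismatched_detectors_rejected(self):
        with pytest.raises(errors.InputError):
            st.sss(series({"A": 1.0}), series({"B": 1.0}), series({"A": 1.0}))

    def test_rank_ties_broken_by_id(self):
        m = {"B": 0.3, "A": 0.3}
        tab = st.sss(series(m), series(m), series(m))
        assert tab.table.loc["A", "rank"] == 1 and tab.table.loc["B", "rank"] == 2

    def test_dominance(self):
        tab = st.sss(series({"a": 0.1, "b": 0.1}), series({"a": 0.2, "b": 0.3}),
                     series({"a": 0.05, "b": 0.05}))
        assert tab.table.loc["a", "sss"] < tab.table.loc["b", "sss"]


class TestSelectReferences:
    def make_table(self, scores, families=None, pseudo=()):
        ids = list(scores)
        tab = st.sss(series(scores), series({d: 0.0 for d in ids}),
                     series({d: 0.0 for d in ids}),
                     families=FamilyMap(families or {}),
                     pseudo_flags=pd.Series([d in pseudo for d in ids], index=ids))
        return tab

    def test_family_skip_rule(self):
        tab = self.make_table({"A": 0.1, "B": 0.2, "C": 0.3},
                              families={"A": "fam1", "B": "fam1", "C": "fam2"})
        fam = FamilyMap({"A": "fam1", "B": "fam1", "C": "fam2"})
        assert st.select_references(tab, fam, 2) == ["A", "C"]

    def test_pseudo_detector_skipped(self):
        tab = self.make_table({"pseudo_mean": 0.01, "A": 0.2, "B": 0.3},
                              pseudo=("pseudo_mean",))
        fam = FamilyMap.singletons(["A", "B"])
        assert st.select_references(tab, fam, 1) == ["A"]

    def test_too_few_families_is_selection_error(self):
        tab = self.make_table({"A": 0.1, "B": 0.2, "C": 0.3},
                              families={"A": "f1", "B": "f1", "C": "f1"})
        fam = FamilyMap({"A": "f1", "B": "f1", "C": "f1"})
        with pytest.raises(errors.SelectionError, match="1"):
            st.select_references(tab, fam, 3)


class TestCombinePlatforms:
    def make_tab(self, scores, platform):
        ids = list(scores)
        return st.sss(series(scores), series({d: 0.0 for d in ids}),
                      series({d: 0.0 for d in ids}), platform=platform)

    def test_minimum_on_every_platform_ranks_first(self):
        t1 = self.make_tab({"A": 0.1, "B": 0.5, "C": 0.9}, "TM")
        t2 = self.make_tab({"A": 0.2, "B": 0.8, "C": 0.4}, "EX")
        combined = st.combine_platforms([t1, t2])
        assert combined.loc["A", "combined_score"] == 0.0
        assert combined.loc["A", "rank"] == 1

    def test_detector_absent_from_one_platform_excluded(self):
        t1 = self.make_tab({"A": 0.1, "B": 0.5, "X": 0.7}, "TM")
        t2 = self.make_tab({"A": 0.2, "B": 0.8, "Y": 0.3}, "EX")
        combined = st.combine_platforms([t1, t2])
        assert set(combined.index) == {"A", "B"}

    def test_identical_tables_keep_single_platform_ranking(self):
        t = self.make_tab({"A": 0.1, "B": 0.5, "C": 0.9}, "TM")
        t2 = self.make_tab({"A": 0.1, "B": 0.5, "C": 0.9}, "EX")
        combined = st.combine_platforms([t, t2])
        single = t.ranked().index.tolist()
        assert combined.sort_values("rank").index.tolist() == single

    def test_empty_intersection_is_data_error(self):
        t1 = self.make_tab({"A": 0.1, "B": 0.2, "C": 0.3}, "TM")
        t2 = self.make_tab({"X": 0.1, "Y": 0.2, "Z": 0.3}, "EX")
        with pytest.raises(errors.DataError):
            st.combine_platforms([t1, t2])


def test_score_stability_wrapper_combines_all_three(random_rq):
    rq, ann = random_rq(6, 8, seed=21, groups=2)
    tab = st.score_stability(rq, ann)
    g = st.genorm(rq).stepwise_m
    r = st.normfinder(rq, ann)
    c = st.cv_score(rq)
    for d in rq.detector_ids:
        expect = np.sqrt(g[d] ** 2 + r[d] ** 2 + c[d] ** 2)
        assert tab.table.loc[d, "sss"] == pytest.approx(expect, abs=1e-12)
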