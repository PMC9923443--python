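import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haikal.core_data import FeatureTable
from haikal.lf_engine import (
    EPS,
    HIGHER_IS_CORRECT,
    LOWER_IS_CORRECT,
    LabelingFunction,
    apply_lf,
    build_lf,
    build_lf_matrix,
    find_thresholds,
    lf_diagnostics,
    lfs_from_text,
    lfs_to_text,
    rank_features_by_auc,
    screen_features,
    select_lfs,
)


def _table_from_columns(**cols) -> FeatureTable:
    n = len(next(iter(cols.values())))
    base = {"target_id": ["t"] * n, "decoy_id": [f"d{i}" for i in range(n)]}
    return FeatureTable(pd.DataFrame({**base, **cols}))


def brute_force_auc(values, y):
    """Concordant-pair count (+1/2 per tie) over all correct x incorrect pairs."""
    pos = [v for v, l in zip(values, y) if l]
    neg = [v for v, l in zip(values, y) if not l]
    s = 0.0
    for p in pos:
        for q in neg:
            s += 1.0 if p > q else (0.5 if p == q else 0.0)
    return s / (len(pos) * len(neg))


class TestAucRanking:
    def test_perfect_separation(self):
        t = _table_from_columns(f=[1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = [False] * 3 + [True] * 3
        r = rank_features_by_auc(t, y)
        assert r.auc("f") == 1.0
        assert r.orientation("f") == HIGHER_IS_CORRECT

    def test_uninformative_feature(self):
        t = _table_from_columns(f=[1.0, 2.0, 1.0, 2.0])
        y = [True, True, False, False]
        assert rank_features_by_auc(t, y).auc("f") == 0.5

    def test_flipped_orientation_reports_complement(self):
        # low values indicate correctness -> raw AUC < 0.5, flipped
        t = _table_from_columns(f=[1.0, 2.0, 9.0, 10.0])
        y = [True, True, False, False]
        r = rank_features_by_auc(t, y)
        assert r.orientation("f") == LOWER_IS_CORRECT
        assert r.auc("f") == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        vals = np.round(rng.standard_normal(n), 1)  # rounding makes ties
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        t = _table_from_columns(f=vals)
        r = rank_features_by_auc(t, y)
        raw = brute_force_auc(vals, y)
        expected = raw if raw >= 0.5 else 1 - raw
        assert r.auc("f") == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        t = _table_from_columns(f=[1.0, 2.0])
        with pytest.raises(ValueError):
            rank_features_by_auc(t, [True, True])


class TestScreening:
    def test_all_random_features_screened_out(self):
        t = _table_from_columns(**{f"f{i}": [1.0, 2.0, 1.0, 2.0] for i in range(5)})
        r = rank_features_by_auc(t, [True, True, False, False])
        with pytest.warns(UserWarning):
            assert screen_features(r) == []

    def test_identity_settings_keep_everything(self, labeled_table):
        r = rank_features_by_auc(labeled_table)
        kept = screen_features(r, auc_min=0.0, top_fraction=1.0)
        assert sorted(kept) == sorted(labeled_table.feature_names)

    def test_top_quarter_cap_matches_panel_arithmetic(self, rng):
        # 157 candidate scoring functions -> at most ceil(0.25*157) = 40 kept
        cols = {f"f{i:03d}": rng.standard_normal(60) for i in range(157)}
        y = np.arange(60) < 20
        shift = rng.uniform(0.5, 3.0, size=157)
        for i, name in enumerate(cols):
            cols[name] = cols[name] + shift[i] * y
        r = rank_features_by_auc(_table_from_columns(**cols), y)
        kept = screen_features(r, auc_min=0.67, top_fraction=0.25)
        assert len(kept) <= 40


def brute_force_thresholds(values, y, orientation, min_cov=0.10):
    """Independent enumeration of the two constrained ratio argmaxes.

    Scans every unique observed value as a cutoff, recomputing the
    confusion of each side's rule with plain python loops, and applies
    the same tie-breaks (ratio, own-class capture, tighter boundary) and
    midpoint-overlap adjustment.
    """
    w = [-v for v in values] if orientation == HIGHER_IS_CORRECT else list(values)
    labels = list(y)
    n_corr = sum(labels)
    n_inc = len(labels) - n_corr
    uniq = sorted(set(w))

    best_c = None
    for t in uniq:
        tp = sum(1 for v, l in zip(w, labels) if l and v <= t)
        fp = sum(1 for v, l in zip(w, labels) if not l and v <= t)
        if tp <= min_cov * n_corr:
            continue
        r_corr = tp / n_corr
        r_fp = fp / (fp + tp) if fp + tp else 0.0
        key = (r_corr / (r_fp + EPS), tp, -t)
        if best_c is None or key > best_c[0]:
            best_c = (key, t, r_corr / (r_fp + EPS), r_corr)
    best_i = None
    for t in uniq:
        tn = sum(1 for v, l in zip(w, labels) if not l and v >= t)
        fn = sum(1 for v, l in zip(w, labels) if l and v >= t)
        tp_out = n_corr - fn
        if tn <= min_cov * n_inc:
            continue
        r_inc = tn / n_inc
        r_fn = fn / (fn + tp_out) if fn + tp_out else 0.0
        key = (r_inc / (r_fn + EPS), tn, t)
        if best_i is None or key > best_i[0]:
            best_i = (key, t, r_inc / (r_fn + EPS), r_inc)
    if best_c is None or best_i is None:
        return None
    t_c, t_i = best_c[1], best_i[1]
    adjusted = t_c >= t_i
    if adjusted:
        mid = (t_c + t_i) / 2.0
        t_c, t_i = mid, float(np.nextafter(mid, np.inf))
    if orientation == HIGHER_IS_CORRECT:
        t_c, t_i = -t_c, -t_i
    return t_c, t_i, best_c[2], best_i[2], adjusted


class TestThresholdSearch:
    def test_separable_toy_has_no_abstentions(self):
        values = [0.1, 0.2, 0.8, 0.9]
        y = [True, True, False, False]
        res = find_thresholds(values, y, LOWER_IS_CORRECT)
        assert res.feasible
        assert res.t_correct == 0.2 and res.t_incorrect == 0.8
        assert res.tp_fraction == 1.0 and res.tn_fraction == 1.0
        votes = apply_lf(build_lf(res), values)
        assert (votes != 0).all()
        assert votes.tolist() == [1, 1, -1, -1]

    def test_constant_feature_is_infeasible(self):
        res = find_thresholds([3.0] * 10, [True] * 5 + [False] * 5,
                              LOWER_IS_CORRECT)
        assert not res.feasible
        assert math.isnan(res.t_correct)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("orientation", [LOWER_IS_CORRECT, HIGHER_IS_CORRECT])
    def test_matches_exhaustive_enumeration(self, seed, orientation):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        y = rng.random(n) < rng.uniform(0.2, 0.5)
        if y.all() or not y.any():
            y[:2] = [True, False]
        shift = rng.uniform(0.3, 2.0) * (1 if orientation == HIGHER_IS_CORRECT else -1)
        vals = np.round(rng.standard_normal(n) + shift * y, 2)
        res = find_thresholds(vals, y, orientation)
        oracle = brute_force_thresholds(vals, y, orientation)
        assert res.feasible == (oracle is not None)
        if oracle:
            t_c, t_i, ratio_c, ratio_i, adjusted = oracle
            assert res.t_correct == pytest.approx(t_c)
            assert res.t_incorrect == pytest.approx(t_i)
            assert res.correct_ratio == pytest.approx(ratio_c)
            assert res.incorrect_ratio == pytest.approx(ratio_i)
            assert res.overlap_adjusted == adjusted

    def test_relaxing_coverage_constraint_cannot_lower_optimum(self, rng):
        vals = np.round(rng.standard_normal(120) + 0.8 * (np.arange(120) < 40), 2)
        y = np.arange(120) < 40
        strict = find_thresholds(vals, y, HIGHER_IS_CORRECT, min_class_cov=0.3)
        loose = find_thresholds(vals, y, HIGHER_IS_CORRECT, min_class_cov=0.05)
        assert loose.correct_ratio >= strict.correct_ratio
        assert loose.incorrect_ratio >= strict.incorrect_ratio

    def test_gaussian_cutoffs_stable_at_large_n(self):
        # two class-conditional Gaussians; the selected cutoffs at n and
        # 4n agree within the empirical grid resolution
        rng = np.random.default_rng(5)
        d = 2.2

        def sample(n):
            y = rng.random(n) < 0.5
            return d * y + rng.standard_normal(n), y

        cuts = []
        for n in (4000, 16000):
            vals, y = sample(n)
            res = find_thresholds(vals, y, HIGHER_IS_CORRECT)
            assert res.feasible and not res.overlap_adjusted
            cuts.append((res.t_correct, res.t_incorrect))
        assert abs(cuts[0][0] - cuts[1][0]) < 0.35
        assert abs(cuts[0][1] - cuts[1][1]) < 0.35


class TestLabelingFunctions:
    def test_three_way_region_membership(self):
        lf = LabelingFunction("f", LOWER_IS_CORRECT, 0.3, 0.7)
        assert apply_lf(lf, [0.1, 0.5, 0.9]).tolist() == [1, 0, -1]

    def test_boundary_belongs_to_decided_region(self):
        lf = LabelingFunction("f", LOWER_IS_CORRECT, 0.3, 0.7)
        assert apply_lf(lf, [0.3]).tolist() == [1]
        assert apply_lf(lf, [0.7]).tolist() == [-1]

    def test_votes_partition_counts(self, rng):
        lf = LabelingFunction("f", HIGHER_IS_CORRECT, 0.6, 0.2)
        votes = apply_lf(lf, rng.random(500))
        counts = {v: int((votes == v).sum()) for v in (-1, 0, 1)}
        assert set(np.unique(votes)) <= {-1, 0, 1}
        assert sum(counts.values()) == 500

    def test_orientation_symmetry(self, rng):
        values = rng.standard_normal(200)
        low = LabelingFunction("f", LOWER_IS_CORRECT, -0.4, 0.9)
        high = LabelingFunction("f", HIGHER_IS_CORRECT, 0.4, -0.9)
        np.testing.assert_array_equal(apply_lf(low, values), apply_lf(high, -values))

    @settings(max_examples=100, derandomize=True)
    @given(
        t_c=st.floats(-5, 5, allow_nan=False),
        gap=st.floats(1e-6, 5, allow_nan=False),
        v=st.floats(-10, 10, allow_nan=False),
    )
    def test_every_value_gets_exactly_one_vote(self, t_c, gap, v):
        lf = LabelingFunction("f", LOWER_IS_CORRECT, t_c, t_c + gap)
        vote = apply_lf(lf, [v])[0]
        assert vote in (-1, 0, 1)
        if v <= t_c:
            assert vote == 1
        elif v >= t_c + gap:
            assert vote == -1
        else:
            assert vote == 0

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            LabelingFunction("f", LOWER_IS_CORRECT, 0.7, 0.3)

    def test_text_roundtrip(self):
        lfs = [
            LabelingFunction("a", LOWER_IS_CORRECT, 0.1, 0.9),
            LabelingFunction("b", HIGHER_IS_CORRECT, 2.5, -1.0),
        ]
        back = lfs_from_text(lfs_to_text(lfs))
        assert back == lfs


class TestDiagnostics:
    def test_single_full_coverage_lf(self):
        m = np.array([[1], [1], [-1], [1]])
        d = lf_diagnostics(m)
        assert d.per_lf["coverage"].iloc[0] == 1.0
        assert d.overlap.shape == (1, 1) and d.overlap[0, 0] == 0.0

    def test_duplicated_lf_overlap_equals_coverage(self):
        col = np.array([1, 0, -1, 1, 0])
        m = np.column_stack([col, col])
        d = lf_diagnostics(m)
        assert d.overlap[0, 1] == pytest.approx((col != 0).mean())
        assert d.conflict[0, 1] == 0.0

    def test_conflict_matches_row_scan(self, rng):
        m = rng.integers(-1, 2, size=(200, 3))
        d = lf_diagnostics(m)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                both = (m[:, i] != 0) & (m[:, j] != 0)
                disagree = both & (m[:, i] != m[:, j])
                assert d.overlap[i, j] == pytest.approx(both.mean())
                assert d.conflict[i, j] == pytest.approx(disagree.mean())
        assert (d.conflict <= d.overlap + 1e-12).all()

    def test_accuracy_against_gold(self):
        m = np.array([[1], [-1], [1], [0]])
        y = np.array([True, True, False, False])
        d = lf_diagnostics(m, y)
        assert d.per_lf["accuracy"].iloc[0] == pytest.approx(1 / 3)


class TestSelection:
    def _candidates(self, table, labels):
        ranking = rank_features_by_auc(table, labels)
        lfs = []
        for name in ranking.table["feature"]:
            res = find_thresholds(
                table.df[name].to_numpy(float),
                np.asarray(labels, bool),
                ranking.orientation(name),
                feature_name=name,
            )
            if res.feasible:
                lfs.append(build_lf(res))
        return lfs

    @staticmethod
    def _objective(lfs, table, y, lam=0.1):
        from haikal.lf_engine import _majority_accuracy

        m = build_lf_matrix(lfs, table)
        acc = _majority_accuracy(m, y)
        kk = m.shape[1]
        if kk < 2:
            return acc
        voted = m != 0
        pairs = [
            (voted[:, i] & voted[:, j]).mean()
            for i in range(kk)
            for j in range(i + 1, kk)
        ]
        return acc - lam * float(np.mean(pairs))

    def test_k1_returns_best_standalone(self, labeled_table):
        y = np.asarray(labeled_table.labels, bool)
        cands = self._candidates(labeled_table, y)
        chosen = select_lfs(
            cands, labeled_table, y, k=1, min_class_cov=0, min_total_cov=0
        )
        assert len(chosen) == 1
        best = max(self._objective([c], labeled_table, y) for c in cands)
        assert self._objective(chosen, labeled_table, y) == pytest.approx(best)

    def test_duplicate_candidate_not_selected_twice(self, labeled_table):
        y = np.asarray(labeled_table.labels, bool)
        cands = self._candidates(labeled_table, y)
        doubled = cands + [cands[0]]
        chosen = select_lfs(
            doubled,
            labeled_table,
            y,
            k=min(3, len(cands)),
            min_class_cov=0,
            min_total_cov=0,
        )
        names = [c.feature_name for c in chosen]
        assert len(names) == len(set(names))

    def test_greedy_at_least_best_single_and_near_exhaustive(self, labeled_table):
        import itertools

        y = np.asarray(labeled_table.labels, bool)
        cands = self._candidates(labeled_table, y)[:6]
        chosen = select_lfs(
            cands,
            labeled_table,
            y,
            k=3,
            lam=0.1,
            min_class_cov=0,
            min_total_cov=0,
            stop_on_no_gain=True,
        )
        assert 1 <= len(chosen) <= 3
        obj_chosen = self._objective(chosen, labeled_table, y)
        best_single = max(self._objective([c], labeled_table, y) for c in cands)
        assert obj_chosen >= best_single - 1e-12
        # exhaustive search over all subsets of size <= 3 as the upper bound
        best_exhaustive = max(
            self._objective(list(sub), labeled_table, y)
            for r in (1, 2, 3)
            for sub in itertools.combinations(cands, r)
        )
        assert obj_chosen <= best_exhaustive + 1e-12
        # greedy is allowed to be suboptimal, but not by much on this panel
        assert obj_chosen >= best_exhaustive - 0.05

    def test_insufficient_candidates_warn(self, labeled_table):
        y = np.asarray(labeled_table.labels, bool)
        cands = self._candidates(labeled_table, y)[:2]
        with pytest.warns(UserWarning, match="feasible"):
            chosen = select_lfs(
                cands, labeled_table, y, k=10, min_class_cov=0, min_total_cov=0
            )
        assert len(chosen) <= 2
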