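"""nanoRF scoring, metrics and threshold selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanorf import (
    NanoRF,
    RFConfig,
    TrainingError,
    TrainingSet,
    ValidationError,
    auc,
    best_threshold,
    fractionate,
    mcc_at_threshold,
    scatter_pairs,
)
from oracles import (
    auc_pairwise,
    best_threshold_exhaustive,
    mcc_by_enumeration,
    profile_from_values,
)


def planted_profile(n_members=6, n_background=60, depth=-3.0, sigma=0.1,
                    n_conditions=3, seed=0):
    """Members at `depth` in every condition, background at 0, Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = n_members + n_background
    vals = rng.normal(0.0, sigma, (n, n_conditions))
    vals[:n_members] += depth
    ids = [f"M{i:02d}" for i in range(n_members)] + [
        f"B{i:03d}" for i in range(n_background)
    ]
    frame = pd.DataFrame(vals, index=ids,
                         columns=[f"C{j}" for j in range(n_conditions)])
    return profile_from_values(frame)


def training_set_for(profile, n_pos, n_neg, name="cx"):
    ids = list(profile.values.index)
    members = [i for i in ids if i.startswith("M")][:n_pos]
    background = [i for i in ids if i.startswith("B")][:n_neg]
    return TrainingSet(name, frozenset(members), frozenset(background))


class TestAUC:
    def test_worked_example(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_one_class_empty_errors(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            y = np.zeros(n, int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # rounding forces occasional ties
            assert auc(s, y) == pytest.approx(auc_pairwise(s, y), abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        y = (rng.random(n) < 0.4).astype(int)
        if y.sum() in (0, n):
            y[0], y[-1] = 1, 0
        s = rng.random(n)
        base = auc(s, y)
        for f in (lambda x: 3 * x + 1, np.exp, lambda x: x ** 3):
            assert auc(f(s), y) == pytest.approx(base, abs=1e-12)


class TestMCC:
    def test_confusion_3_1_5_1(self):
        # positives: 3 above t, 1 below; negatives: 1 above, 5 below
        scores = [0.9, 0.8, 0.7, 0.3, 0.6, 0.2, 0.1, 0.15, 0.05, 0.25]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        assert mcc_at_threshold(scores, labels, 0.5) == pytest.approx(14 / 24)

    def test_perfect_split(self):
        assert mcc_at_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5) == 1.0

    def test_all_predicted_positive_degenerates_to_zero(self):
        assert mcc_at_threshold([0.9, 0.8, 0.7], [1, 0, 1], 0.0) == 0.0

    def test_label_swap_negates(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            s = rng.random(n)
            t = float(rng.random())
            assert mcc_at_threshold(s, 1 - y, t) == pytest.approx(
                -mcc_at_threshold(s, y, t), abs=1e-12
            )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)
            t = float(rng.random())
            assert mcc_at_threshold(s, y, t) == pytest.approx(
                mcc_by_enumeration(s, y, t), abs=1e-12
            )


class TestBestThreshold:
    def test_midpoint_of_separated_groups(self):
        t, m = best_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert t == pytest.approx(0.5)
        assert m == 1.0

    def test_all_equal_scores(self):
        t, m = best_threshold([0.4, 0.4, 0.4], [1, 0, 1])
        assert (t, m) == (0.0, 0.0)

    def test_single_top_ranked_positive(self):
        scores = [0.95] + [0.1 * k for k in range(1, 10)]
        labels = [1] + [0] * 9
        t, m = best_threshold(scores, labels)
        assert m == 1.0
        assert 0.9 < t < 0.95

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)
            got_t, got_m = best_threshold(s, y)
            want_t, want_m = best_threshold_exhaustive(s, y)
            assert got_m == pytest.approx(want_m, abs=1e-12)
            assert got_t == pytest.approx(want_t, abs=1e-12)


class TestFractionate:
    def test_separable_planted_data(self):
        prof = planted_profile(sigma=0.1, seed=4)
        ts = training_set_for(prof, n_pos=4, n_neg=20)
        res = fractionate(prof, ts, RFConfig(n_trees=300, seed=1))
        assert res.auc == 1.0
        assert res.best_mcc == 1.0
        # withheld members score above all background proteins
        withheld = [f"M{i:02d}" for i in range(4, 6)]
        background = [i for i in res.scores.index if i.startswith("B")][20:]
        assert res.scores[withheld].min() > res.scores[background].max()

    def test_random_labels_give_chance_auc(self):
        prof = planted_profile(n_members=0, n_background=80, sigma=0.5)
        rng = np.random.default_rng(21)
        ids = np.array(prof.values.index)
        aucs = []
        for k in range(30):
            chosen = rng.choice(ids, size=16, replace=False)
            ts = TrainingSet("rand", frozenset(chosen[:6]), frozenset(chosen[6:]))
            res = fractionate(prof, ts, RFConfig(n_trees=150, seed=int(k)))
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_single_positive_errors(self):
        prof = planted_profile()
        ts = TrainingSet("cx", frozenset({"M00"}),
                         frozenset({"B000", "B001", "B002"}))
        with pytest.raises(TrainingError):
            NanoRF(prof, ts)

    def test_incomplete_profile_rejected(self):
        vals = pd.DataFrame({"A": [0.0, np.nan, 1.0, 2.0]},
                            index=["P0", "P1", "P2", "P3"])
        prof = profile_from_values(vals)
        ts = TrainingSet("cx", frozenset({"P0", "P1"}), frozenset({"P2", "P3"}))
        with pytest.raises(ValidationError, match="missing"):
            NanoRF(prof, ts)

    def test_seed_reproducible(self):
        prof = planted_profile(sigma=0.3, seed=8)
        ts = training_set_for(prof, n_pos=4, n_neg=15)
        r1 = fractionate(prof, ts, RFConfig(n_trees=200, seed=42))
        r2 = fractionate(prof, ts, RFConfig(n_trees=200, seed=42))
        pd.testing.assert_series_equal(r1.scores, r2.scores)
        assert r1.threshold == r2.threshold

    def test_row_permutation_invariant(self):
        prof = planted_profile(sigma=0.3, seed=8)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(prof.values))
        shuffled = profile_from_values(prof.values.iloc[perm])
        ts = training_set_for(prof, n_pos=4, n_neg=15)
        r1 = fractionate(prof, ts, RFConfig(n_trees=200, seed=42))
        r2 = fractionate(shuffled, ts, RFConfig(n_trees=200, seed=42))
        pd.testing.assert_series_equal(r1.scores, r2.scores)

    def test_training_scores_are_out_of_bag(self):
        """With one uninformative feature copy of the labels absent, a
        self-fit forest would score every training row near its label; the
        OOB adjustment keeps training scores honest on pure-noise data."""
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(0, 1, (40, 3)),
                            index=[f"P{i:02d}" for i in range(40)],
                            columns=["A", "B", "C"])
        prof = profile_from_values(vals)
        ts = TrainingSet("noise", frozenset(f"P{i:02d}" for i in range(8)),
                         frozenset(f"P{i:02d}" for i in range(8, 28)))
        res = fractionate(prof, ts, RFConfig(n_trees=400, seed=3))
        pos_scores = res.scores[[f"P{i:02d}" for i in range(8)]]
        # self-fit votes would push these toward 1; OOB keeps them mid-range
        assert pos_scores.mean() < 0.85
        assert res.auc < 0.95

    def test_positives_outscore_hitchhikers_across_seeds(self):
        hits = 0
        for seed in range(10):
            prof = planted_profile(sigma=0.5, seed=seed)
            ts = training_set_for(prof, n_pos=4, n_neg=20)
            res = fractionate(prof, ts, RFConfig(n_trees=150, seed=seed))
            members = [i for i in res.scores.index if i.startswith("M")]
            hitch = [i for i in res.scores.index if i.startswith("B")]
            if res.scores[members].mean() > res.scores[hitch].mean():
                hits += 1
        assert hits == 10

    def test_roc_points_monotone_from_origin_to_corner(self):
        prof = planted_profile(sigma=0.4, seed=12)
        ts = training_set_for(prof, n_pos=5, n_neg=25)
        res = fractionate(prof, ts, RFConfig(n_trees=200, seed=7))
        pts = res.roc_points
        assert (pts[0] == [0.0, 0.0]).all()
        assert (pts[-1] == [1.0, 1.0]).all()
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()
        assert (res.scores >= 0).all() and (res.scores <= 1).all()


class TestScatterPairs:
    def test_identical_results_lie_on_diagonal(self, small_profile, small_truth):
        ts, _ = small_truth.training_set("cx1", fraction=0.6, seed=1)
        res = fractionate(small_profile, ts, RFConfig(n_trees=150, seed=2))
        pairs = scatter_pairs(res, res)
        np.testing.assert_array_equal(pairs["score_a"], pairs["score_b"])

    def test_disjoint_complexes_in_opposite_corners(self, small_profile,
                                                    small_truth):
        ts1, _ = small_truth.training_set("cx1", fraction=1.0, seed=1)
        ts2, _ = small_truth.training_set("cx2", fraction=1.0, seed=2)
        r1 = fractionate(small_profile, ts1, RFConfig(n_trees=200, seed=3))
        r2 = fractionate(small_profile, ts2, RFConfig(n_trees=200, seed=4))
        pairs = scatter_pairs(r1, r2)
        m1 = small_truth.members("cx1")
        m2 = small_truth.members("cx2")
        assert pairs.loc[m1, "score_a"].mean() > 0.7
        assert pairs.loc[m1, "score_b"].mean() < 0.3
        assert pairs.loc[m2, "score_b"].mean() > 0.7
        assert pairs.loc[m2, "score_a"].mean() < 0.3

    def test_threshold_rectangle_selection(self):
        ids = ["P1", "P2", "P3", "P4"]
        a = _results_with(ids, [0.30, 0.29, 0.27, 0.90], threshold=0.28)
        b = _results_with(ids, [0.40, 0.25, 0.35, 0.31], threshold=0.30)
        pairs = scatter_pairs(a, b)
        assert set(pairs.index[pairs["above_both"]]) == {"P1", "P4"}


def _results_with(ids, scores, threshold):
    from nanorf.rf import FractionationResults

    return FractionationResults(
        complex_name="toy",
        scores=pd.Series(scores, index=ids),
        in_training=pd.Series("unlabeled", index=ids),
        threshold=threshold,
        auc=1.0,
        best_mcc=1.0,
        roc_points=np.array([[0.0, 0.0], [1.0, 1.0]]),
        config=RFConfig(n_trees=100, seed=0),
    )


def test_sample_background_is_seeded_and_excludes(small_profile, small_truth):
    from nanorf import sample_background

    members = set(small_truth.members("cx1"))
    s1 = sample_background(small_profile, members, n=25, seed=4)
    s2 = sample_background(small_profile, members, n=25, seed=4)
    assert s1 == s2
    assert len(s1) == 25
    assert not (s1 & members)
    assert s1 != sample_background(small_profile, members, n=25, seed=5)
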