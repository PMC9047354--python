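import numpy as np
import pandas as pd
import pytest

from methfert import classify as cl
from methfert._seeds import child_seed

from .conftest import make_matrix


def labelled(index, n_fertile):
    return pd.Series(["fertile"] * n_fertile
                     + ["subfertile"] * (len(index) - n_fertile), index=index)


def gaussian_cohort(n_per_class=30, n_features=40, shift=5.0, seed=0):
    """Two Gaussian clusters separated by `shift` SDs on every feature."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b = rng.normal(shift, 1.0, size=(n_per_class, n_features))
    X = pd.DataFrame(np.vstack([a, b]),
                     index=[f"s{i}" for i in range(2 * n_per_class)])
    X.columns = [f"f{j}" for j in range(n_features)]
    y = labelled(X.index, n_per_class)
    return X, y


class TestPrepareFeatures:
    def make(self):
        # 10 samples x 3 DMC sites; site 2 has 20% missing, site 3 has 10%
        total = np.full((3, 10), 20)
        total[1, :2] = 0          # 20% missing
        total[2, 0] = 0           # 10% missing
        meth = (total * 0.5).astype(int)
        m = make_matrix(meth, total)
        dmcs = m.sites.copy()
        return m, dmcs

    def test_complete_only_drops_any_missing(self):
        m, dmcs = self.make()
        feats = cl.prepare_features(m, dmcs, policy="complete_only")
        assert feats.shape == (10, 1)

    def test_impute_policy_requires_under_10pct(self):
        m, dmcs = self.make()
        feats = cl.prepare_features(m, dmcs, policy="impute_lt_10pct")
        # 20%-missing and 10%-missing features both dropped (<10% is strict)
        assert feats.shape == (10, 1)
        assert not feats.isna().any().any()

    def test_no_missing_unchanged_by_both_policies(self):
        total = np.full((2, 6), 20)
        meth = np.arange(12).reshape(2, 6)
        m = make_matrix(meth, total)
        a = cl.prepare_features(m, m.sites, policy="complete_only")
        b = cl.prepare_features(m, m.sites, policy="impute_lt_10pct")
        pd.testing.assert_frame_equal(a, b)

    def test_zero_surviving_features_rejected(self):
        total = np.array([[20, 0, 20, 20]])
        m = make_matrix([[10, 0, 10, 10]], total)
        with pytest.raises(ValueError, match="no DMC features"):
            cl.prepare_features(m, m.sites, policy="complete_only")


class TestLowrankImpute:
    def test_rank1_completion_oracle(self):
        rng = np.random.default_rng(2)
        u = rng.random(12)
        v = rng.random(8)
        X = np.outer(u, v)
        X_missing = X.copy()
        X_missing[3, 4] = np.nan
        done = cl.lowrank_impute(X_missing, rank=1)
        assert done[3, 4] == pytest.approx(X[3, 4], abs=1e-6)

    def test_internal_cv_handles_noisy_lowrank(self):
        rng = np.random.default_rng(3)
        X = np.outer(rng.random(30), rng.random(15)) * 50 \
            + rng.normal(0, 0.1, size=(30, 15))
        mask = rng.random(X.shape) < 0.05
        Xm = X.copy()
        Xm[mask] = np.nan
        done = cl.lowrank_impute(Xm, seed=1)
        assert np.abs(done[mask] - X[mask]).mean() < 2.0


class TestStratifiedSplit:
    def test_cohort_sizes_57_43(self):
        y = labelled([f"s{i}" for i in range(100)], 57)
        train, test = cl.stratified_split(y, train_frac=2 / 3, seed=1)
        assert len(train) == 67 and len(test) == 33
        assert (y[train] == "fertile").sum() == 38
        assert (y[test] == "fertile").sum() == 19

    def test_half_split_4_16(self):
        y = labelled([f"s{i}" for i in range(20)], 4)
        train, _ = cl.stratified_split(y, train_frac=0.5, seed=2)
        assert (y[train] == "fertile").sum() == 2
        assert (y[train] == "subfertile").sum() == 8

    def test_seed_contract(self):
        y = labelled([f"s{i}" for i in range(30)], 18)
        a = cl.stratified_split(y, seed=5)
        b = cl.stratified_split(y, seed=5)
        c = cl.stratified_split(y, seed=6)
        assert a == b
        assert a != c
        assert len(c[0]) == len(a[0])  # sizes seed-independent

    def test_empty_side_rejected(self):
        y = labelled(list("abc"), 1)
        with pytest.raises(ValueError, match="empty train or test"):
            cl.stratified_split(y, train_frac=0.9, seed=0)


class TestTrainAndEvaluate:
    def test_separable_training_accuracy(self):
        X, y = gaussian_cohort(30, 20, shift=5.0, seed=4)
        clf = cl.train_model(X, y, n_trees=100, seed=1)
        report = cl.evaluate(clf, X, y)
        assert report.accuracy == 1.0

    def test_single_class_labels_rejected(self):
        X, _ = gaussian_cohort(10, 5)
        with pytest.raises(ValueError, match="single class"):
            cl.train_model(X, pd.Series("fertile", index=X.index))

    def test_metric_arithmetic(self):
        # 10 fertile (8 correct) + 8 subfertile (5 correct)
        class Stub:
            classes_ = np.array(["fertile", "subfertile"])

            def predict_proba(self, X):
                p = np.concatenate([np.full(8, .9), np.full(2, .1),
                                    np.full(5, .1), np.full(3, .9)])
                return np.column_stack([p, 1 - p])

        X = pd.DataFrame(np.zeros((18, 2)), index=[f"s{i}" for i in range(18)])
        y = labelled(X.index, 10)
        r = cl.evaluate(Stub(), X, y)
        assert r.sensitivity == pytest.approx(0.8)
        assert r.specificity == pytest.approx(0.625)
        assert r.accuracy == pytest.approx(13 / 18)

    def test_auc_extremes(self):
        class Perfect:
            classes_ = np.array(["fertile", "subfertile"])

            def predict_proba(self, X):
                p = np.r_[np.linspace(.6, .9, 5), np.linspace(.1, .4, 5)]
                return np.column_stack([p, 1 - p])

        class Constant:
            classes_ = np.array(["fertile", "subfertile"])

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        X = pd.DataFrame(np.zeros((10, 1)), index=[f"s{i}" for i in range(10)])
        y = labelled(X.index, 5)
        assert cl.evaluate(Perfect(), X, y).auc == pytest.approx(1.0)
        assert cl.evaluate(Constant(), X, y).auc == pytest.approx(0.5)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(20)

        def stub(s):
            class S:
                classes_ = np.array(["fertile", "subfertile"])

                def predict_proba(self, X, _s=s):
                    return np.column_stack([_s, 1 - _s])
            return S()

        X = pd.DataFrame(np.zeros((20, 1)), index=[f"s{i}" for i in range(20)])
        y = labelled(X.index, 9)
        a1 = cl.evaluate(stub(scores), X, y).auc
        a2 = cl.evaluate(stub(scores ** 3), X, y).auc  # strictly monotone
        assert a1 == pytest.approx(a2)

    def test_accuracy_between_weighted_sens_spec(self):
        X, y = gaussian_cohort(15, 10, shift=1.0, seed=9)
        clf = cl.train_model(X, y, n_trees=50, seed=1)
        r = cl.evaluate(clf, X, y)
        n_pos = (y == "fertile").sum()
        n_neg = len(y) - n_pos
        expected = (r.sensitivity * n_pos + r.specificity * n_neg) / len(y)
        assert r.accuracy == pytest.approx(expected)


class TestCrossvalidate:
    def test_single_iteration_composition_identity(self):
        X, y = gaussian_cohort(12, 8, shift=2.0, seed=5)
        summary = cl.crossvalidate_resampled(X, y, iterations=1, seed=7,
                                             n_trees=50)
        it_seed = child_seed(7, "cv_iter_0")
        train, test = cl.stratified_split(y, 2 / 3, seed=it_seed)
        clf = cl.train_model(X.loc[train], y.loc[train], n_trees=50,
                             seed=it_seed)
        single = cl.evaluate(clf, X.loc[test], y.loc[test])
        assert summary["mean_accuracy"] == pytest.approx(single.accuracy)
        assert summary["mean_auc"] == pytest.approx(single.auc)

    def test_separable_cohort_high_auc(self):
        X, y = gaussian_cohort(20, 15, shift=4.0, seed=6)
        summary = cl.crossvalidate_resampled(X, y, iterations=5, n_trees=100,
                                             seed=2)
        assert summary["mean_auc"] >= 0.95


class TestGroupAndIndependent:
    def test_group_split_directions(self):
        X, y = gaussian_cohort(20, 10, shift=3.0, seed=8)
        groups = pd.Series((["c1", "c2"] * 20), index=X.index)
        out = cl.evaluate_group_split(X, y, groups, n_trees=50, seed=1)
        assert set(out) == {"c1->c2", "c2->c1"}
        assert len(out["c1->c2"].predictions) == 20

    def test_identical_groups_symmetric(self):
        X, y = gaussian_cohort(8, 6, shift=3.0, seed=9)
        dup_index = pd.Index([f"t{i}" for i in range(len(X))])
        groups = pd.Series(["g1"] * len(X) + ["g2"] * len(X),
                           index=list(X.index) + list(dup_index))
        X2 = pd.concat([X, X.set_axis(dup_index)])
        y2 = pd.concat([y, y.set_axis(dup_index)])
        out = cl.evaluate_group_split(X2, y2, groups, n_trees=50, seed=1)
        a, b = out["g1->g2"], out["g2->g1"]
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.auc == pytest.approx(b.auc)

    def test_independent_label_flip_complements_accuracy(self):
        X, y = gaussian_cohort(15, 10, shift=4.0, seed=10)
        Xi, yi = gaussian_cohort(8, 10, shift=4.0, seed=11)
        Xi.index = [f"i{k}" for k in range(len(Xi))]
        yi.index = Xi.index
        r = cl.evaluate_independent(X, y, Xi, yi, n_trees=50, seed=1)
        flipped = yi.map({"fertile": "subfertile", "subfertile": "fertile"})
        r2 = cl.evaluate_independent(X, y, Xi, flipped, n_trees=50, seed=1)
        assert r2.accuracy == pytest.approx(1.0 - r.accuracy)

    def test_missing_columns_rejected(self):
        X, y = gaussian_cohort(10, 6, seed=12)
        Xi = X.iloc[:, :-2].copy()
        with pytest.raises(ValueError, match="lacks DMC features"):
            cl.evaluate_independent(X, y, Xi, y)


class TestMisclassificationPCA:
    def test_all_correct_only_ff_ss(self):
        X, y = gaussian_cohort(10, 8, shift=5.0, seed=13)
        out = cl.misclassification_pca(X, y, y)
        assert set(out["quadrant"]) <= {"FF", "SS"}

    def test_swapped_samples_land_on_opposite_side(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 0.5, size=(10, 6))
        b = rng.normal(8, 0.5, size=(10, 6))
        # two samples with swapped profiles
        a[0], b[0] = b[0].copy(), a[0].copy()
        X = pd.DataFrame(np.vstack([a, b]),
                         index=[f"s{i}" for i in range(20)])
        y = labelled(X.index, 10)
        pred = y.copy()
        pred.iloc[0], pred.iloc[10] = "subfertile", "fertile"
        out = cl.misclassification_pca(X, y, pred)
        mid = out["PC1"].mean()
        fs = out.loc[out["quadrant"] == "FS", "PC1"].iloc[0]
        ss_side = np.sign(out.loc[out["quadrant"] == "SS", "PC1"].mean() - mid)
        assert np.sign(fs - mid) == ss_side

    def test_constant_features_rejected(self):
        X = pd.DataFrame(np.ones((6, 3)), index=[f"s{i}" for i in range(6)])
        y = labelled(X.index, 3)
        with pytest.raises(ValueError, match="constant"):
            cl.misclassification_pca(X, y, y)


class TestCompareGroups:
    def test_small_groups_use_rank_sum(self):
        vals = np.r_[np.random.default_rng(0).normal(0, 1, 5),
                     np.random.default_rng(1).normal(0, 1, 5)]
        name, _ = cl.compare_groups(vals, ["a"] * 5 + ["b"] * 5)
        assert name == "rank-sum"

    def test_large_normal_equal_variance_uses_t(self):
        rng = np.random.default_rng(2)
        vals = np.r_[rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)]
        name, _ = cl.compare_groups(vals, ["a"] * 30 + ["b"] * 30)
        assert name == "t-test"

    def test_identical_samples_p_one(self):
        vals = np.r_[np.arange(5.0), np.arange(5.0)]
        name, p = cl.compare_groups(vals, ["a"] * 5 + ["b"] * 5)
        assert name == "rank-sum"
        assert p == pytest.approx(1.0)


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(3)
        base = rng.random(20)
        X = pd.DataFrame([base, base, rng.random(20)],
                         index=["a", "b", "c"])
        Z = cl.hierarchical_cluster(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_correlated_pair_merges_first(self):
        x = np.arange(10.0)
        X = pd.DataFrame([x, 2 * x + 1, x[::-1]], index=["a", "b", "c"])
        Z = cl.hierarchical_cluster(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_matches_lance_williams_ward_oracle(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((10, 50)))
        X.index = [f"s{i}" for i in range(10)]
        Z = cl.hierarchical_cluster(X)
        oracle = ward_bruteforce(1.0 - np.corrcoef(X.to_numpy()))
        # compare merge heights (tree shape may permute at exact ties)
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(oracle), rtol=1e-8)

    def test_constant_profile_rejected_by_name(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0], [0.2, 0.5, 0.9]],
                         index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            cl.hierarchical_cluster(X)


def ward_bruteforce(dist):
    """Lance-Williams Ward update on a dense distance matrix; returns merge
    heights (scipy convention: distances, squared internally)."""
    n = dist.shape[0]
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    d2 = {(i, j): dist[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    heights = []
    nxt = n
    while len(active) > 1:
        (i, j), _ = min(d2.items(), key=lambda kv: kv[1])
        heights.append(np.sqrt(d2[(i, j)]))
        si, sj = sizes[i], sizes[j]
        merged = nxt
        nxt += 1
        for k in sorted(active - {i, j}):
            sk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            dij = d2[(i, j)]
            new = ((si + sk) * dik + (sj + sk) * djk - sk * dij) / (si + sj + sk)
            d2[tuple(sorted((merged, k)))] = new
        active -= {i, j}
        for key in [key for key in d2 if i in key or j in key]:
            del d2[key]
        active.add(merged)
        sizes[merged] = si + sj
    return heights


class TestCorrectBatch:
    def test_two_batch_means_removed(self):
        vals = [1, 2, 3, 11, 12, 13]
        res = cl.correct_batch(vals, ["A"] * 3 + ["B"] * 3)
        np.testing.assert_allclose(res, [-1, 0, 1, -1, 0, 1])

    def test_single_batch_centers(self):
        res = cl.correct_batch([1.0, 2.0, 3.0], ["A"] * 3)
        np.testing.assert_allclose(res, [-1, 0, 1])

    def test_residuals_orthogonal_to_batch_indicators(self):
        rng = np.random.default_rng(5)
        vals = rng.random(40)
        batches = rng.choice(list("abcd"), size=40)
        res = cl.correct_batch(vals, batches)
        for b in "abcd":
            assert abs(res[batches == b].sum()) < 1e-8

    def test_singleton_batch_zero_residual(self):
        res = cl.correct_batch([5.0, 1.0, 3.0], ["solo", "B", "B"])
        assert res[0] == 0.0
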