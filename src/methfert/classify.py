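"""Random-Forest fertility prediction and cohort-level statistics.

The feature matrix is samples x DMC methylation percentages. The positive
class is *fertile* (sensitivity = true-positive rate on fertile bulls;
specificity = true-negative rate on subfertile bulls) — note this inverts
the usual disease convention. Three evaluation strategies are provided:
stratified 2/3-1/3 resampling averaged over iterations, a two-direction
group (collection-center) split, and a train-on-everything / test-on-
independent-cohort run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from ._seeds import child_seed

logger = logging.getLogger(__name__)

__all__ = [
    "ModelReport", "prepare_features", "lowrank_impute", "stratified_split",
    "train_model", "evaluate", "crossvalidate_resampled",
    "evaluate_group_split", "evaluate_independent", "misclassification_pca",
    "compare_groups", "hierarchical_cluster", "correct_batch",
]

POSITIVE_CLASS = "fertile"
NEGATIVE_CLASS = "subfertile"


# ---------------------------------------------------------------------------
# feature preparation
# ---------------------------------------------------------------------------

def lowrank_impute(X: np.ndarray, rank: int | None = None, seed: int = 0,
                   max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Iterative low-rank SVD completion of a matrix with NaN cells.

    Missing cells are initialized at column means, then alternately replaced
    by the rank-``rank`` SVD reconstruction until the imputed values
    stabilize. When ``rank`` is None it is chosen by internal cross-
    validation: a random 10% of the observed cells are held out and the rank
    (among 1..min(8, dims-1)) with the lowest held-out squared error wins.
    """
    X = np.asarray(X, dtype=float)
    missing = np.isnan(X)
    if not missing.any():
        return X.copy()
    if missing.all(axis=0).any() or missing.all(axis=1).any():
        raise ValueError("a fully-missing row or column cannot be imputed")

    def _complete(mat, miss, r):
        filled = mat.copy()
        col_means = np.nanmean(mat, axis=0)
        filled[miss] = np.take(col_means, np.where(miss)[1])
        prev = filled[miss]
        for _ in range(max_iter):
            u, s, vt = np.linalg.svd(filled, full_matrices=False)
            recon = (u[:, :r] * s[:r]) @ vt[:r]
            filled[miss] = recon[miss]
            if np.max(np.abs(filled[miss] - prev)) < tol:
                break
            prev = filled[miss].copy()
        return filled

    max_rank = min(8, min(X.shape) - 1)
    if rank is None:
        rng = np.random.default_rng(child_seed(seed, "impute_cv"))
        obs = np.argwhere(~missing)
        n_hold = max(1, int(0.1 * len(obs)))
        hold = obs[rng.choice(len(obs), size=n_hold, replace=False)]
        holdout = np.zeros_like(missing)
        holdout[hold[:, 0], hold[:, 1]] = True
        trial_miss = missing | holdout
        if trial_miss.all(axis=0).any() or trial_miss.all(axis=1).any():
            rank = 1  # too sparse to cross-validate; smallest structure wins
        else:
            masked = X.copy()
            masked[holdout] = np.nan
            errs = []
            for r in range(1, max_rank + 1):
                rec = _complete(masked, trial_miss, r)
                errs.append(np.mean((rec[holdout] - X[holdout]) ** 2))
            rank = int(np.argmin(errs)) + 1
    rank = min(rank, min(X.shape))
    return _complete(X, missing, rank)


def prepare_features(matrix, dmcs: pd.DataFrame, policy: str = "complete_only",
                     min_reads: int = 10, seed: int = 0,
                     rank: int | None = None) -> pd.DataFrame:
    """Build the samples x DMC feature matrix of methylation percentages.

    A cell is missing when the sample lacks CpG10 coverage at the DMC.
    ``complete_only`` keeps features with zero missing cells;
    ``impute_lt_10pct`` keeps features with a missing fraction strictly below
    0.10 and fills them by iterative low-rank SVD reconstruction (fixed
    seed). Raises if no feature survives.
    """
    if policy not in ("complete_only", "impute_lt_10pct"):
        raise ValueError(f"unknown policy {policy!r}")
    lookup = matrix.site_lookup()
    rows = [lookup[(c, int(p))] for c, p in zip(dmcs["chrom"], dmcs["pos"])]
    pct = matrix.percentages()[rows]
    ok = matrix.total[rows] >= min_reads
    pct = np.where(ok, pct, np.nan)
    names = [f"{c}:{p}" for c, p in zip(dmcs["chrom"], dmcs["pos"])]
    feats = pd.DataFrame(pct.T, index=matrix.samples, columns=names)

    miss_frac = feats.isna().mean(axis=0)
    if policy == "complete_only":
        feats = feats.loc[:, miss_frac == 0]
    else:
        feats = feats.loc[:, miss_frac < 0.10]
        if feats.isna().any().any():
            feats = pd.DataFrame(
                lowrank_impute(feats.to_numpy(), rank=rank, seed=seed),
                index=feats.index, columns=feats.columns,
            )
    if feats.shape[1] == 0:
        raise ValueError("no DMC features survive the missing-value policy")
    assert not feats.isna().any().any()
    return feats


# ---------------------------------------------------------------------------
# splitting, training, evaluation
# ---------------------------------------------------------------------------

def stratified_split(labels: pd.Series, train_frac: float = 2 / 3,
                     seed: int = 0):
    """Random class-stratified train/test partition.

    Per class, the training side receives round-half-up(train_frac * class
    size) samples; the remainder tests. Sizes are seed-independent, contents
    seed-dependent. Returns (train_ids, test_ids) in label order.
    """
    rng = np.random.default_rng(child_seed(seed, "split"))
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError("expected exactly two classes")
    train_ids, test_ids = [], []
    for cls in classes:
        members = np.asarray(labels.index[labels == cls])
        n_train = int(np.floor(train_frac * len(members) + 0.5))
        if n_train == 0 or n_train == len(members):
            raise ValueError(
                f"class {cls!r} would get an empty train or test side "
                f"({n_train}/{len(members)})"
            )
        perm = rng.permutation(len(members))
        train_ids.extend(members[perm[:n_train]])
        test_ids.extend(members[perm[n_train:]])
    order = {s: i for i, s in enumerate(labels.index)}
    train_ids.sort(key=order.get)
    test_ids.sort(key=order.get)
    return train_ids, test_ids


def train_model(features: pd.DataFrame, labels: pd.Series, n_trees: int = 500,
                mtry: str | int = "sqrt", seed: int = 0) -> RandomForestClassifier:
    """Fit the Random-Forest fertility classifier.

    Per-split candidate features default to floor(sqrt(p)); 500 trees. The
    classifier exposes class-probability scores and is reproducible given
    the seed.
    """
    y = labels.reindex(features.index)
    if y.nunique() < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry,
        random_state=child_seed(seed, "rf"),
    )
    clf.fit(features.to_numpy(), y.to_numpy())
    return clf


@dataclass
class ModelReport:
    """Confusion-derived metrics and ROC for one evaluation."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    roc: pd.DataFrame = field(repr=False)
    predictions: pd.DataFrame = field(repr=False)
    strategy: str = ""
    iterations: int = 1

    def to_dict(self) -> dict:
        return {"strategy": self.strategy, "iterations": self.iterations,
                "accuracy": self.accuracy, "auc": self.auc,
                "sensitivity": self.sensitivity, "specificity": self.specificity}


def _roc_points(y_true: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """ROC from fertile-class probabilities (fertile positive)."""
    order = np.argsort(-scores, kind="mergesort")
    y = (y_true[order] == POSITIVE_CLASS).astype(int)
    s = scores[order]
    P = y.sum()
    N = len(y) - P
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # one point per distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / max(P, 1)]
    fpr = np.r_[0.0, fps[distinct] / max(N, 1)]
    thr = np.r_[np.inf, s[distinct]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate(classifier, features: pd.DataFrame, labels: pd.Series,
             strategy: str = "") -> ModelReport:
    """Confusion-based metrics with fertile as the positive class.

    Predicted class is fertile when its probability >= 0.5; AUC is the
    trapezoidal integral of the probability-ranked ROC (NaN if the test set
    has a single class).
    """
    y = labels.reindex(features.index).to_numpy()
    if len(y) == 0:
        raise ValueError("empty test set")
    pos_col = list(classifier.classes_).index(POSITIVE_CLASS)
    prob = classifier.predict_proba(features.to_numpy())[:, pos_col]
    pred = np.where(prob >= 0.5, POSITIVE_CLASS, NEGATIVE_CLASS)

    tp = int(((y == POSITIVE_CLASS) & (pred == POSITIVE_CLASS)).sum())
    fn = int(((y == POSITIVE_CLASS) & (pred == NEGATIVE_CLASS)).sum())
    tn = int(((y == NEGATIVE_CLASS) & (pred == NEGATIVE_CLASS)).sum())
    fp = int(((y == NEGATIVE_CLASS) & (pred == POSITIVE_CLASS)).sum())
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    if len(np.unique(y)) == 2:
        roc = _roc_points(y, prob)
        auc = float(np.trapezoid(roc["tpr"], roc["fpr"]))
    else:
        roc = pd.DataFrame(columns=["fpr", "tpr", "threshold"])
        auc = np.nan
    quad = np.array([
        ("F" if a == POSITIVE_CLASS else "S") + ("F" if p == POSITIVE_CLASS else "S")
        for a, p in zip(y, pred)
    ])
    preds = pd.DataFrame({"sample_id": features.index, "actual": y,
                          "predicted": pred, "prob_fertile": prob,
                          "quadrant": quad})
    return ModelReport(accuracy=accuracy, auc=auc, sensitivity=sensitivity,
                       specificity=specificity, roc=roc, predictions=preds,
                       strategy=strategy)


def crossvalidate_resampled(features: pd.DataFrame, labels: pd.Series,
                            iterations: int = 50, train_frac: float = 2 / 3,
                            seed: int = 0, n_trees: int = 500) -> dict:
    """Stratified resampling: split, train, evaluate; average the metrics.

    Iteration ``i`` uses the child seed derived from (seed, ``cv_iter_i``)
    for both the split and the forest, so ``iterations=1`` reproduces a
    single split/train/evaluate run with that child seed. Returns a dict
    with mean and SD of the four indicators plus the per-iteration reports.
    """
    reports = []
    for i in range(iterations):
        it_seed = child_seed(seed, f"cv_iter_{i}")
        train_ids, test_ids = stratified_split(labels, train_frac, seed=it_seed)
        clf = train_model(features.loc[train_ids], labels.loc[train_ids],
                          n_trees=n_trees, seed=it_seed)
        reports.append(evaluate(clf, features.loc[test_ids],
                                labels.loc[test_ids], strategy="crossval"))
    metrics = ("accuracy", "auc", "sensitivity", "specificity")
    summary = {"strategy": "crossval", "iterations": iterations}
    for m in metrics:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            summary[f"mean_{m}"] = float(np.nanmean(vals))
            summary[f"sd_{m}"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
    summary["reports"] = reports
    return summary


def evaluate_group_split(features: pd.DataFrame, labels: pd.Series,
                         groups: pd.Series, n_trees: int = 500,
                         seed: int = 0) -> dict:
    """Train on one group, test on the other, both directions; no resampling."""
    groups = groups.reindex(features.index)
    names = list(pd.unique(groups))
    if len(names) != 2:
        raise ValueError(f"expected exactly two group labels, got {names}")
    out = {}
    for train_g, test_g in ((names[0], names[1]), (names[1], names[0])):
        tr = features.index[groups == train_g]
        te = features.index[groups == test_g]
        clf = train_model(features.loc[tr], labels.loc[tr],
                          n_trees=n_trees, seed=seed)
        out[f"{train_g}->{test_g}"] = evaluate(
            clf, features.loc[te], labels.loc[te],
            strategy=f"group_split:{train_g}->{test_g}")
    return out


def evaluate_independent(train_features: pd.DataFrame, train_labels: pd.Series,
                         test_features: pd.DataFrame, test_labels: pd.Series,
                         n_trees: int = 500, seed: int = 0) -> ModelReport:
    """Train on the whole main cohort, evaluate once on an independent cohort."""
    missing = [c for c in train_features.columns if c not in test_features.columns]
    if missing:
        raise ValueError(f"independent cohort lacks DMC features: {missing}")
    clf = train_model(train_features, train_labels, n_trees=n_trees, seed=seed)
    return evaluate(clf, test_features[train_features.columns], test_labels,
                    strategy="independent")


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------

def misclassification_pca(features: pd.DataFrame, labels: pd.Series,
                          predictions: pd.Series, scale: bool = False,
                          n_components: int = 2) -> pd.DataFrame:
    """PC scores with actual/predicted quadrant tags (FF, FS, SF, SS).

    Features are centered (and optionally unit-scaled; percentages share
    units so scaling is off by default). Raises on zero-variance input.
    """
    X = features.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate input: all features are constant")
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=min(n_components, min(X.shape)))
    scores = pca.fit_transform(X - X.mean(axis=0) if not scale else X)
    out = pd.DataFrame(scores[:, :2], index=features.index, columns=["PC1", "PC2"])
    a = labels.reindex(features.index)
    p = predictions.reindex(features.index)
    out["quadrant"] = [
        ("F" if x == POSITIVE_CLASS else "S") + ("F" if y == POSITIVE_CLASS else "S")
        for x, y in zip(a, p)
    ]
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_[:2]
    return out


def compare_groups(values, group_labels) -> tuple[str, float]:
    """Two-group comparison with the cohort's test-selection rule.

    The two-sample t-test is used only when (1) each group has more than 15
    values, (2) both pass Shapiro-Wilk normality (p > 0.05) and (3) the
    F-test accepts equal variances (p > 0.05); otherwise the Wilcoxon
    rank-sum test. Returns (test name, p-value).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    names = pd.unique(group_labels)
    if len(names) != 2:
        raise ValueError("expected exactly two groups")
    a = values[group_labels == names[0]]
    b = values[group_labels == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")

    use_t = len(a) > 15 and len(b) > 15
    if use_t:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            use_t = (stats.shapiro(a).pvalue > 0.05
                     and stats.shapiro(b).pvalue > 0.05)
    if use_t:
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
        pf = 2 * min(stats.f.cdf(f, len(a) - 1, len(b) - 1),
                     stats.f.sf(f, len(a) - 1, len(b) - 1))
        use_t = pf > 0.05
    if use_t:
        return "t-test", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return "rank-sum", float(stats.ranksums(a, b).pvalue)


def hierarchical_cluster(features: pd.DataFrame) -> np.ndarray:
    """Ward linkage on 1 - Pearson correlation between sample profiles.

    Returns a scipy linkage matrix. A constant sample profile has no defined
    correlation and is rejected by name.
    """
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing cells")
    sds = X.std(axis=1)
    if (sds == 0).any():
        bad = [features.index[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant sample profiles (correlation undefined): {bad}")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return linkage(squareform(dist, checks=False), method="ward")


def correct_batch(values, batch_labels) -> np.ndarray:
    """Residuals of an OLS fit of the values on batch indicators.

    Equivalent to subtracting per-batch means, so per-batch residual means
    are exactly 0; a single-sample batch therefore yields residual 0 (and is
    flagged in the log). With a single batch the correction degenerates to
    centering.
    """
    values = np.asarray(values, dtype=float)
    batch_labels = pd.Series(batch_labels)
    counts = batch_labels.value_counts()
    if len(counts) < 2:
        logger.warning("single batch: correction is identity-centering")
    singletons = counts.index[counts == 1].tolist()
    if singletons:
        logger.warning("batches with one sample (residual forced to 0): %s",
                       singletons)
    means = pd.Series(values).groupby(batch_labels.values).transform("mean")
    return values - means.to_numpy()
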