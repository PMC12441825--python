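"""Time-resolved expectancy classification with shrinkage LDA.

The designed 75/25 class imbalance would let a degenerate classifier score
75%, so the majority class is repeatedly subsampled to the minority count
before stratified cross-validation — making 50% the true chance level that
accuracy time courses are tested against with a sign-flipping cluster
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .iem import analytic_shrinkage_intensity
from .ts_stats import ClusterResult, one_sample_cluster

__all__ = [
    "ShrinkageLDA",
    "fit_lda",
    "AccuracyTimecourse",
    "expectancy_timecourse",
    "accuracy_vs_chance",
]


class ShrinkageLDA(BaseEstimator, ClassifierMixin):
    """Binary LDA with analytic shrinkage of the pooled covariance.

    The discriminant direction is ``Sigma_pooled^{-1} (mu_1 - mu_0)`` with
    ``Sigma_pooled`` shrunk toward the scaled identity at the analytic
    (Ledoit-Wolf) intensity (``shrinkage='analytic'``; a float fixes the
    intensity, None disables shrinkage).  The decision threshold sits at the
    midpoint of the projected class means.

    Fitted attributes: ``classes_``, ``means_``, ``coef_``, ``threshold_``,
    ``shrinkage_``, ``covariance_``.
    """

    def __init__(self, shrinkage="analytic"):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.size}")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        self.classes_ = classes
        n, p = X.shape
        means = np.stack([X[y == c].mean(axis=0) for c in classes])
        Xc = X.copy()
        for k, c in enumerate(classes):
            Xc[y == c] -= means[k]
        S = (Xc.T @ Xc) / (n - 2)
        if self.shrinkage == "analytic":
            lam = analytic_shrinkage_intensity(Xc.T)
        elif self.shrinkage is None:
            lam = 0.0
        else:
            lam = float(self.shrinkage)
        nu = float(np.trace(S)) / p
        cov = (1.0 - lam) * S + lam * nu * np.eye(p)
        w = np.linalg.solve(cov, means[1] - means[0])
        self.means_ = means
        self.shrinkage_ = lam
        self.covariance_ = cov
        self.coef_ = w
        self.threshold_ = float(w @ (means[0] + means[1]) / 2.0)
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ - self.threshold_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def fit_lda(X, y, shrinkage="analytic") -> ShrinkageLDA:
    """Fit a binary shrinkage LDA (thin wrapper over ``ShrinkageLDA``)."""
    return ShrinkageLDA(shrinkage=shrinkage).fit(X, y)


@dataclass
class AccuracyTimecourse:
    accuracy: np.ndarray      # (n_timepoints,) proportions in [0, 1]
    n_folds: int
    n_repeats: int
    chance: float = 0.5
    time_ms: np.ndarray | None = None


def expectancy_timecourse(
    dataset,
    labels,
    k: int = 10,
    n_repeats: int = 2,
    balance: str = "subsample",
    seed: int | None = 0,
) -> AccuracyTimecourse:
    """Per-timepoint cross-validated expectancy classification accuracy.

    Features are all sensor amplitudes at a single timepoint.  With
    ``balance='subsample'`` the majority class is randomly subsampled to the
    minority count, freshly per repeat; accuracy is averaged over stratified
    folds and repeats.  Deterministic for a fixed seed.
    """
    data = dataset.data
    y = np.asarray(labels)
    if y.shape[0] != data.shape[0]:
        raise ValueError("labels length does not match trials")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    n_min = int(counts.min())
    if n_min < k:
        raise ValueError(f"minority class has {n_min} trials < {k} folds")
    if balance not in ("subsample", "none"):
        raise ValueError(f"unknown balance strategy {balance!r}")

    rng = np.random.default_rng(seed)
    n_time = data.shape[2]
    acc = np.zeros(n_time)
    for rep in range(n_repeats):
        if balance == "subsample":
            keep = np.concatenate([
                rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
                for c in classes
            ])
            keep.sort()
        else:
            keep = np.arange(y.size)
        y_rep = y[keep]
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        folds = list(splitter.split(np.zeros(keep.size), y_rep))
        for t in range(n_time):
            Xt = data[keep, :, t]
            fold_acc = 0.0
            for train, test in folds:
                est = ShrinkageLDA().fit(Xt[train], y_rep[train])
                fold_acc += est.score(Xt[test], y_rep[test])
            acc[t] += fold_acc / len(folds)
    acc /= n_repeats
    return AccuracyTimecourse(
        accuracy=acc, n_folds=k, n_repeats=n_repeats,
        time_ms=getattr(dataset, "times_ms", None),
    )


def accuracy_vs_chance(
    timecourses,
    chance: float = 0.5,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int | None = 0,
) -> ClusterResult:
    """Cluster-corrected test of per-subject accuracy time courses vs chance.

    One-sample sign-flipping variant of the cluster-mass permutation test,
    applied to accuracy - chance.
    """
    values = np.asarray(timecourses, dtype=float)
    return one_sample_cluster(values, mu=chance, n_perm=n_perm,
                              cluster_alpha=cluster_alpha, seed=seed)
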