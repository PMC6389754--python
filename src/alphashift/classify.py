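"""Cross-validated linear discriminant classification of seizure control.

Features are the 19 per-channel log2 alpha-power-shift values (a global
scalar is equally accepted); the classifier is Fisher's linear
discriminant from the pooled within-class covariance with a small ridge
for numerical stability, thresholded at the equal-prior midpoint.
Performance (sensitivity, specificity, AUC) is estimated with repeated
stratified 10-fold cross-validation: metrics are computed per repeat
from pooled out-of-fold predictions, and summarized as mean +/- SD with
a normal-approximation 95% CI across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass
class LinearDiscriminant:
    weights: np.ndarray
    threshold: float

    def scores(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) > self.threshold).astype(int)


@dataclass
class ClassifierReport:
    """CV performance, percent scale; CIs are mean +/- 1.96 SD over repeats."""

    sensitivity: tuple[float, float, tuple[float, float]]  # mean, sd, ci
    specificity: tuple[float, float, tuple[float, float]]
    auc: tuple[float, float, tuple[float, float]]
    n_folds: int
    n_repeats: int
    seed: int


def lda_train(features, labels, ridge: float = 1e-6) -> LinearDiscriminant:
    """Fisher discriminant w = Sigma^-1 (mu1 - mu0), equal-prior threshold.

    The pooled within-class covariance is regularized by
    ridge * trace / dim on the diagonal.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError(">= 2 subjects per class required")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Sw = (np.cov(X0, rowvar=False, ddof=1) * (len(X0) - 1)
          + np.cov(X1, rowvar=False, ddof=1) * (len(X1) - 1))
    Sw = np.atleast_2d(Sw) / (len(X0) + len(X1) - 2)
    if np.allclose(Sw, 0) and np.allclose(mu0, mu1):
        raise ValueError("both classes identical: no discriminant exists")
    d = Sw.shape[0]
    Sw_reg = Sw + ridge * (np.trace(Sw) / d if np.trace(Sw) > 0 else 1.0) \
        * np.eye(d)
    w = np.linalg.solve(Sw_reg, mu1 - mu0)
    thr = float(w @ (mu0 + mu1) / 2)
    return LinearDiscriminant(weights=w, threshold=thr)


def _summarize(values: np.ndarray) -> tuple[float, float,
                                            tuple[float, float]]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return mean, sd, (mean - 1.96 * sd, mean + 1.96 * sd)


def cross_validate(features, labels, n_folds: int = 10,
                   n_repeats: int = 100, seed: int = 0) -> ClassifierReport:
    """Repeated stratified k-fold CV of the linear discriminant.

    Per repeat, sensitivity and specificity come from pooled
    out-of-fold class predictions and the AUC from pooled out-of-fold
    discriminant scores (rank-based).  The positive class is the
    higher-coded label.  Deterministic under ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if counts.min() < n_folds:
        raise ValueError(f"smallest class ({counts.min()}) is below the "
                         f"fold count ({n_folds})")
    y01 = (y == classes[1]).astype(int)
    rng = np.random.default_rng(seed)
    sens = np.empty(n_repeats)
    spec = np.empty(n_repeats)
    auc = np.empty(n_repeats)
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        pred = np.empty_like(y01)
        score = np.empty(len(y01), dtype=float)
        for train, test in skf.split(X, y01):
            lda = lda_train(X[train], y01[train])
            pred[test] = lda.predict(X[test])
            score[test] = lda.scores(X[test])
        sens[r] = (pred[y01 == 1] == 1).mean()
        spec[r] = (pred[y01 == 0] == 0).mean()
        auc[r] = roc_auc_score(y01, score)
    return ClassifierReport(
        sensitivity=_summarize(100 * sens),
        specificity=_summarize(100 * spec),
        auc=_summarize(100 * auc),
        n_folds=n_folds, n_repeats=n_repeats, seed=seed)


def auc_z_test(scores, labels) -> tuple[float, float]:
    """z-test of the AUC against 0.5 (rank-sum normal approximation).

    Uses the Mann-Whitney U of the positive-class scores with tie
    correction; returns (z, two-sided p).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    n1 = int((y == classes[1]).sum())
    n0 = int((y == classes[0]).sum())
    ranks = stats.rankdata(s)
    U = float(ranks[y == classes[1]].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n0 / 2
    n = n0 + n1
    _, tie_counts = np.unique(s, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) \
        if n > 1 else 0.0
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise ValueError("degenerate score distribution (all ties)")
    # continuity-corrected z (U is integer-stepped under the null)
    z = (U - mu - 0.5 * np.sign(U - mu)) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))
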