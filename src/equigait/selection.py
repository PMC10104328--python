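"""NCA feature weighting, greedy forward selection and LOSO-CV evaluation.

The feature-weighting variant of neighborhood component analysis learns a
nonnegative relevance weight per feature by maximizing the expected
leave-one-out accuracy of a soft nearest-neighbour classifier under the
weighted L1 metric d(i,j) = sum_f w_f^2 |x_if - x_jf|, with an L2 penalty
on the weights.  Features are ranked by weight; a classifier is then grown
over ranked prefixes and evaluated with leave-one-subject-out (one horse =
one fold) cross-validation, the positive class being the rested (pre
exercise test) state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIERS = ("SVM", "kNN", "tree", "NB", "logistic")


@dataclass
class FeatureRanking:
    """Features ordered by descending NCA weight (ties: canonical order)."""

    names: list
    weights: np.ndarray
    subset_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("ranking weights must be nonnegative")


@dataclass
class ConfusionCounts:
    """Pooled confusion counts; positive class = pre (non-fatigue)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceMetrics:
    """Accuracy, sensitivity (pre recall) and specificity (post recall)."""

    accuracy: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan


def performance(counts: ConfusionCounts) -> PerformanceMetrics:
    """accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP); an empty denominator yields NaN."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    return PerformanceMetrics(
        accuracy=(tp + tn) / total if total else np.nan,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
    )


# ---------------------------------------------------------------------------
# feature-weighting NCA
# ---------------------------------------------------------------------------

def _nca_objective(w: np.ndarray, diffs: np.ndarray, same: np.ndarray,
                   lam: float) -> tuple[float, np.ndarray]:
    """Negative regularized NCA objective and gradient.

    diffs: (n, n, p) pairwise absolute feature differences;
    same: (n, n) boolean same-class mask with zero diagonal.
    """
    n = diffs.shape[0]
    w2 = w ** 2
    d = diffs @ w2                                     # (n, n)
    np.fill_diagonal(d, np.inf)
    neg = -d
    neg -= neg.max(axis=1, keepdims=True)
    k = np.exp(neg)
    p = k / k.sum(axis=1, keepdims=True)               # soft-neighbour probs
    p_i = (p * same).sum(axis=1)
    f = p_i.mean() - lam * float(w2.sum())

    # dF/dw_f = (2 w_f / n) sum_i [ p_i sum_k p_ik A_ikf - sum_{j in C_i} p_ij A_ijf ]
    coef = p * p_i[:, None] - p * same                 # (n, n)
    grad = (2.0 * w / n) * np.einsum("ij,ijf->f", coef, diffs) - 2.0 * lam * w
    return -f, -grad


def nca_weights(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    seed: int = 0,
    max_iter: int = 200,
) -> np.ndarray:
    """Per-feature NCA relevance weights (absolute values).

    Gradient-based optimization (L-BFGS) from the all-ones start.  ``lam``
    defaults to 1/n.  The objective is even in each weight, so the sign is
    irrelevant and |w| is returned.  A constant feature matrix yields
    all-equal weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if n < 4:
        raise ValueError("NCA needs at least 4 samples")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if lam is None:
        lam = 1.0 / n
    diffs = np.abs(X[:, None, :] - X[None, :, :])
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    res = optimize.minimize(
        _nca_objective, np.ones(p), args=(diffs, same, lam),
        jac=True, method="L-BFGS-B", options={"maxiter": max_iter},
    )
    return np.abs(res.x)


def rank_features(weights: np.ndarray, names: list, subset_id: str = "") -> FeatureRanking:
    """Order features by descending weight; ties keep the canonical
    (input) order, and permuting the inputs permutes nothing in the
    resulting name sequence."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(names):
        raise ValueError("weights and names must align")
    order = np.argsort(-weights, kind="stable")
    return FeatureRanking(
        names=[names[i] for i in order],
        weights=weights[order],
        subset_id=subset_id,
    )


# ---------------------------------------------------------------------------
# classifiers and cross-validation
# ---------------------------------------------------------------------------

def make_classifier(name: str, seed: int = 0, hyperparams: dict | None = None):
    """The five classifier families; features are already in [0, 1], so the
    SVM is linear with unit regularization constant."""
    hp = hyperparams or {}
    if name == "SVM":
        return SVC(kernel=hp.get("kernel", "linear"), C=hp.get("C", 1.0))
    if name == "kNN":
        return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if name == "NB":
        return GaussianNB(**hp)
    if name == "logistic":
        return LogisticRegression(max_iter=hp.get("max_iter", 1000), C=hp.get("C", 1.0))
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class LosoResult:
    counts: ConfusionCounts
    metrics: PerformanceMetrics
    fold_accuracy: np.ndarray = field(default_factory=lambda: np.empty(0))
    fold_sensitivity: np.ndarray = field(default_factory=lambda: np.empty(0))
    fold_specificity: np.ndarray = field(default_factory=lambda: np.empty(0))


def loso_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    classifier: str = "SVM",
    seed: int = 0,
    hyperparams: dict | None = None,
) -> LosoResult:
    """Leave-one-subject-out cross-validation with pooled confusion counts.

    One fold per horse; the held-out horse's samples never appear in that
    fold's training set.  Per-fold accuracy/sensitivity/specificity are
    also returned (NaN where a fold lacks a class).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("LOSO-CV needs at least two subjects")
    counts = ConfusionCounts()
    f_acc, f_sen, f_spe = [], [], []
    for train, test in LeaveOneGroupOut().split(X, y, groups):
        clf = make_classifier(classifier, seed=seed, hyperparams=hyperparams)
        if classifier == "kNN":
            k = min(clf.n_neighbors, len(train))
            clf.set_params(n_neighbors=k)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        truth = y[test]
        tp = int(np.sum((truth == 1) & (pred == 1)))
        fp = int(np.sum((truth == 0) & (pred == 1)))
        tn = int(np.sum((truth == 0) & (pred == 0)))
        fn = int(np.sum((truth == 1) & (pred == 0)))
        counts.tp += tp
        counts.fp += fp
        counts.tn += tn
        counts.fn += fn
        m = performance(ConfusionCounts(tp, fp, tn, fn))
        f_acc.append(m.accuracy)
        f_sen.append(m.sensitivity)
        f_spe.append(m.specificity)
    return LosoResult(
        counts=counts,
        metrics=performance(counts),
        fold_accuracy=np.asarray(f_acc),
        fold_sensitivity=np.asarray(f_sen),
        fold_specificity=np.asarray(f_spe),
    )


@dataclass
class SelectionResult:
    features: list
    result: LosoResult
    accuracy_path: list


def greedy_forward_selection(
    ranking: FeatureRanking,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list,
    classifier: str = "SVM",
    seed: int = 0,
    hyperparams: dict | None = None,
    max_features: int | None = None,
) -> SelectionResult:
    """Grow the feature set along the NCA ranking until accuracy drops.

    Prefixes of size 1, 2, ... of the ranking are evaluated with LOSO-CV;
    the process stops at the first strict accuracy decrease and returns the
    preceding prefix.  Equal accuracy continues.
    """
    if not ranking.names:
        raise ValueError("empty feature ranking")
    col = {n: i for i, n in enumerate(names)}
    best: SelectionResult | None = None
    path: list = []
    limit = len(ranking.names) if max_features is None else min(max_features, len(ranking.names))
    for k in range(1, limit + 1):
        idx = [col[n] for n in ranking.names[:k]]
        res = loso_cv(X[:, idx], y, groups, classifier, seed=seed, hyperparams=hyperparams)
        path.append(res.metrics.accuracy)
        if best is not None and res.metrics.accuracy < best.result.metrics.accuracy:
            break
        best = SelectionResult(features=list(ranking.names[:k]), result=res,
                               accuracy_path=path)
    assert best is not None
    best.accuracy_path = path
    return best
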