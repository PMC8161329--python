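"""Statistical testing and the repeated-cross-validation harness.

Five classifiers separate SR from PAF feature vectors: linear SVM, kNN,
random forest, rotation forest (trees on per-group principal-component
rotations of the feature space), and an error-weighted voting ensemble
over SVM, RF and RoF.  Evaluation uses stratified 5-fold cross-validation
repeated 10 times with a fresh shuffle per repeat; reported metrics are
precision, recall, F (harmonic mean), accuracy, and AUC from a
fold-averaged ROC curve.  PAF is the positive class throughout —
screening for the pathological rhythm — and tied ensemble votes resolve
to PAF for the same reason.

Group separation of scalar features is assessed with the non-parametric
Wilcoxon test: signed-rank for paired samples, rank-sum otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y

__all__ = [
    "POSITIVE_LABEL",
    "ClassifierConfig",
    "CVResult",
    "DEFAULT_CONFIGS",
    "RotationForestClassifier",
    "WeightedVoteEnsemble",
    "make_classifier",
    "wilcoxon_test",
    "classification_metrics",
    "run_cv",
    "average_roc",
]

POSITIVE_LABEL = "PAF"
NEGATIVE_LABEL = "SR"

CLASSIFIER_NAMES = ("SVM", "kNN", "RF", "RoF", "EL")


@dataclass
class ClassifierConfig:
    """Name + hyperparameters for one classifier, with an optional search grid."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    grid: dict | None = None

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")


# Tuned defaults and their admissible search ranges.  The SVM gamma is
# carried for completeness but is inert under the linear kernel.
DEFAULT_CONFIGS: dict[str, ClassifierConfig] = {
    "SVM": ClassifierConfig(
        "SVM",
        {"kernel": "linear", "C": 0.01, "gamma": 0.1},
        grid={"C": [0.001, 0.01, 0.1, 1], "gamma": [0.01, 0.1, 1]},
    ),
    "kNN": ClassifierConfig(
        "kNN",
        {"n_neighbors": 5, "weights": "uniform", "metric": "euclidean"},
        grid={"n_neighbors": list(range(1, 11)), "weights": ["uniform", "distance"]},
    ),
    "RF": ClassifierConfig(
        "RF",
        {
            "n_estimators": 100,
            "max_features": "sqrt",
            "min_samples_split": 10,
            "min_samples_leaf": 1,
            "max_depth": None,
        },
        grid={"min_samples_split": [2, 4, 6, 8, 10, 12], "min_samples_leaf": [1, 2, 3]},
    ),
    "RoF": ClassifierConfig(
        "RoF",
        {"n_rotations": 10, "group_size": 3, "base_trees": 10},
    ),
    "EL": ClassifierConfig("EL", {"members": ["SVM", "RF", "RoF"]}),
}


# ---------------------------------------------------------------------------
# Rotation forest
# ---------------------------------------------------------------------------

class RotationForestClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of forests trained on per-group PCA rotations.

    For each ensemble member the features are partitioned at random into
    disjoint groups of ``group_size`` (the last group may be smaller).
    For every group a PCA is fitted on a bootstrap subsample drawn from a
    random subset of the classes, and the per-group loadings are
    assembled into a block-diagonal orthonormal rotation of the full
    feature space.  A small forest is then fitted on the rotated data;
    prediction averages the members' class probabilities.

    Rotating per group rather than globally keeps every component (no
    dimensionality reduction) while decorrelating the members, which is
    what gives the ensemble its diversity.
    """

    def __init__(
        self,
        n_rotations: int = 10,
        group_size: int = 3,
        base_trees: int = 10,
        sample_fraction: float = 0.75,
        random_state: int | None = None,
    ):
        self.n_rotations = n_rotations
        self.group_size = group_size
        self.base_trees = base_trees
        self.sample_fraction = sample_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("degenerate labels: need at least 2 classes")
        n_features = X.shape[1]
        if self.group_size > n_features:
            raise ValueError("invalid grouping: group size exceeds feature count")
        rng = np.random.default_rng(self.random_state)
        self.rotations_ = []
        self.estimators_ = []
        for _ in range(self.n_rotations):
            R = self._build_rotation(X, y_enc, n_features, rng)
            est = RandomForestClassifier(
                n_estimators=self.base_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
            )
            est.fit(X @ R, y_enc)
            self.rotations_.append(R)
            self.estimators_.append(est)
        return self

    def _build_rotation(self, X, y_enc, n_features, rng) -> np.ndarray:
        perm = rng.permutation(n_features)
        groups = [perm[i : i + self.group_size] for i in range(0, n_features, self.group_size)]
        R = np.zeros((n_features, n_features))
        for cols in groups:
            # PCA basis estimated on a bootstrap of a random class subset
            classes = np.unique(y_enc)
            keep = classes[rng.random(classes.size) < 0.75]
            if keep.size == 0:
                keep = classes
            pool = np.flatnonzero(np.isin(y_enc, keep))
            n_draw = max(int(self.sample_fraction * pool.size), cols.size, 2)
            sample = rng.choice(pool, size=min(n_draw, pool.size) if pool.size else 0, replace=True)
            sub = X[np.atleast_1d(sample)][:, cols]
            if np.unique(sub, axis=0).shape[0] < 2:
                basis = np.eye(cols.size)  # degenerate subsample: identity block
            else:
                pca = PCA(n_components=cols.size, svd_solver="full")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pca.fit(sub)
                basis = pca.components_.T
                if basis.shape[1] < cols.size:  # rank-deficient: pad to orthonormal
                    basis = np.linalg.qr(
                        np.hstack([basis, rng.standard_normal((cols.size, cols.size))])
                    )[0][:, : cols.size]
            R[np.ix_(cols, cols)] = basis
        return R

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        probas = np.zeros((X.shape[0], self.classes_.size))
        for R, est in zip(self.rotations_, self.estimators_):
            p = est.predict_proba(X @ R)
            probas[:, est.classes_] += p
        return probas / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Error-weighted voting ensemble
# ---------------------------------------------------------------------------

class WeightedVoteEnsemble(BaseEstimator, ClassifierMixin):
    """Committee of heterogeneous learners combined by weighted vote.

    Each member is fitted on the full training set and weighted by its
    training error through the boosting weight w = ln((1−err)/err),
    clipped to [0, 10] (an error-free member takes the clip value, a
    worse-than-chance member is silenced).  Prediction is the
    weight-majority label; exact ties resolve to the positive class.
    ``voting="majority"`` switches to unweighted votes.
    """

    def __init__(
        self,
        members: Sequence[tuple[str, BaseEstimator]] | None = None,
        voting: str = "weighted",
        positive_label: str = POSITIVE_LABEL,
    ):
        self.members = members
        self.voting = voting
        self.positive_label = positive_label

    def fit(self, X, y):
        if not self.members:
            raise ValueError("no base classifiers")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("degenerate labels: need at least 2 classes")
        self.fitted_ = []
        self.weights_ = []
        for _, est in self.members:
            est = clone(est)
            est.fit(X, y)
            err = float(np.mean(est.predict(X) != y))
            if self.voting == "majority":
                w = 1.0
            elif err == 0.0:
                w = 10.0
            else:
                w = float(np.clip(np.log((1 - err) / err), 0.0, 10.0))
            self.fitted_.append(est)
            self.weights_.append(w)
        if not any(self.weights_):  # all at or below chance: fall back to plain vote
            self.weights_ = [1.0] * len(self.fitted_)
        return self

    def vote_score(self, X) -> np.ndarray:
        """Weighted fraction of votes for the positive class, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        total = sum(self.weights_)
        score = np.zeros(X.shape[0])
        for est, w in zip(self.fitted_, self.weights_):
            score += w * (est.predict(X) == self.positive_label)
        return score / total

    def predict(self, X):
        score = self.vote_score(X)
        other = next(c for c in self.classes_ if c != self.positive_label)
        return np.where(score >= 0.5, self.positive_label, other)  # tie -> positive


def make_classifier(cfg: ClassifierConfig, random_state: int | None = None) -> BaseEstimator:
    """Instantiate the estimator a config describes."""
    hp = cfg.hyperparameters
    if cfg.name == "SVM":
        return SVC(
            kernel=hp.get("kernel", "linear"),
            C=hp.get("C", 0.01),
            gamma=hp.get("gamma", 0.1),
        )
    if cfg.name == "kNN":
        return KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 5),
            weights=hp.get("weights", "uniform"),
            metric=hp.get("metric", "euclidean"),
        )
    if cfg.name == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_features=hp.get("max_features", "sqrt"),
            min_samples_split=hp.get("min_samples_split", 10),
            min_samples_leaf=hp.get("min_samples_leaf", 1),
            max_depth=hp.get("max_depth", None),
            random_state=random_state,
        )
    if cfg.name == "RoF":
        return RotationForestClassifier(
            n_rotations=hp.get("n_rotations", 10),
            group_size=hp.get("group_size", 3),
            base_trees=hp.get("base_trees", 10),
            random_state=random_state,
        )
    if cfg.name == "EL":
        names = hp.get("members", ["SVM", "RF", "RoF"])
        members = [
            (m, make_classifier(DEFAULT_CONFIGS[m], random_state=random_state))
            for m in names
        ]
        return WeightedVoteEnsemble(members=members, voting=hp.get("voting", "weighted"))
    raise ValueError(f"unknown classifier {cfg.name!r}")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def wilcoxon_test(group_a, group_b, paired: bool = False) -> float:
    """Two-sided Wilcoxon p-value for a difference between two groups.

    Signed-rank test for paired samples, rank-sum (Mann-Whitney) for
    independent groups.  Small samples use exact null distributions
    where scipy provides them, the normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 values per group")
    if paired:
        if a.size != b.size:
            raise ValueError("pairing mismatch: groups differ in length")
        if np.all(a == b):
            raise ValueError("degenerate test: all paired differences are zero")
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def classification_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Precision, recall, F, accuracy from a confusion table (PAF positive).

    Zero-denominator metrics are reported as 0 and flagged in the
    ``undefined`` list rather than raising.
    """
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise ValueError("invalid confusion counts")
    undefined = []
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        undefined.append("precision")
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        recall = 0.0
        undefined.append("recall")
    if precision + recall:
        f = 2 * precision * recall / (precision + recall)
    else:
        f = 0.0
        undefined.append("F")
    acc = (tp + tn) / (tp + fp + fn + tn)
    return {
        "precision": precision,
        "recall": recall,
        "F": f,
        "ACC": acc,
        "undefined": undefined,
    }


def average_roc(
    per_fold_scores: Sequence[tuple[np.ndarray, np.ndarray]],
    grid_points: int = 101,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Average per-fold ROC curves on a common FPR grid.

    Each element is ``(y_true_positive, scores)`` for one fold.  Folds
    whose truth contains a single class are excluded with a warning.
    Returns ``(fpr_grid, mean_tpr, auc)`` with AUC by trapezoid on the
    mean curve.
    """
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = []
    for y_true, scores in per_fold_scores:
        y_true = np.asarray(y_true, dtype=bool)
        if y_true.all() or not y_true.any():
            warnings.warn("fold with single-class truth excluded from ROC averaging")
            continue
        fpr, tpr, _ = roc_curve(y_true, scores)
        # reduce to vertices (unique FPR, highest TPR) and interpolate linearly
        # between operating points — the standard convention under tied scores
        last = np.r_[np.flatnonzero(np.diff(fpr)), fpr.size - 1]
        tprs.append(np.interp(grid, fpr[last], tpr[last]))
    if not tprs:
        raise ValueError("no usable folds for ROC averaging")
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    auc = float(np.trapezoid(mean_tpr, grid))
    return grid, mean_tpr, auc


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Grand-mean metrics of a repeated stratified cross-validation run."""

    classifier: str
    folds: int
    repeats: int
    per_repeat: pd.DataFrame  # one row per repeat: precision, recall, F, ACC
    means: dict  # grand means incl. AUC
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    seed: int


def _score_fn(est) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous positive-class score for ROC, per estimator type."""
    if isinstance(est, WeightedVoteEnsemble):
        return est.vote_score
    if hasattr(est, "predict_proba"):
        def proba(X):
            pos = int(np.flatnonzero(est.classes_ == POSITIVE_LABEL)[0])
            return est.predict_proba(X)[:, pos]
        return proba
    def decision(X):  # SVC decision_function; sign toward classes_[1]
        d = est.decision_function(X)
        return d if est.classes_[1] == POSITIVE_LABEL else -d
    return decision


def run_cv(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    cfg: ClassifierConfig,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    use_grid: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation repeated with fresh shuffles.

    Folds are stratified on the binary label and reshuffled each repeat
    from a seed-derived stream, so the same seed reproduces the exact
    partition.  Metrics are pooled over the folds of a repeat and then
    averaged over repeats; ROC curves are averaged over all folds of all
    repeats.  With ``use_grid`` the config's search grid is tuned by
    nested cross-validation inside each training fold.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("degenerate labels: need both classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        raise ValueError("insufficient data: need at least `folds` samples per class")

    rows = []
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(repeats):
        rep_seed = (seed * 1000 + rep) % (2**31)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        tp = fp = fn = tn = 0
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            est = make_classifier(cfg, random_state=(rep_seed + fold_i) % (2**31))
            if use_grid and cfg.grid:
                est = GridSearchCV(est, cfg.grid, cv=3, scoring="f1_macro")
            est.fit(X[tr], y[tr])
            inner = est.best_estimator_ if isinstance(est, GridSearchCV) else est
            pred = np.asarray(inner.predict(X[te]))
            truth = y[te]
            tp += int(np.sum((pred == POSITIVE_LABEL) & (truth == POSITIVE_LABEL)))
            fp += int(np.sum((pred == POSITIVE_LABEL) & (truth != POSITIVE_LABEL)))
            fn += int(np.sum((pred != POSITIVE_LABEL) & (truth == POSITIVE_LABEL)))
            tn += int(np.sum((pred != POSITIVE_LABEL) & (truth != POSITIVE_LABEL)))
            fold_scores.append((truth == POSITIVE_LABEL, _score_fn(inner)(X[te])))
        m = classification_metrics(tp, fp, fn, tn)
        rows.append({k: m[k] for k in ("precision", "recall", "F", "ACC")})
    per_repeat = pd.DataFrame(rows)
    fpr, tpr, auc = average_roc(fold_scores)
    means = {k: float(per_repeat[k].mean()) for k in per_repeat.columns}
    means["AUC"] = auc
    return CVResult(
        classifier=cfg.name,
        folds=folds,
        repeats=repeats,
        per_repeat=per_repeat,
        means=means,
        roc_fpr=fpr,
        roc_tpr=tpr,
        seed=seed,
    )
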