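"""Severity grading: band selection, classifiers, and accuracy evaluation.

Feature selection follows the field procedure: Pearson correlation between
the ordinal aphid grade (0-4) of the ground points and each
derivative-of-ratio feature, with two-sided t-test p-values starred at the
0.05 / 0.01 / 0.001 levels; features significant at the selection level
(default 0.01) become classifier inputs.

Classification treats grades as nominal classes.  Random forest is the
reference model; spectral angle mapper (SAM), decision tree, RBF support
vector machine and a one-hidden-layer backpropagation network are the
comparison contract.  Accuracy is reported as a confusion matrix (rows =
predicted, columns = truth) with overall accuracy OA = sum(n_ii)/n,
producer's accuracy PA (column-wise), user's accuracy UA (row-wise), and
the chance-corrected kappa coefficient

    kappa = (n * sum_i n_ii - sum_i row_i * col_i) / (n^2 - sum_i row_i * col_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "SIGNIFICANCE_TIERS",
    "CorrelationTable",
    "BandSelection",
    "ClassifierSpec",
    "ConfusionMatrix",
    "GradingResult",
    "pearson_band_correlation",
    "select_bands",
    "PearsonBandSelector",
    "SAMClassifier",
    "sam_classify",
    "make_classifier",
    "train_grading_model",
    "predict_map",
    "confusion_metrics",
]

#: significance levels and their star labels, strongest first
SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _tier(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for level, stars in SIGNIFICANCE_TIERS:
        if p <= level:
            return stars
    return ""


@dataclass(frozen=True)
class CorrelationTable:
    """Per-feature Pearson r, two-sided p and significance tier.

    Constant features are flagged (``defined`` False, r and p NaN) and are
    excluded from selection.
    """

    labels: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.labels,
                "r": self.r,
                "p": self.p,
                "significance": [_tier(pv) for pv in self.p],
            }
        )


@dataclass(frozen=True)
class BandSelection:
    """Ordered selected feature labels plus the selection level used."""

    labels: tuple[str, ...]
    alpha: float

    def indices(self, all_labels) -> np.ndarray:
        all_labels = list(all_labels)
        return np.asarray([all_labels.index(l) for l in self.labels], dtype=int)


def pearson_band_correlation(
    grades, features, labels=None
) -> CorrelationTable:
    """Pearson correlation of ordinal grade with each feature column.

    Parameters
    ----------
    grades : array of shape (n_points,)
        Ordinal severity grades (not all equal).
    features : array of shape (n_points, n_features)
        Per-point feature vectors.
    labels : sequence of str, optional
        Feature names; defaults to f0..f{k-1}.
    """
    g = np.asarray(grades, dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(g) != len(X):
        raise ValueError("features must be (n_points, n_features) aligned to grades")
    if len(g) < 3:
        raise ValueError("need at least 3 points for a correlation test")
    if np.ptp(g) == 0:
        raise ValueError("grades are all equal; correlation undefined")
    if labels is None:
        labels = tuple(f"f{i}" for i in range(X.shape[1]))
    labels = tuple(labels)
    if len(labels) != X.shape[1]:
        raise ValueError("one label per feature column required")
    r = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    defined = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        col = X[:, j]
        if not np.all(np.isfinite(col)) or np.ptp(col) == 0:
            continue
        res = stats.pearsonr(g, col)
        r[j], p[j] = res.statistic, res.pvalue
        defined[j] = True
    return CorrelationTable(labels, r, p, defined)


def select_bands(table: CorrelationTable, alpha: float = 0.01) -> BandSelection:
    """Features significant at level ``alpha`` (p <= alpha), in band order.

    Raises
    ------
    ValueError
        If no feature passes, with a hint to relax alpha.
    """
    keep = table.defined & (table.p <= alpha)
    if not keep.any():
        raise ValueError(
            f"no feature significant at alpha={alpha}; increase alpha or "
            "revisit the features"
        )
    return BandSelection(
        tuple(l for l, k in zip(table.labels, keep) if k), alpha
    )


class PearsonBandSelector(SelectorMixin, BaseEstimator):
    """Feature selection by Pearson significance against an ordinal target.

    Keeps the columns whose two-sided Pearson p-value against ``y`` is at or
    below ``alpha`` (default 0.01).  Constant or non-finite columns are
    dropped.

    Attributes
    ----------
    r_ : ndarray
        Pearson correlation per input feature (NaN where undefined).
    pvalues_ : ndarray
        Two-sided p-values.
    support_ : ndarray of bool
        Selected-feature mask.
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_all_finite="allow-nan")
        table = pearson_band_correlation(y, X)
        self.r_ = table.r
        self.pvalues_ = table.p
        self.support_ = table.defined & (table.p <= self.alpha)
        self.n_features_in_ = X.shape[1]
        if not self.support_.any():
            raise ValueError(
                f"no feature significant at alpha={self.alpha}; increase alpha"
            )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# Spectral angle mapper


def sam_classify(features, references) -> np.ndarray:
    """Assign each feature vector to the reference with the smallest spectral
    angle arccos(x.ref / (|x||ref|)).

    ``references`` maps class label -> reference vector (or is an array whose
    row index is the label).  Ties break to the lower class index; zero-norm
    inputs raise.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if isinstance(references, dict):
        labels = sorted(references)
        R = np.stack([np.asarray(references[l], dtype=float) for l in labels])
    else:
        R = np.atleast_2d(np.asarray(references, dtype=float))
        labels = list(range(len(R)))
    xn = np.linalg.norm(X, axis=1)
    rn = np.linalg.norm(R, axis=1)
    if np.any(xn == 0):
        raise ValueError("zero-norm feature vector has no spectral angle")
    if np.any(rn == 0):
        raise ValueError("zero-norm reference vector has no spectral angle")
    cos = np.clip((X @ R.T) / np.outer(xn, rn), -1.0, 1.0)
    theta = np.arccos(cos)
    return np.asarray(labels)[np.argmin(theta, axis=1)]


class SAMClassifier(ClassifierMixin, BaseEstimator):
    """Spectral angle mapper with per-class mean reference vectors.

    ``fit`` stores the mean training vector of each class; ``predict``
    assigns the class whose reference subtends the smallest angle with the
    input.  Scale-invariant: predict(c*x) == predict(x) for c > 0.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = unique_labels(y)
        self.references_ = np.stack(
            [X[y == c].mean(axis=0) for c in self.classes_]
        )
        if np.any(np.linalg.norm(self.references_, axis=1) == 0):
            raise ValueError("a class mean reference has zero norm")
        return self

    def predict(self, X):
        check_is_fitted(self, "references_")
        X = check_array(X)
        idx = sam_classify(X, self.references_)
        return self.classes_[idx]


# ---------------------------------------------------------------------------
# Classifier contract


@dataclass(frozen=True)
class ClassifierSpec:
    """Which severity classifier to train and how.

    ``algorithm`` is one of rf / sam / dt / svm / bp; ``cv_folds`` controls
    the stratified cross-validation used for hyperparameter tuning on the
    training split (``tune=False`` fits library defaults directly).
    """

    algorithm: str = "rf"
    params: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0
    tune: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in ("rf", "sam", "dt", "svm", "bp"):
            raise ValueError(f"unsupported algorithm {self.algorithm!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the estimator and hyperparameter grid for a spec."""
    if spec.algorithm == "rf":
        est = RandomForestClassifier(random_state=spec.seed, **spec.params)
        grid = {"n_estimators": [100, 300, 500], "max_features": ["sqrt", None]}
    elif spec.algorithm == "dt":
        est = DecisionTreeClassifier(random_state=spec.seed, **spec.params)
        grid = {"max_depth": [None, 3, 5]}
    elif spec.algorithm == "svm":
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="rbf", **spec.params))]
        )
        grid = {"clf__C": [1.0, 10.0, 100.0]}
    elif spec.algorithm == "bp":
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=(16,),
                        max_iter=3000,
                        random_state=spec.seed,
                        **spec.params,
                    ),
                ),
            ]
        )
        grid = {"clf__alpha": [1e-4, 1e-3]}
    else:  # sam
        est = SAMClassifier()
        grid = {}
    return est, grid


# ---------------------------------------------------------------------------
# Confusion matrix


class ConfusionMatrix:
    """K x K confusion counts with OA / PA / UA / kappa.

    Orientation: ``counts[i, j]`` is the number of samples of true class
    ``labels[j]`` predicted as ``labels[i]`` (rows = predicted, columns =
    truth).  User's accuracy is row-wise, producer's accuracy column-wise.
    """

    def __init__(self, counts, labels=None):
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        if counts.sum() == 0:
            raise ValueError("empty confusion matrix")
        self.counts = counts.astype(int)
        self.labels = (
            tuple(labels) if labels is not None else tuple(range(len(counts)))
        )
        if len(self.labels) != len(counts):
            raise ValueError("one label per class required")

    @classmethod
    def from_labels(cls, pred, truth, labels=None) -> "ConfusionMatrix":
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        if pred.shape != truth.shape or pred.size == 0:
            raise ValueError("pred and truth must be equal-length and non-empty")
        if labels is None:
            labels = np.unique(np.concatenate([truth, pred]))
        labels = list(labels)
        k = len(labels)
        lut = {l: i for i, l in enumerate(labels)}
        counts = np.zeros((k, k), dtype=int)
        for p, t in zip(pred, truth):
            counts[lut[p], lut[t]] += 1
        return cls(counts, labels)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def oa(self) -> float:
        """Overall accuracy sum(n_ii) / n."""
        return float(np.trace(self.counts) / self.n)

    @property
    def ua(self) -> np.ndarray:
        """User's accuracy per class: diagonal / row total (NaN for empty rows)."""
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    @property
    def pa(self) -> np.ndarray:
        """Producer's accuracy per class: diagonal / column total."""
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, np.diag(self.counts) / col, np.nan)

    @property
    def kappa(self) -> float:
        """Chance-corrected agreement coefficient."""
        n = self.n
        chance = float(self.counts.sum(axis=1) @ self.counts.sum(axis=0))
        denom = n * n - chance
        if denom == 0:
            return 0.0
        return float((n * np.trace(self.counts) - chance) / denom)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=[f"pred_{l}" for l in self.labels],
            columns=[f"true_{l}" for l in self.labels],
        )
        df["UA"] = self.ua
        return df

    def metrics(self) -> dict:
        return {
            "n": self.n,
            "oa": self.oa,
            "kappa": self.kappa,
            "ua": {str(l): float(u) for l, u in zip(self.labels, self.ua)},
            "pa": {str(l): float(p) for l, p in zip(self.labels, self.pa)},
        }


def confusion_metrics(pred, truth, labels=None) -> ConfusionMatrix:
    """Confusion matrix and accuracy metrics from predicted vs true labels."""
    return ConfusionMatrix.from_labels(pred, truth, labels)


# ---------------------------------------------------------------------------
# Model training


@dataclass(frozen=True)
class GradingResult:
    """A fitted severity model plus its held-out evaluation."""

    model: object
    confusion: ConfusionMatrix
    train_idx: np.ndarray
    test_idx: np.ndarray
    spec: ClassifierSpec


def stratified_split(grades, test_fraction: float = 1.0 / 3.0, seed: int = 0):
    """Stratified train/test split of point indices by grade (2:1 default).

    Grades with fewer than 3 points trigger a warning and a best-effort
    split (stratification is dropped if any grade has fewer than 2 points).
    """
    g = np.asarray(grades)
    idx = np.arange(len(g))
    counts = pd.Series(g).value_counts()
    stratify = g
    if counts.min() < 3:
        warnings.warn(
            f"grade(s) {sorted(counts[counts < 3].index.tolist())} have fewer "
            "than 3 points; split is best-effort",
            UserWarning,
            stacklevel=2,
        )
        if counts.min() < 2:
            stratify = None
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=stratify
    )
    return np.sort(train_idx), np.sort(test_idx)


def train_grading_model(
    features,
    grades,
    spec: ClassifierSpec = ClassifierSpec(),
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> GradingResult:
    """Train a severity classifier with a stratified 2:1 train/test split.

    Hyperparameters are chosen by stratified k-fold cross-validation on the
    training split only (the fold count is capped by the rarest training
    grade); the returned confusion matrix is computed on the held-out third.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(grades)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n_points, n_features) aligned to grades")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two grades present to train")
    if split is None:
        split = stratified_split(y, seed=spec.seed)
    train_idx, test_idx = split
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]

    est, grid = make_classifier(spec)
    if spec.tune and grid:
        min_class = int(pd.Series(y_tr).value_counts().min())
        n_splits = max(2, min(spec.cv_folds, min_class))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
        search = GridSearchCV(est, grid, cv=cv, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            search.fit(X_tr, y_tr)
        model = search.best_estimator_
    else:
        model = clone(est)
        model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    cm = ConfusionMatrix.from_labels(pred, y_te, labels=np.unique(y))
    return GradingResult(model, cm, train_idx, test_idx, spec)


def predict_map(
    model,
    feature_raster: np.ndarray,
    mask: np.ndarray,
    selection_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel severity labels over the masked area.

    ``feature_raster`` is (rows, cols, k); ``selection_idx`` restricts to the
    selected feature planes.  Returns an int raster with -1 outside the mask
    or where features are not finite.
    """
    if feature_raster.ndim != 3:
        raise ValueError("feature raster must be (rows, cols, k)")
    if mask.shape != feature_raster.shape[:2]:
        raise ValueError("mask shape does not match the feature raster")
    feats = feature_raster
    if selection_idx is not None:
        selection_idx = np.asarray(selection_idx, dtype=int)
        if selection_idx.max(initial=-1) >= feats.shape[2]:
            raise ValueError("selection index beyond available feature planes")
        feats = feats[:, :, selection_idx]
    n_expected = getattr(model, "n_features_in_", feats.shape[2])
    if feats.shape[2] != n_expected:
        raise ValueError(
            f"model expects {n_expected} features, raster provides {feats.shape[2]}"
        )
    rows, cols, k = feats.shape
    flat = feats.reshape(-1, k)
    ok = mask.ravel() & np.all(np.isfinite(flat), axis=1)
    out = np.full(rows * cols, -1, dtype=int)
    if ok.any():
        out[ok] = model.predict(flat[ok])
    return out.reshape(rows, cols)
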