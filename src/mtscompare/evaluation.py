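"""Cross-validated case-control classification harness.

Every representation is scored the same way: 10-fold stratified
cross-validation repeated 10 times (100 test folds), a linear SVM with
C = 1 and inverse-probability class weights, outlier-robust sigmoidal
normalization fitted on each training fold, and out-of-sample balanced
accuracy (mean of sensitivity and specificity) per fold. The fold
assignments are a function of the seed alone, so every model compared
under the same scheme sees the identical 100 test folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

#: Normal-consistency constant: IQR / 1.349 estimates the SD of a Gaussian.
IQR_TO_SD = 1.349


@dataclass
class CVScheme:
    """Repeated stratified k-fold plan shared across compared models."""

    k: int = 10
    r: int = 10
    seed: int = 0

    @property
    def n_folds(self) -> int:
        return self.k * self.r

    def splits(self, y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Deterministic (train, test) index pairs for a label vector."""
        cv = RepeatedStratifiedKFold(
            n_splits=self.k, n_repeats=self.r, random_state=self.seed
        )
        return list(cv.split(np.zeros((len(y), 1)), y))

    def test_train_ratio(self) -> float:
        """Realized mean test/train size ratio (1/(k-1) for k-fold)."""
        return 1.0 / (self.k - 1)


@dataclass
class ClassifierSpec:
    """Linear maximum-margin classifier settings."""

    C: float = 1.0
    class_weighting: str = "inverse_frequency"

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("C must be positive")
        if self.class_weighting not in {"inverse_frequency", "none"}:
            raise ValueError("class_weighting must be inverse_frequency or none")

    def make(self) -> SVC:
        return SVC(
            kernel="linear",
            C=self.C,
            class_weight=(
                "balanced" if self.class_weighting == "inverse_frequency" else None
            ),
        )


@dataclass
class CVResult:
    """Per-fold out-of-sample metrics for one model under one scheme."""

    balanced_accuracies: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    kind: str
    unit_id: str
    scheme: CVScheme
    fold_assignments: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(self.balanced_accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.balanced_accuracies.std(ddof=1))


class RobustSigmoidScaler:
    """Scaled outlier-robust sigmoidal normalization, fit per column.

    y = 1 / (1 + exp(-(x - median) / (IQR / 1.349))), linearly rescaled so
    the transformed *training* values span [0, 1]. Columns whose training
    IQR is zero fall back to a mean/SD sigmoid; fully constant training
    columns map everything to 0.5. Test values are transformed with the
    fitted parameters and are not clipped, preserving monotonicity in the
    tails.
    """

    def fit(self, x_train: np.ndarray) -> "RobustSigmoidScaler":
        x = np.asarray(x_train, dtype=float)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("training matrix must be non-empty and 2-d")
        q25, self.center_, q75 = np.percentile(x, [25, 50, 75], axis=0)
        scale = (q75 - q25) / IQR_TO_SD
        sd = x.std(axis=0, ddof=0)
        fallback = scale <= 0
        scale = np.where(fallback, sd, scale)
        self.center_ = np.where(fallback, x.mean(axis=0), self.center_)
        self.constant_ = scale <= 0
        self.scale_ = np.where(self.constant_, 1.0, scale)
        ytr = self._sigmoid(x)
        self.ymin_ = ytr.min(axis=0)
        self.yspan_ = ytr.max(axis=0) - self.ymin_
        self.degenerate_ = self.constant_ | (self.yspan_ <= 0)
        self.yspan_ = np.where(self.degenerate_, 1.0, self.yspan_)
        return self

    def _sigmoid(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(x - self.center_) / self.scale_))

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = (self._sigmoid(x) - self.ymin_) / self.yspan_
        return np.where(self.degenerate_, 0.5, y)

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def balanced_accuracy(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Mean of sensitivity and specificity for binary labels (1 = case)."""
    sens, spec = sensitivity_specificity(truth, predicted)
    return (sens + spec) / 2.0


def sensitivity_specificity(
    truth: np.ndarray, predicted: np.ndarray
) -> tuple[float, float]:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    pos = truth == 1
    neg = truth == 0
    if not pos.any() or not neg.any():
        raise ValueError("truth must contain both classes")
    sens = float(np.mean(predicted[pos] == 1))
    spec = float(np.mean(predicted[neg] == 0))
    return sens, spec


def impute_train_median(
    x_train: np.ndarray, x_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing cells with the training-fold column median (0 if a
    column is entirely missing in the training fold)."""
    med = np.nanmedian(x_train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    xtr = np.where(np.isfinite(x_train), x_train, med)
    xte = np.where(np.isfinite(x_test), x_test, med)
    return xtr, xte


def fit_fold(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    spec: ClassifierSpec,
    has_missing: bool = True,
):
    """One fold of the pipeline: impute, normalize, fit, predict.

    All fitted components see training rows only. Returns the fitted
    classifier and its test predictions. ``has_missing=False`` skips the
    imputation pass when the caller knows the matrix is complete.
    """
    if has_missing:
        xtr, xte = impute_train_median(x_train, x_test)
    else:
        xtr, xte = x_train, x_test
    scaler = RobustSigmoidScaler().fit(xtr)
    clf = spec.make()
    clf.fit(scaler.transform(xtr), y_train)
    return clf, clf.predict(scaler.transform(xte))


def run_repeated_cv(
    X, y: np.ndarray, scheme: CVScheme, spec: ClassifierSpec | None = None
) -> CVResult:
    """Repeated stratified k-fold evaluation of one design matrix.

    ``X`` is a DesignMatrix or a plain 2-d array. Returns k*r balanced
    accuracies with per-fold sensitivity and specificity.
    """
    spec = spec or ClassifierSpec()
    mat = X.X if hasattr(X, "X") else np.asarray(X, dtype=float)
    kind = getattr(X, "kind", "array")
    unit = getattr(X, "unit_id", "")
    y = np.asarray(y)
    if mat.shape[0] != len(y):
        raise ValueError("X and y are misaligned")
    if mat.shape[0] < 2 * scheme.k:
        raise ValueError("fewer than 2 participants per fold on average")
    splits = scheme.splits(y)
    has_missing = bool(np.isnan(mat).any())
    bacc = np.empty(len(splits))
    sens = np.empty(len(splits))
    spcf = np.empty(len(splits))
    assignments = []
    for f, (tr, te) in enumerate(splits):
        _, pred = fit_fold(mat[tr], y[tr], mat[te], spec, has_missing)
        s, p = sensitivity_specificity(y[te], pred)
        sens[f], spcf[f] = s, p
        bacc[f] = (s + p) / 2.0
        assignments.append(te)
    return CVResult(
        balanced_accuracies=bacc,
        sensitivities=sens,
        specificities=spcf,
        kind=kind,
        unit_id=unit,
        scheme=scheme,
        fold_assignments=assignments,
    )
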