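"""Fold-wise model selection within a representation family, and PCA.

For families with more samples than variables (regions, features), the
unit with the best in-sample (resubstitution) training balanced accuracy
is chosen independently in every fold, and its out-of-sample accuracy
retained; ties contribute the mean of the tied units' test accuracies.
High-dimensional coupling families would tie at 100% training accuracy,
so their per-fold selection instead scores each SPI in a 10-component PCA
subspace fitted on the training rows, then evaluates the winner in its
full variable space. Selection never sees test labels or test rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .evaluation import (
    ClassifierSpec,
    CVScheme,
    RobustSigmoidScaler,
    balanced_accuracy,
    fit_fold,
    impute_train_median,
)
from .representations import DesignMatrix

#: Training accuracies within this tolerance count as tied.
TIE_TOL = 1e-12


@dataclass
class SelectionResult:
    """Per-fold winning unit(s) and their out-of-sample accuracy."""

    chosen_units: list[list[str]]
    test_accuracies: np.ndarray
    kind: str
    scheme: CVScheme

    @property
    def mean(self) -> float:
        return float(self.test_accuracies.mean())

    def selection_frequency(self, unit_id: str) -> float:
        """Fraction of folds in which ``unit_id`` was among the winners."""
        hits = sum(unit_id in units for units in self.chosen_units)
        return hits / len(self.chosen_units)


def _fold_metrics(x, y, tr, te, spec):
    """Training (resubstitution) and test balanced accuracy for one fold."""
    xtr, xte = impute_train_median(x[tr], x[te])
    scaler = RobustSigmoidScaler().fit(xtr)
    clf = spec.make()
    ztr = scaler.transform(xtr)
    clf.fit(ztr, y[tr])
    train_acc = balanced_accuracy(y[tr], clf.predict(ztr))
    test_acc = balanced_accuracy(y[te], clf.predict(scaler.transform(xte)))
    return train_acc, test_acc


def select_best_by_training(
    family: list[DesignMatrix],
    y: np.ndarray,
    scheme: CVScheme,
    spec: ClassifierSpec | None = None,
) -> SelectionResult:
    """Per fold, keep the unit with the best training balanced accuracy."""
    if not family:
        raise ValueError("empty model family")
    spec = spec or ClassifierSpec()
    y = np.asarray(y)
    splits = scheme.splits(y)
    chosen: list[list[str]] = []
    test_accs = np.empty(len(splits))
    for f, (tr, te) in enumerate(splits):
        train_scores = np.empty(len(family))
        fold_tests = np.empty(len(family))
        for u, dm in enumerate(family):
            train_scores[u], fold_tests[u] = _fold_metrics(dm.X, y, tr, te, spec)
        best = train_scores.max()
        winners = np.flatnonzero(train_scores >= best - TIE_TOL)
        chosen.append([family[u].unit_id for u in winners])
        test_accs[f] = fold_tests[winners].mean()
    return SelectionResult(
        chosen_units=chosen,
        test_accuracies=test_accs,
        kind=family[0].kind,
        scheme=scheme,
    )


def select_best_spi_by_pca(
    family: list[DesignMatrix],
    y: np.ndarray,
    scheme: CVScheme,
    spec: ClassifierSpec | None = None,
    n_pcs: int = 10,
) -> SelectionResult:
    """Per fold, rank SPIs by training accuracy in a PCA subspace.

    For each SPI the training rows are imputed, sigmoid-normalized and
    projected onto their first ``n_pcs`` principal components; the SPI
    with the best training balanced accuracy in that subspace wins and is
    re-evaluated on the fold in its full variable space. Ties contribute
    the mean of the tied SPIs' full-space test accuracies.
    """
    if not family:
        raise ValueError("empty model family")
    spec = spec or ClassifierSpec()
    y = np.asarray(y)
    for dm in family:
        if dm.n_columns < n_pcs:
            raise ValueError(
                f"{dm.unit_id!r} has {dm.n_columns} columns < n_pcs={n_pcs}"
            )
    splits = scheme.splits(y)
    chosen: list[list[str]] = []
    test_accs = np.empty(len(splits))
    for f, (tr, te) in enumerate(splits):
        train_scores = np.empty(len(family))
        for u, dm in enumerate(family):
            xtr, _ = impute_train_median(dm.X[tr], dm.X[te])
            ztr = RobustSigmoidScaler().fit_transform(xtr)
            pcs = PCA(n_components=n_pcs).fit_transform(ztr)
            clf = spec.make()
            clf.fit(pcs, y[tr])
            train_scores[u] = balanced_accuracy(y[tr], clf.predict(pcs))
        best = train_scores.max()
        winners = np.flatnonzero(train_scores >= best - TIE_TOL)
        chosen.append([family[u].unit_id for u in winners])
        fold_tests = []
        for u in winners:
            _, pred = fit_fold(family[u].X[tr], y[tr], family[u].X[te], spec)
            fold_tests.append(balanced_accuracy(y[te], pred))
        test_accs[f] = float(np.mean(fold_tests))
    return SelectionResult(
        chosen_units=chosen,
        test_accuracies=test_accs,
        kind=family[0].kind,
        scheme=scheme,
    )


def pca_reduce(X: DesignMatrix, n_pcs: int = 25) -> DesignMatrix:
    """Project a design matrix onto its leading principal components.

    Pure PCA (centering only): normalization, when wanted, is the
    caller's responsibility, and inside cross-validation the projection
    must be fitted on training rows only.
    """
    n_pcs = min(n_pcs, min(X.X.shape))
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(np.nan_to_num(X.X, nan=0.0))
    out = DesignMatrix(
        X=scores,
        column_names=[f"pc:{i + 1}|source:{X.kind}:{X.unit_id}" for i in range(n_pcs)],
        kind=X.kind,
        unit_id=X.unit_id,
        participant_ids=list(X.participant_ids),
    )
    out.explained_variance_ratio_ = pca.explained_variance_ratio_
    return out
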