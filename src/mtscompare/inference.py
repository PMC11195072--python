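"""Statistical inference for cross-validated classification results.

Chance-level calibration uses a permutation null: the full repeated-CV
harness is re-run under shuffled diagnostic labels, each run contributing
one null mean balanced accuracy. The null is summarized by a fitted
Gaussian (its first two moments), whose upper tail supplies one-tailed
p-values far smaller than a raw permutation count could resolve.
Families of models are corrected with the Benjamini-Hochberg step-up.
Paired model comparisons over the shared 100 folds use the corrected
resampled t-test, which inflates the variance term to account for
overlapping training sets in repeated k-fold CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .evaluation import ClassifierSpec, CVResult, CVScheme, run_repeated_cv


@dataclass
class NullDistribution:
    """Permutation-null samples of mean balanced accuracy, plus Gaussian fit."""

    samples: np.ndarray
    mu: float
    sigma: float
    n_perm: int
    seed: int

    @classmethod
    def from_samples(cls, samples: np.ndarray, seed: int) -> "NullDistribution":
        samples = np.asarray(samples, dtype=float)
        return cls(
            samples=samples,
            mu=float(samples.mean()),
            sigma=float(samples.std(ddof=1)),
            n_perm=len(samples),
            seed=seed,
        )


@dataclass
class ComparisonResult:
    """Corrected resampled t-test outcome for a paired model comparison."""

    t_corr: float
    df: int
    p_two_tailed: float
    k: int
    r: int
    test_train_ratio: float


@dataclass
class SimilarityMatrix:
    """Absolute Spearman correlations between items over matched values."""

    rho_abs: np.ndarray
    item_names: list[str]


def permutation_null(
    X,
    y: np.ndarray,
    scheme: CVScheme,
    spec: ClassifierSpec | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of mean balanced accuracy under label shuffling.

    Each of the ``n_perm`` permutations re-runs the identical repeated-CV
    procedure (same scheme seed, hence comparable fold structure) on a
    shuffled copy of the labels and records the mean of its k*r balanced
    accuracies. Fully deterministic given ``seed``.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate")
    rng = np.random.default_rng(seed)
    spec = spec or ClassifierSpec()
    samples = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        samples[i] = run_repeated_cv(X, y_perm, scheme, spec).mean
    return NullDistribution.from_samples(samples, seed)


def gaussian_tail_pvalue(observed: float, null: NullDistribution) -> float:
    """One-tailed p: probability of a null mean >= observed under the
    fitted Gaussian."""
    if null.sigma <= 0:
        raise ValueError("null SD must be positive")
    return float(stats.norm.sf((observed - null.mu) / null.sigma))


def bh_adjust(pvalues: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the family size; by default the number of p-values supplied.
    An explicit larger ``m`` treats the unsupplied tests as nonsignificant.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    m = n if m is None else int(m)
    if m < n:
        raise ValueError("family size m cannot be smaller than len(pvalues)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def corrected_resampled_ttest(a: CVResult, b: CVResult) -> ComparisonResult:
    """Corrected two-tailed t-test over the shared k*r fold accuracies.

    t = mean(d) / sqrt((1/(k*r) + n2/n1) * var(d)), where d are the
    paired fold differences and n2/n1 the mean test/train size ratio;
    the extra n2/n1 term widens the denominator to compensate for the
    dependence induced by overlapping training sets. df = k*r - 1.
    """
    sa, sb = a.scheme, b.scheme
    if (sa.k, sa.r, sa.seed) != (sb.k, sb.r, sb.seed):
        raise ValueError("results were produced under different CV schemes")
    d = a.balanced_accuracies - b.balanced_accuracies
    n = d.size
    ratio = sa.test_train_ratio()
    var = d.var(ddof=1)
    if var == 0:
        t = 0.0
    else:
        t = float(d.mean() / np.sqrt((1.0 / n + ratio) * var))
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df)) if var > 0 else 1.0
    return ComparisonResult(
        t_corr=t, df=df, p_two_tailed=p, k=sa.k, r=sa.r, test_train_ratio=ratio
    )


def similarity_index(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """|Spearman rho| between two items' values over matched observations
    (units x participants, concatenated)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    mask = np.isfinite(a) & np.isfinite(b)
    rho = stats.spearmanr(a[mask], b[mask]).statistic
    return float(abs(rho))


def similarity_matrix(values: dict[str, np.ndarray]) -> SimilarityMatrix:
    """Pairwise |Spearman rho| between named items (features or SPIs)."""
    names = list(values)
    m = len(names)
    rho = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            rho[i, j] = rho[j, i] = similarity_index(
                values[names[i]], values[names[j]]
            )
    return SimilarityMatrix(rho_abs=rho, item_names=names)
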