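"""PCA + leave-one-out nearest-neighbour discrimination.

The classifier mirrors the standard chemometric recipe: mean-centre the
descriptor matrix, take the top-k eigenvectors of its covariance as
principal components, and score a held-out cell by the class of its
Euclidean nearest neighbour in PC-score space. Leave-one-out
cross-validation refits the PCA for every held-out cell, tallies
predictions into a confusion matrix, and pairwise sensitivity and
specificity are read off the matrix:

for an ordered class pair (A, B), with N(X -> Y) the count of class-X
cells predicted as Y,

    sensitivity(A vs B) = N(A->A) / (N(A->A) + N(B->A))
    specificity(A vs B) = N(B->B) / (N(B->B) + N(A->B))

Reported percentages are rounded half-up to one decimal; the printed
"Average" rows are the unweighted means of the *rounded* pairwise
values, again rounded half-up — exact decimal arithmetic throughout the
reporting layer so printed tables are reproduced digit for digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "LabeledDataset",
    "PCAModel",
    "ConfusionMatrix",
    "PairwiseMetrics",
    "DEFAULT_PCS",
    "fit_pca",
    "project",
    "loocv_nn",
    "pairwise_metrics",
    "run_modality",
    "round_half_up",
]

DEFAULT_PCS = {
    "RAMAN": 10,
    "HIST": 10,
    "TEXTURE4": 3,
    "TEXTURE16": 10,
    "HIST+TEXTURE4": 10,
    "HIST+TEXTURE": 10,
    "RAMAN+HIST": 10,
}


@dataclass(frozen=True)
class LabeledDataset:
    """Descriptor matrix with per-row class labels.

    ``classes`` fixes the class order for confusion matrices; by default
    it is the order of first appearance in ``y``.
    """

    X: np.ndarray
    y: tuple[str, ...]
    provenance: str = ""
    classes: tuple[str, ...] = ()

    def __post_init__(self):
        x = np.asarray(self.X, dtype=float)
        y = tuple(self.y)
        if x.ndim != 2 or x.shape[0] != len(y):
            raise ValueError("X must be 2D with one row per label")
        if not np.all(np.isfinite(x)):
            raise ValueError("X contains non-finite entries")
        classes = self.classes or tuple(dict.fromkeys(y))
        if x.shape[0] < len(classes) + 1:
            raise ValueError("need at least n_classes + 1 rows")
        object.__setattr__(self, "X", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "classes", tuple(classes))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # k x d, row-orthonormal
    eigenvalues: np.ndarray  # top-k covariance eigenvalues, descending
    variance_fraction: float


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer class-by-class counts; rows = actual, cols = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("counts must be square and match the class list")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class PairwiseMetrics:
    """Sensitivity/specificity (%) per unordered class pair, plus averages.

    ``pairs`` maps (A, B) to dicts with raw and 1-decimal-rounded
    values; undefined metrics (empty denominator) are NaN.
    """

    pairs: dict = field(default_factory=dict)
    average_sensitivity_pct: float = float("nan")
    average_specificity_pct: float = float("nan")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the convention of printed clinical tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """Top-k principal components of a data matrix.

    Mean-centred SVD route; covariance eigenvalues are s^2/(n-1).
    Component signs are fixed by making the largest-magnitude loading of
    each component positive, so the fit is fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k={k} must satisfy 1 <= k <= min(n-1, d) = {min(n - 1, d)}")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    components = vt[:k].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    total = eigenvalues.sum()
    fraction = float(eigenvalues[:k].sum() / total) if total > 0 else 1.0
    return PCAModel(
        mean=mean,
        components=components,
        eigenvalues=eigenvalues[:k].copy(),
        variance_fraction=fraction,
    )


def project(model: PCAModel, x: np.ndarray) -> np.ndarray:
    """Project vectors (or a matrix of rows) into PC-score space."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: got {x.shape[-1]}, model expects {model.mean.shape[0]}"
        )
    return (x - model.mean) @ model.components.T


def loocv_nn(data: LabeledDataset, k: int) -> ConfusionMatrix:
    """Leave-one-out nearest-neighbour classification in PC space.

    For each held-out row the PCA is refit on the remaining rows, all
    rows are projected, and the held-out cell takes the label of its
    Euclidean nearest training neighbour (ties -> smallest training-row
    index). Counts accumulate into a confusion matrix in class order.
    """
    n = data.n
    counts = np.array([data.y.count(c) for c in data.classes])
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 members for LOOCV")
    if not 1 <= k <= min(n - 2, data.d):
        raise ValueError(f"k={k} must satisfy 1 <= k <= min(n-2, d) = {min(n - 2, data.d)}")
    index = {c: i for i, c in enumerate(data.classes)}
    cm = np.zeros((len(data.classes), len(data.classes)), dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pca(data.X[mask], k)
        train_scores = project(model, data.X[mask])
        test_score = project(model, data.X[i])
        d2 = ((train_scores - test_score) ** 2).sum(axis=1)
        j = int(np.argmin(d2))  # first minimum == smallest training index
        predicted = [lbl for lbl, keep in zip(data.y, mask) if keep][j]
        cm[index[data.y[i]], index[predicted]] += 1
    return ConfusionMatrix(counts=cm, classes=data.classes)


def _ratio_pct(num: int, den: int):
    """Exact percentage as (raw float, half-up 1-decimal Decimal)."""
    if den == 0:
        return float("nan"), None
    exact = Decimal(num * 100) / Decimal(den)
    rounded = exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(exact), rounded


def pairwise_metrics(cm: ConfusionMatrix) -> PairwiseMetrics:
    """Pairwise sensitivity/specificity and their rounded-mean averages."""
    c = cm.counts
    pairs = {}
    rounded_sens, rounded_spec = [], []
    for i in range(len(cm.classes)):
        for j in range(i + 1, len(cm.classes)):
            sens_raw, sens_dec = _ratio_pct(int(c[i, i]), int(c[i, i] + c[j, i]))
            spec_raw, spec_dec = _ratio_pct(int(c[j, j]), int(c[j, j] + c[i, j]))
            pairs[(cm.classes[i], cm.classes[j])] = {
                "sensitivity_pct": float(sens_dec) if sens_dec is not None else sens_raw,
                "specificity_pct": float(spec_dec) if spec_dec is not None else spec_raw,
                "sensitivity_raw": sens_raw,
                "specificity_raw": spec_raw,
            }
            if sens_dec is not None:
                rounded_sens.append(sens_dec)
            if spec_dec is not None:
                rounded_spec.append(spec_dec)

    def _avg(vals):
        if not vals:
            return float("nan")
        mean = sum(vals) / Decimal(len(vals))
        return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    return PairwiseMetrics(
        pairs=pairs,
        average_sensitivity_pct=_avg(rounded_sens),
        average_specificity_pct=_avg(rounded_spec),
    )


def run_modality(
    data: LabeledDataset, modality: str | None = None, k: int | None = None
) -> tuple[ConfusionMatrix, PairwiseMetrics]:
    """End-to-end LOOCV for one descriptor family.

    ``k`` defaults per modality (10 PCs for spectra/histograms, 3 for
    the 4-value texture vector) and is additionally capped by the
    feature dimension and sample count only when defaulted — an explicit
    out-of-range ``k`` is an error.
    """
    modality = modality or data.provenance
    if k is None:
        k = DEFAULT_PCS.get(modality, 10)
        k = max(1, min(k, data.d, data.n - 2))
    cm = loocv_nn(data, k)
    return cm, pairwise_metrics(cm)
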