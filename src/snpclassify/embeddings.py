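"""Dimensionality reductions for genotype matrices.

Two projections are supported:

* **Truncated SVD.**  For a training matrix X (n samples x m variants, raw
  dosages, no centering) the basis U^k holds the top-k right singular vectors
  of X — equivalently the top-k left singular vectors of X^T — and the
  embedded data is X' = X U^k.
* **Per-class histogram.**  Each variant is described, per class, by the
  training-set proportions of dosage 0, 1 and 2 in that class, giving an
  m x 3c basis (78 columns for the 26 populations of a 1000 Genomes-style
  panel) used exactly like U^k.

Both are fit on training data only; applying them is a pure matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix, LabelSet

#: relative threshold below which trailing singular values count as zero
_SV_RTOL = 1e-12


@dataclass
class SVDProjection:
    """Orthonormal projection basis from a truncated SVD.

    ``basis`` is m x k with orthonormal columns ordered by decreasing singular
    value; the sign of each column is fixed so its largest-magnitude entry is
    positive, which makes fits reproducible (SVD signs are otherwise
    arbitrary).
    """

    basis: np.ndarray
    singular_values: np.ndarray
    k: int
    fitted_on_variant_ids: list[str]

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.basis.shape[1] != self.k or self.singular_values.shape != (self.k,):
            raise ValueError("basis/singular_values inconsistent with k")
        if np.any(np.diff(self.singular_values) > 0):
            raise ValueError("singular values must be nonincreasing")
        if np.any(self.singular_values <= 0):
            raise ValueError("singular values must be positive")
        gram = self.basis.T @ self.basis
        if np.abs(gram - np.eye(self.k)).max() > 1e-8:
            raise ValueError("basis columns are not orthonormal")


@dataclass
class ClassHistogramEmbedding:
    """Per-class genotype-proportion basis (m x 3c).

    Column order is class-major: for class index c the columns 3c, 3c+1,
    3c+2 hold the proportions of dosage 0, 1, 2.  Each class's triplet sums
    to 1 in every row.
    """

    basis: np.ndarray
    classes: list[str]
    fitted_on_variant_ids: list[str]

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        c = len(self.classes)
        if self.basis.shape[1] != 3 * c:
            raise ValueError(f"basis must have 3c = {3 * c} columns")
        if self.basis.min() < 0 or self.basis.max() > 1:
            raise ValueError("proportions must lie in [0, 1]")
        triplet_sums = self.basis.reshape(self.basis.shape[0], c, 3).sum(axis=2)
        if np.abs(triplet_sums - 1.0).max() > 1e-12:
            raise ValueError("per-class genotype proportions must sum to 1")


def fit_svd(X_train: GenotypeMatrix, k: int) -> SVDProjection:
    """Top-k right singular vectors of the raw training dosage matrix.

    No centering or scaling is applied.  Raises if ``k`` exceeds the rank
    bound min(n, m) or if the k-th singular value is numerically zero
    (relative to the largest), in which case a smaller k should be used.
    """
    n, m = X_train.values.shape
    if not (1 <= k <= min(n, m)):
        raise ValueError(f"k must be in [1, {min(n, m)}], got {k}")
    A = X_train.values.astype(float)
    if not A.any():
        raise ValueError("cannot fit SVD on an all-zero matrix")
    # economy SVD of the n x m matrix: rows of Vt are right singular vectors
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    if s[k - 1] < _SV_RTOL * s[0]:
        raise ValueError(
            f"singular value {k} is numerically zero "
            f"(sigma_k/sigma_1 = {s[k - 1] / s[0]:.2e}); use a smaller k"
        )
    basis = vt[:k].T.copy()
    # sign convention: largest-magnitude entry of each column positive
    for j in range(k):
        col = basis[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            basis[:, j] = -col
    return SVDProjection(
        basis=basis,
        singular_values=s[:k].copy(),
        k=k,
        fitted_on_variant_ids=list(X_train.variant_ids),
    )


def fit_class_histogram(X_train: GenotypeMatrix, labels: LabelSet) -> ClassHistogramEmbedding:
    """Per-(variant, class) genotype-value proportions over the training set."""
    y = labels.indices(X_train.sample_ids)
    m = X_train.n_variants
    c = labels.n_classes
    basis = np.zeros((m, 3 * c))
    for ci in range(c):
        members = X_train.values[y == ci]
        if members.shape[0] == 0:
            raise ValueError(f"class {labels.classes[ci]!r} has no training samples")
        for g in (0, 1, 2):
            basis[:, 3 * ci + g] = (members == g).mean(axis=0)
    return ClassHistogramEmbedding(
        basis=basis,
        classes=list(labels.classes),
        fitted_on_variant_ids=list(X_train.variant_ids),
    )


def project(
    X: GenotypeMatrix, embedding: SVDProjection | ClassHistogramEmbedding
) -> np.ndarray:
    """Embed a genotype matrix: X' = X . basis (no re-fitting).

    The variant columns of ``X`` must match the variants the embedding was
    fitted on, in the same order.
    """
    fitted = embedding.fitted_on_variant_ids
    if X.variant_ids != fitted:
        if len(X.variant_ids) != len(fitted):
            raise ValueError(
                f"variant count mismatch: matrix has {len(X.variant_ids)}, "
                f"embedding was fitted on {len(fitted)}"
            )
        pos = next(i for i, (a, b) in enumerate(zip(X.variant_ids, fitted)) if a != b)
        raise ValueError(
            f"variant mismatch at position {pos}: matrix has {X.variant_ids[pos]!r}, "
            f"embedding was fitted on {fitted[pos]!r}"
        )
    return X.values.astype(float) @ embedding.basis
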