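"""Reference-anchored (uncentered) principal component analysis of fold matrices.

The second-moment matrix is taken about e_fold = 0 — the geometric-mean
normal reference — rather than about the sample mean:

    sigma_ij = sum_s e_fold_i(s) e_fold_j(s) / (N_samples - 1)

so PC1 points from the normal attractor towards the dominant direction of
departure, which in normal/tumor cohorts is the cancer axis. The gene-by-gene
sigma (60,483² at TCGA scale) is never materialized: sigma = F Fᵀ/(N−1) for
the G×N fold matrix F, and its leading eigenpairs come from the economy SVD
of F (left singular vectors; eigenvalues are squared singular values over
N−1). Projections x_m = e_fold · v_m are the sample coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SampleTable, ValidationError
from .preprocess import FoldMatrix

DENSE_GENE_CAP = 5_000
DEFAULT_K = 100


@dataclass(frozen=True)
class CovarianceOperator:
    """Matrix-free form of the uncentered covariance sigma = F Fᵀ / (N−1)."""

    fold: pd.DataFrame  # genes x samples
    dense_cap: int = DENSE_GENE_CAP

    def __post_init__(self) -> None:
        if self.fold.shape[1] < 2:
            raise ValidationError(
                f"covariance needs at least 2 samples, got {self.fold.shape[1]}"
            )

    @property
    def n_genes(self) -> int:
        return self.fold.shape[0]

    @property
    def n_samples(self) -> int:
        return self.fold.shape[1]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """sigma @ x without forming sigma."""
        F = self.fold.to_numpy()
        return F @ (F.T @ x) / (self.n_samples - 1)

    def dense(self) -> np.ndarray:
        """Materialize sigma; refused above ``dense_cap`` genes."""
        if self.n_genes > self.dense_cap:
            raise ValidationError(
                f"refusing to materialize {self.n_genes}x{self.n_genes} covariance "
                f"(cap {self.dense_cap})"
            )
        F = self.fold.to_numpy()
        return F @ F.T / (self.n_samples - 1)

    @property
    def total_variance(self) -> float:
        """Exact trace of sigma: sum of squared folds over N−1."""
        F = self.fold.to_numpy()
        return float((F**2).sum() / (self.n_samples - 1))


@dataclass(frozen=True)
class RefPCAModel:
    """Leading eigenpairs of the reference-anchored covariance."""

    eigenvalues: np.ndarray  # (k,), nonincreasing, >= 0
    eigenvectors: pd.DataFrame  # genes x k, orthonormal columns, labelled PC1..PCk
    total_variance: float  # trace of sigma, not the partial eigenvalue sum
    n_samples: int
    orientation: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    @property
    def variance_fractions(self) -> np.ndarray:
        if self.total_variance == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance

    @property
    def v1(self) -> pd.Series:
        return self.eigenvectors["PC1"]


@dataclass(frozen=True)
class ProjectionTable:
    """Sample coordinates x_1..x_k along the PC axes (condition optional)."""

    data: pd.DataFrame  # index sample_id; columns PC1..PCk [+ condition]

    def coordinate(self, component: int = 1) -> pd.Series:
        return self.data[f"PC{component}"]


def covariance_factor(f: FoldMatrix, dense_cap: int = DENSE_GENE_CAP) -> CovarianceOperator:
    return CovarianceOperator(f.data, dense_cap=dense_cap)


def _fix_component_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude loading of each column is positive."""
    out = vecs.copy()
    for m in range(out.shape[1]):
        col = out[:, m]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, m] = -col
    return out


def top_components(op: CovarianceOperator, k: int | None = None) -> RefPCAModel:
    """Leading k eigenpairs of sigma via economy SVD of the fold factor.

    k defaults to min(100, N_samples). The total variance reported is the
    exact trace of sigma, so variance fractions refer to all of the variance
    in the data, not merely the computed subspace.
    """
    n = op.n_samples
    if k is None:
        k = min(DEFAULT_K, n)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}] (uncentered rank bound), got {k}")
    F = op.fold.to_numpy()
    U, s, _ = np.linalg.svd(F, full_matrices=False)
    eigenvalues = (s**2) / (n - 1)
    # sigma has at most min(G, N) eigenpairs
    order = np.argsort(eigenvalues)[::-1][: min(k, op.n_genes)]
    eigenvalues = eigenvalues[order]
    vecs = _fix_component_signs(U[:, order])
    eigenvectors = pd.DataFrame(
        vecs, index=op.fold.index, columns=[f"PC{m + 1}" for m in range(vecs.shape[1])]
    )
    return RefPCAModel(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        total_variance=op.total_variance,
        n_samples=n,
    )


def project(
    f: FoldMatrix, model: RefPCAModel, samples: SampleTable | None = None
) -> ProjectionTable:
    """x_m(s) = e_fold(s) · v_m for every sample and computed component."""
    if list(f.data.index) != list(model.eigenvectors.index):
        raise ValidationError("gene order of fold matrix and model disagree")
    coords = f.data.to_numpy().T @ model.eigenvectors.to_numpy()
    out = pd.DataFrame(coords, index=f.data.columns, columns=model.eigenvectors.columns)
    if samples is not None:
        out["condition"] = samples.data.loc[out.index, "condition"]
    return ProjectionTable(out)


def orient(model: RefPCAModel, f: FoldMatrix, samples: SampleTable) -> RefPCAModel:
    """Fix the arbitrary sign of v_1 so tumors project to the positive side.

    Higher components keep the deterministic largest-loading-positive rule.
    With only one condition present the orientation is left unfixed and
    flagged in ``model.orientation``.
    """
    normals = [s for s in samples.normals if s in f.data.columns]
    tumors = [s for s in samples.tumors if s in f.data.columns]
    if not normals or not tumors:
        return replace(model, orientation={"fixed": False, "reason": "single condition"})
    x1 = f.data[normals + tumors].to_numpy().T @ model.v1.to_numpy()
    mean_t = x1[len(normals):].mean()
    mean_n = x1[: len(normals)].mean()
    flipped = bool(mean_t < mean_n)
    vecs = model.eigenvectors.copy()
    if flipped:
        vecs["PC1"] = -vecs["PC1"]
    return replace(
        model,
        eigenvectors=vecs,
        orientation={"fixed": True, "pc1_flipped": flipped, "rule": "tumor-positive"},
    )


def cumulative_variance(model: RefPCAModel, n: int) -> float:
    """Fraction of total variance captured by the first n components."""
    if n > model.k:
        raise ValidationError(f"n={n} exceeds computed components k={model.k}")
    if model.total_variance == 0:
        return 0.0
    return float(model.eigenvalues[:n].sum() / model.total_variance)
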