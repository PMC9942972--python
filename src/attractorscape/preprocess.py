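"""Normalization chain: pseudocount regularization, geometric-mean normal
reference, differential expression and log2 fold variation.

The chain is fixed: ``regularize`` (add 0.1 FPKM to every value) →
``geometric_reference`` (per-gene geometric mean over normal samples) →
``fold_matrix`` (e_fold = log2(e / e_ref)). The geometric mean is taken on
regularized values, so a gene that is exactly zero in every sample has
e_diff = 1 and e_fold = 0 throughout — such genes carry no weight in the
downstream principal-component analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_EPSILON, ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class ReferenceVector:
    """Strictly positive per-gene reference expression, with provenance."""

    values: pd.Series  # index: gene_id
    provenance: str = ""

    def __post_init__(self) -> None:
        if (self.values <= 0).any() or not np.isfinite(self.values).all():
            bad = self.values.index[~(self.values > 0) | ~np.isfinite(self.values)][0]
            raise ValidationError(f"reference must be strictly positive; gene {bad!r} is not")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class FoldMatrix:
    """Per-gene, per-sample log2 fold variation relative to a reference."""

    data: pd.DataFrame  # genes x samples, finite log2 units

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("fold matrix must be finite everywhere")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def regularize(m: ExpressionMatrix, epsilon: float = DEFAULT_EPSILON) -> ExpressionMatrix:
    """Add a small constant to every FPKM value so geometric means are defined.

    The default 0.1 doubles as a significance floor: genes expressed below it
    end up with differential expression ≈ 1 and thus negligible fold weight.
    """
    if epsilon <= 0:
        raise ValidationError(f"epsilon must be > 0, got {epsilon}")
    return ExpressionMatrix(m.data + epsilon)


def geometric_mean(data: pd.DataFrame, columns: Sequence[str]) -> pd.Series:
    """Per-row geometric mean over the given columns of a strictly positive frame."""
    cols = list(columns)
    if not cols:
        raise ValidationError("geometric mean over an empty sample set is undefined")
    sub = data.loc[:, cols].to_numpy()
    if (sub <= 0).any():
        raise ValidationError("geometric mean requires strictly positive values")
    gm = np.exp(np.log(sub).mean(axis=1))
    # a constant row's geometric mean is that constant, exactly: this keeps
    # the fold of regularized all-zero genes at an identical 0.0
    const = (sub == sub[:, :1]).all(axis=1)
    gm[const] = sub[const, 0]
    return pd.Series(gm, index=data.index)


def geometric_reference(
    m: ExpressionMatrix, normals: Sequence[str], provenance: str = "normal samples"
) -> ReferenceVector:
    """Per-gene geometric mean of (regularized) expression over normal samples."""
    return ReferenceVector(geometric_mean(m.data, normals), provenance=provenance)


def fold_matrix(m: ExpressionMatrix, ref: ReferenceVector) -> FoldMatrix:
    """e_fold[i, s] = log2(e[i, s] / e_ref[i]); both inputs strictly positive."""
    missing = set(m.gene_ids) - set(ref.gene_ids)
    if missing:
        raise ValidationError(
            f"{len(missing)} gene(s) missing from reference, e.g. {sorted(missing)[0]!r}"
        )
    if (m.values <= 0).any():
        raise ValidationError("fold_matrix requires a regularized (strictly positive) matrix")
    ref_aligned = ref.values.loc[m.gene_ids]
    folds = np.log2(m.values / ref_aligned.to_numpy()[:, None])
    return FoldMatrix(pd.DataFrame(folds, index=m.data.index, columns=m.data.columns))


def fold_pipeline(
    m: ExpressionMatrix, normals: Sequence[str], epsilon: float = DEFAULT_EPSILON
) -> tuple[FoldMatrix, ReferenceVector]:
    """regularize → geometric_reference → fold_matrix, in fixed order."""
    reg = regularize(m, epsilon)
    ref = geometric_reference(reg, normals)
    return fold_matrix(reg, ref), ref
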