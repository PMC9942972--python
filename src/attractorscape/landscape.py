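"""The multi-tissue gene-expression landscape.

Each localization's normal and tumor sample clouds are reduced to their
geometric-mean centers; the common reference is the (geometric-mean) center
of the cloud of normal centers. Fold vectors of all 2T centers against that
common reference feed the same uncentered covariance used per tissue, giving
landscape principal components. Unlike single-tissue cohorts there is no
single cancer axis here — tissue differentiation dominates the leading
components — so the normal/tumor border is best seen in a plane combining a
leading and a later component (the (PC1, PC3) plane in the 15-localization
TCGA analysis, where PC1+PC2 carry ~37% and PC3 ~12% of the variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleTable, ValidationError
from .pca import RefPCAModel, covariance_factor, orient, project, top_components
from .preprocess import FoldMatrix, ReferenceVector, geometric_mean
from .profile import GeneProfile, rank_genes

CENTER_SEP = ":"


@dataclass(frozen=True)
class TissueSummary:
    """Geometric-mean normal and tumor centers of one localization (regularized units)."""

    tissue_code: str
    e_normal: pd.Series
    e_tumor: pd.Series

    def __post_init__(self) -> None:
        if not self.e_normal.index.equals(self.e_tumor.index):
            raise ValidationError(f"{self.tissue_code}: center gene universes differ")


@dataclass(frozen=True)
class LandscapeModel:
    """Common reference, center fold vectors and their uncentered PCA."""

    ref_all: ReferenceVector
    fold: FoldMatrix  # genes x (2T centers), columns "TISSUE:condition"
    model: RefPCAModel
    coords: pd.DataFrame  # per center: tissue_code, condition, PC1..PCk

    @property
    def n_tissues(self) -> int:
        return self.fold.data.shape[1] // 2


def tissue_centers(m: ExpressionMatrix, samples: SampleTable, tissue_code: str | None = None) -> TissueSummary:
    """Reduce one localization's clouds to normal and tumor centers.

    ``m`` must already be regularized (strictly positive).
    """
    normals, tumors = samples.normals, samples.tumors
    if not normals or not tumors:
        missing = "normal" if not normals else "tumor"
        raise ValidationError(f"no {missing} samples for tissue centers")
    if tissue_code is None:
        tissue_code = str(samples.data["tissue_code"].iloc[0])
    return TissueSummary(
        tissue_code,
        geometric_mean(m.data, normals),
        geometric_mean(m.data, tumors),
    )


def common_reference(
    summaries: Sequence[TissueSummary], method: str = "geometric"
) -> ReferenceVector:
    """Center of the cloud of normal centers, shared by all tissues.

    Geometric mean by default (consistent with every other average in the
    pipeline, and it makes the mean log-fold of the normal centers exactly
    zero); ``method="arithmetic"`` is available for sensitivity analysis.
    """
    if len(summaries) < 2:
        raise ValidationError("common reference needs >= 2 tissues")
    universe = summaries[0].e_normal.index
    for s in summaries[1:]:
        if not s.e_normal.index.equals(universe):
            extra = set(s.e_normal.index).symmetric_difference(universe)
            raise ValidationError(
                f"tissue {s.tissue_code} gene universe differs by {len(extra)} gene(s), "
                f"e.g. {sorted(extra)[0]!r}"
            )
    stack = np.vstack([s.e_normal.to_numpy() for s in summaries])
    if method == "geometric":
        ref = np.exp(np.log(stack).mean(axis=0))
    elif method == "arithmetic":
        ref = stack.mean(axis=0)
    else:
        raise ValidationError(f"unknown averaging method {method!r}")
    return ReferenceVector(
        pd.Series(ref, index=universe),
        provenance=f"{method} mean of {len(summaries)} normal centers",
    )


def landscape_pca(
    summaries: Sequence[TissueSummary],
    ref_all: ReferenceVector | None = None,
    k: int | None = None,
) -> LandscapeModel:
    """Uncentered PCA of the 2T tissue centers in fold space.

    Each center (tissue × condition) acts as one "sample" of the covariance;
    PC1 is oriented so tumor centers project positively.
    """
    if 2 * len(summaries) < 3:
        raise ValidationError("landscape needs >= 3 center points (>= 2 tissues)")
    if ref_all is None:
        ref_all = common_reference(summaries)
    cols, vecs, meta = [], [], []
    for s in summaries:
        for condition, center in (("normal", s.e_normal), ("tumor", s.e_tumor)):
            cols.append(f"{s.tissue_code}{CENTER_SEP}{condition}")
            vecs.append(np.log2(center.to_numpy() / ref_all.values.to_numpy()))
            meta.append((s.tissue_code, condition))
    fold = FoldMatrix(
        pd.DataFrame(np.column_stack(vecs), index=ref_all.values.index, columns=cols)
    )
    center_table = SampleTable(
        pd.DataFrame(
            {"tissue_code": [t for t, _ in meta], "condition": [c for _, c in meta]},
            index=pd.Index(cols, name="sample_id"),
        )
    )
    model = top_components(covariance_factor(fold), k=k)
    model = orient(model, fold, center_table)
    proj = project(fold, model, center_table)
    coords = proj.data.copy()
    coords.insert(0, "tissue_code", [t for t, _ in meta])
    return LandscapeModel(ref_all, fold, model, coords)


def landscape_plane(
    lm: LandscapeModel, axes: tuple[int, int] = (1, 3)
) -> pd.DataFrame:
    """Coordinates of every center in a chosen PC plane (default PC1 vs PC3)."""
    for a in axes:
        if a > lm.model.k:
            raise ValidationError(f"axis PC{a} beyond computed k={lm.model.k}")
    out = lm.coords[["tissue_code", "condition", f"PC{axes[0]}", f"PC{axes[1]}"]]
    return out.copy()


def landscape_top_genes(lm: LandscapeModel, axis: int = 1, n: int = 8) -> GeneProfile:
    """The n genes with the largest |loading| on a landscape axis, with signs."""
    if axis > lm.model.k:
        raise ValidationError(f"axis PC{axis} beyond computed k={lm.model.k}")
    profile = rank_genes(lm.model.eigenvectors[f"PC{axis}"])
    return GeneProfile(profile.table.head(n).reset_index(drop=True))


def tumor_fold_centers(lm: LandscapeModel) -> Mapping[str, pd.Series]:
    """Per-tissue tumor-center fold vectors against the common reference."""
    out: dict[str, pd.Series] = {}
    for col in lm.fold.data.columns:
        tissue, condition = col.split(CENTER_SEP)
        if condition == "tumor":
            out[tissue] = lm.fold.data[col]
    return out
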