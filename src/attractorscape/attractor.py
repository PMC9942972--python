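"""Attractor-state diagnostics: age-stratified expression distributions and
stage-stratified sample-density differences in the PC plane.

If the tumor cloud is an attractor, the average expression profile of
advanced tumors should not depend on how (or when) the trajectory entered
it: tumor samples from young and old patients should share essentially the
same over-expression tail, while among normal samples aging perturbs only a
handful of genes. A complementary view orders tumors by clinical stage and
maps the normal-minus-tumor sample density in the (PC1, PC2) plane: early
stages populate the transition region, late stages concentrate in the tumor
attractor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STAGES, ExpressionMatrix, SampleTable, ValidationError
from .pca import ProjectionTable
from .preprocess import geometric_mean

GROUPS = ("NY", "NO", "TY", "TO")


@dataclass(frozen=True)
class AgeGroups:
    """Normal/tumor × young/old split at the cohort's median age.

    Young means age < threshold; samples with missing age are excluded and
    counted in ``n_missing_age``.
    """

    threshold: float
    members: dict[str, list[str]]  # NY / NO / TY / TO -> sample ids
    n_missing_age: int
    degenerate: bool = False  # all ages equal -> everyone "old"

    @property
    def empty_groups(self) -> list[str]:
        return [g for g in GROUPS if not self.members[g]]


@dataclass(frozen=True)
class OverlapStatistic:
    jaccard: float
    max_abs_log2_ratio: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class DensityField:
    """rho_normal − rho_tumor on a shared (PC1, PC2) grid, unit-mass densities."""

    x: np.ndarray  # grid nodes along PC1
    y: np.ndarray  # grid nodes along PC2
    field: np.ndarray  # shape (len(y), len(x))
    bandwidths: tuple[float, float, float, float]  # (nx, ny, tx, ty)
    stage: str

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.field, self.x, axis=1), self.y))


def age_split(samples: SampleTable) -> AgeGroups:
    """Split samples at the median age of all samples with a known age."""
    data = samples.data
    known = data["age_years"].dropna()
    n_missing = len(data) - len(known)
    for condition in ("normal", "tumor"):
        if (data.loc[known.index, "condition"] == condition).sum() < 2:
            raise ValidationError(f"need >= 2 aged samples in condition {condition!r}")
    threshold = float(known.median())
    members: dict[str, list[str]] = {g: [] for g in GROUPS}
    for sid, age in known.items():
        key = ("N" if data.loc[sid, "condition"] == "normal" else "T") + (
            "Y" if age < threshold else "O"
        )
        members[key].append(sid)
    degenerate = known.nunique() == 1
    return AgeGroups(threshold, members, n_missing, degenerate=degenerate)


def group_distribution(
    m: ExpressionMatrix, groups: AgeGroups
) -> dict[str, pd.Series]:
    """Per-group average differential expression against the NY reference.

    For each subgroup the per-gene geometric mean of (regularized) expression
    is divided by the Normal-Young geometric mean; NY against itself is
    identically 1. Sorting a returned vector descending gives the integrated
    over-expression distribution curve.
    """
    if not groups.members["NY"]:
        raise ValidationError("NY subgroup is empty; reference undefined")
    ny_ref = geometric_mean(m.data, groups.members["NY"])
    out: dict[str, pd.Series] = {}
    for g in GROUPS:
        if not groups.members[g]:
            continue
        out[g] = geometric_mean(m.data, groups.members[g]) / ny_ref
    return out


def sorted_curve(e_diff: pd.Series) -> np.ndarray:
    """Integrated distribution curve: e_diff values sorted descending."""
    return np.sort(e_diff.to_numpy())[::-1]


def overlap_statistic(
    curve_a: pd.Series, curve_b: pd.Series, cut: float = 2.0
) -> OverlapStatistic:
    """Similarity of the over-expression tails of two e_diff vectors.

    Jaccard index of the gene sets above ``cut``, plus the largest |log2
    ratio| between the two vectors over the union of those sets. Two empty
    tails are identical (Jaccard 1).
    """
    common = curve_a.index.intersection(curve_b.index)
    if len(common) == 0:
        raise ValidationError("curves share no genes")
    a = set(common[curve_a.loc[common] > cut])
    b = set(common[curve_b.loc[common] > cut])
    union = a | b
    jaccard = 1.0 if not union else len(a & b) / len(union)
    if union:
        genes = sorted(union)
        ratios = np.log2(curve_a.loc[genes].to_numpy() / curve_b.loc[genes].to_numpy())
        max_ratio = float(np.abs(ratios).max())
    else:
        max_ratio = 0.0
    return OverlapStatistic(jaccard, max_ratio, len(a), len(b))


def _scott_bandwidth(values: np.ndarray) -> float:
    # per-axis Scott rule for a 2D product kernel; unit fallback for
    # zero-spread (point-mass) clouds
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    h = sd * len(values) ** (-1.0 / 6.0)
    return h if h > 0 else 1.0


def _product_kde(
    px: np.ndarray, py: np.ndarray, gx: np.ndarray, gy: np.ndarray, hx: float, hy: float
) -> np.ndarray:
    zx = (gx[None, :] - px[:, None]) / hx
    zy = (gy[None, :] - py[:, None]) / hy
    kx = np.exp(-0.5 * zx**2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * zy**2) / (hy * np.sqrt(2 * np.pi))
    # average of per-point product kernels, evaluated on the full grid
    return ky.T @ kx / len(px)


def stage_density_diff(
    proj: ProjectionTable,
    samples: SampleTable,
    stage: str,
    grid_size: int = 100,
    pad_fraction: float = 0.1,
) -> DensityField:
    """Normal-minus-tumor sample density for one tumor stage on a shared grid.

    All normal samples enter every stage panel; the tumor density uses only
    tumors of the requested stage. Each density is a unit-mass Gaussian
    product-kernel estimate (per-axis Scott bandwidth), so the field
    integrates to ~0 and its sign marks normal- versus tumor-dominated
    regions.
    """
    if stage not in STAGES:
        raise ValidationError(f"stage must be one of {STAGES}, got {stage!r}")
    meta = samples.data
    normals = [s for s in samples.normals if s in proj.data.index]
    tumors = [
        s
        for s in samples.tumors
        if s in proj.data.index and meta.loc[s, "stage"] == stage
    ]
    if len(normals) < 2:
        raise ValidationError("need >= 2 normal samples")
    if len(tumors) < 2:
        raise ValidationError(f"need >= 2 tumor samples at stage {stage}")
    pn = proj.data.loc[normals, ["PC1", "PC2"]].to_numpy()
    pt = proj.data.loc[tumors, ["PC1", "PC2"]].to_numpy()
    hnx, hny = _scott_bandwidth(pn[:, 0]), _scott_bandwidth(pn[:, 1])
    htx, hty = _scott_bandwidth(pt[:, 0]), _scott_bandwidth(pt[:, 1])
    allpts = np.vstack([pn, pt])
    grid = []
    for axis, h in ((0, max(hnx, htx)), (1, max(hny, hty))):
        lo, hi = allpts[:, axis].min(), allpts[:, axis].max()
        pad = max(pad_fraction * (hi - lo), 3.0 * h)
        grid.append(np.linspace(lo - pad, hi + pad, grid_size))
    gx, gy = grid
    rho_n = _product_kde(pn[:, 0], pn[:, 1], gx, gy, hnx, hny)
    rho_t = _product_kde(pt[:, 0], pt[:, 1], gx, gy, htx, hty)
    return DensityField(gx, gy, rho_n - rho_t, (hnx, hny, htx, hty), stage)


def stage_progression_summary(
    proj: ProjectionTable, samples: SampleTable
) -> pd.DataFrame:
    """Per-stage count, mean and standard deviation of the cancer-axis coordinate.

    Rows ordered I→IV; stages with no tumor samples are omitted. A positive
    trend in the means is the signature of progression along the cancer axis.
    """
    meta = samples.data
    tumors = [s for s in samples.tumors if s in proj.data.index]
    x1 = proj.coordinate(1)
    rows = []
    for stage in STAGES:
        members = [s for s in tumors if meta.loc[s, "stage"] == stage]
        if not members:
            continue
        vals = x1.loc[members].to_numpy()
        rows.append(
            {
                "stage": stage,
                "n": len(members),
                "mean_x1": float(vals.mean()),
                "sd_x1": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
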