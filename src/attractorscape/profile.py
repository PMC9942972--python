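"""Cancer gene-expression profiles: v_1 rankings, signed top-k gene sets,
integrated over/under-expression tail curves and Pareto (power-law) fits.

Each component v1_i of the unit cancer-axis eigenvector weights gene i in the
definition of the tumor state; a positive sign marks over-expression in
tumors, a negative sign under-expression. The integrated distribution
function of the tumor-cloud center counts, for each threshold x > 1, the
genes whose average differential expression exceeds x (over-expression tail)
or falls below 1/x (under-expression tail); in log-log coordinates these
tails are close to straight lines, i.e. Pareto-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignedGeneSet, ValidationError
from .preprocess import ReferenceVector, geometric_mean

UNIT_TOL = 1e-6
DEFAULT_TOP_K = 2_500
DEFAULT_THRESHOLDS = np.geomspace(1.2, 1000.0, 40)
DEFAULT_FIT_WINDOW = (2.0, 100.0)
MIN_FIT_COUNT = 10


@dataclass(frozen=True)
class GeneProfile:
    """Genes ranked by |weight| on the cancer axis, signs reported separately."""

    table: pd.DataFrame  # columns gene_id, weight, sign, rank; sorted by rank

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


@dataclass(frozen=True)
class TailCurve:
    """Integrated distribution function of a per-gene e_diff vector."""

    direction: str  # "over" | "under"
    thresholds: np.ndarray  # x > 1, increasing
    counts: np.ndarray  # nonincreasing gene counts

    def __post_init__(self) -> None:
        if self.direction not in ("over", "under"):
            raise ValidationError(f"direction must be 'over' or 'under', got {self.direction!r}")
        if np.any(np.diff(self.counts) > 0):
            raise ValidationError("tail counts must be nonincreasing in the threshold")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares log-log line through a tail curve: count ∝ x^(−alpha)."""

    alpha: float
    intercept: float  # log10 count at x = 1
    x_min: float
    x_max: float
    r_squared: float
    n_points: int


def rank_genes(v1: pd.Series) -> GeneProfile:
    """Stable descending sort of a unit eigenvector by |weight|.

    Ties are broken by lexicographic gene id so the ranking is deterministic
    and invariant under permutation of the input gene order.
    """
    norm = float(np.sqrt((v1**2).sum()))
    if abs(norm - 1.0) > UNIT_TOL:
        raise ValidationError(f"expected a unit vector, got norm {norm}")
    df = pd.DataFrame({"gene_id": v1.index.astype(str), "weight": v1.to_numpy()})
    df["sign"] = np.where(df["weight"] >= 0, 1, -1)
    df = df.sort_values(
        ["weight", "gene_id"], key=lambda c: -c.abs() if c.name == "weight" else c
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return GeneProfile(df)


def top_k_set(p: GeneProfile, k: int = DEFAULT_TOP_K) -> SignedGeneSet:
    """The k genes with the largest |v1_i|, annotated with their signs."""
    if k > len(p.table):
        raise ValidationError(f"k={k} exceeds the {len(p.table)}-gene universe")
    head = p.table.head(k)
    return SignedGeneSet(dict(zip(head["gene_id"], head["sign"].astype(int))))


def tumor_center(
    m: ExpressionMatrix, tumors: Sequence[str], ref: ReferenceVector
) -> pd.Series:
    """Per-gene average differential expression of the tumor-cloud center.

    Geometric mean of (regularized) expression over tumor samples, divided by
    the normal reference.
    """
    if not list(tumors):
        raise ValidationError("tumor center of an empty sample set is undefined")
    center = geometric_mean(m.data, tumors)
    return center / ref.values.loc[center.index]


def tail_curve(
    center: pd.Series,
    direction: str = "over",
    thresholds: np.ndarray | None = None,
) -> TailCurve:
    """Count genes beyond each threshold: e_diff > x (over) or <= 1/x (under).

    The under tail is inclusive at the boundary: a gene under-expressed by
    exactly the factor x counts as reaching that threshold.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 1) or np.any(np.diff(thresholds) <= 0):
        raise ValidationError("thresholds must be > 1 and strictly increasing")
    vals = center.to_numpy()
    if direction == "over":
        counts = (vals[None, :] > thresholds[:, None]).sum(axis=1)
    else:
        counts = (vals[None, :] <= 1.0 / thresholds[:, None]).sum(axis=1)
    return TailCurve(direction, thresholds, counts.astype(int))


def fit_power_tail(
    c: TailCurve,
    x_min: float = DEFAULT_FIT_WINDOW[0],
    x_max: float = DEFAULT_FIT_WINDOW[1],
    min_count: int = MIN_FIT_COUNT,
) -> PowerLawFit:
    """Fit log10(count) against log10(x) inside [x_min, x_max]; alpha = −slope.

    Only curve points with count ≥ ``min_count`` enter the fit (the far tail
    of a cumulative count is dominated by a handful of genes and would just
    add noise); at least 3 such points are required.
    """
    mask = (c.thresholds >= x_min) & (c.thresholds <= x_max) & (c.counts >= min_count)
    if mask.sum() < 3:
        raise ValidationError(
            f"need >= 3 points with count >= {min_count} in [{x_min}, {x_max}], "
            f"got {int(mask.sum())}"
        )
    lx = np.log10(c.thresholds[mask])
    ly = np.log10(c.counts[mask])
    res = stats.linregress(lx, ly)
    return PowerLawFit(
        alpha=float(-res.slope),
        intercept=float(res.intercept),
        x_min=float(c.thresholds[mask].min()),
        x_max=float(c.thresholds[mask].max()),
        r_squared=float(res.rvalue**2) if np.ptp(ly) > 0 else 1.0,
        n_points=int(mask.sum()),
    )


def expression_balance(center: pd.Series, cut: float = 2.0) -> tuple[int, int]:
    """(n_over, n_under): genes with e_diff > cut and e_diff <= 1/cut."""
    if cut <= 1:
        raise ValidationError(f"cut must be > 1, got {cut}")
    vals = center.to_numpy()
    return int((vals > cut).sum()), int((vals <= 1.0 / cut).sum())
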