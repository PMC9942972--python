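"""Cross-localization comparisons of cancer profiles.

Pairwise shared-gene counts between the signed top-k gene sets of different
tumor localizations, multi-way and pan-cancer intersections, Euclidean
distances between tumor centers in fold space, and the (inverse) relation
between distance and shared-gene count. Membership intersection ignores the
over/under sign by default — signs are reported per tissue, and a signed
mode requiring identical signs is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SignedGeneSet, ValidationError


@dataclass(frozen=True)
class SharedGeneTable:
    """Symmetric matrix of shared-gene counts over tissue codes."""

    counts: pd.DataFrame  # tissues x tissues, int
    shared: Mapping[tuple[str, str], list[str]]  # per unordered pair (sorted key)

    def pair(self, a: str, b: str) -> list[str]:
        return self.shared[tuple(sorted((a, b)))]


@dataclass(frozen=True)
class PanCancerResult:
    """Genes present in every input set, with per-tissue signs."""

    signs: pd.DataFrame  # genes x tissues, +1/-1
    consensus: dict[str, int]  # unanimous sign per gene (0 if discordant)

    @property
    def genes(self) -> list[str]:
        return list(self.signs.index)

    @property
    def discordant(self) -> list[str]:
        return [g for g, s in self.consensus.items() if s == 0]

    def __len__(self) -> int:
        return len(self.signs)


def shared_genes(
    a: SignedGeneSet, b: SignedGeneSet, signed: bool = False
) -> tuple[int, list[str]]:
    """Intersection of two signed gene sets; ``signed=True`` requires equal signs."""
    common = a.genes & b.genes
    if signed:
        common = {g for g in common if a.signs[g] == b.signs[g]}
    genes = sorted(common)
    return len(genes), genes


def shared_gene_table(
    sets: Mapping[str, SignedGeneSet], signed: bool = False
) -> SharedGeneTable:
    """All pairwise shared-gene counts (diagonal = own set size)."""
    tissues = list(sets)
    counts = pd.DataFrame(0, index=tissues, columns=tissues, dtype=int)
    shared: dict[tuple[str, str], list[str]] = {}
    for i, a in enumerate(tissues):
        counts.loc[a, a] = len(sets[a])
        for b in tissues[i + 1:]:
            n, genes = shared_genes(sets[a], sets[b], signed=signed)
            counts.loc[a, b] = counts.loc[b, a] = n
            shared[tuple(sorted((a, b)))] = genes
    return SharedGeneTable(counts, shared)


def pan_cancer(
    sets: Mapping[str, SignedGeneSet] | Sequence[SignedGeneSet], signed: bool = False
) -> PanCancerResult:
    """Genes common to ALL input sets (the pan-cancer core).

    With 15 TCGA localizations and k = 2500 this intersection collapses to a
    handful of genes; discordant signs across tissues are flagged rather than
    dropped.
    """
    if not isinstance(sets, Mapping):
        sets = {f"set{i + 1}": s for i, s in enumerate(sets)}
    if len(sets) < 2:
        raise ValidationError("pan-cancer intersection needs at least 2 sets")
    tissues = list(sets)
    common: set[str] | None = None
    for s in sets.values():
        common = s.genes if common is None else (common & s.genes)
    if signed:
        common = {
            g for g in common if len({sets[t].signs[g] for t in tissues}) == 1
        }
    genes = sorted(common)
    signs = pd.DataFrame(
        {t: [sets[t].signs[g] for g in genes] for t in tissues}, index=genes, dtype=int
    )
    consensus = {
        g: (int(signs.loc[g].iloc[0]) if signs.loc[g].nunique() == 1 else 0)
        for g in genes
    }
    return PanCancerResult(signs, consensus)


def subgroup_intersections(
    sets: Mapping[str, SignedGeneSet],
    subsets: Sequence[Sequence[str]],
    signed: bool = False,
) -> dict[tuple[str, ...], int]:
    """Intersection count for each requested tissue subset."""
    out: dict[tuple[str, ...], int] = {}
    for subset in subsets:
        unknown = [t for t in subset if t not in sets]
        if unknown:
            raise ValidationError(f"unknown tissue code(s): {unknown}")
        if len(subset) == 1:
            out[tuple(subset)] = len(sets[subset[0]])
            continue
        result = pan_cancer({t: sets[t] for t in subset}, signed=signed)
        out[tuple(subset)] = len(result)
    return out


def tumor_distance(fa: pd.Series, fb: pd.Series) -> float:
    """Euclidean distance between two fold vectors over their shared genes."""
    common = fa.index.intersection(fb.index)
    if len(common) == 0:
        raise ValidationError("fold vectors share no genes")
    return float(np.linalg.norm(fa.loc[common].to_numpy() - fb.loc[common].to_numpy()))


def distance_matrix(centers: Mapping[str, pd.Series]) -> pd.DataFrame:
    tissues = list(centers)
    d = pd.DataFrame(0.0, index=tissues, columns=tissues)
    for i, a in enumerate(tissues):
        for b in tissues[i + 1:]:
            d.loc[a, b] = d.loc[b, a] = tumor_distance(centers[a], centers[b])
    return d


def distance_shared_correlation(
    dist: pd.DataFrame, shared: SharedGeneTable
) -> dict[str, float | None]:
    """Pearson and Spearman correlation of distance vs shared-gene count.

    Computed over the upper-triangle tissue pairs; tumors that are close in
    gene-expression space tend to share more profile genes, so both
    coefficients are expected to be negative. Degenerate (constant) inputs
    yield ``None`` coefficients with a flag.
    """
    tissues = [t for t in dist.index if t in shared.counts.index]
    if list(dist.index) != list(shared.counts.index):
        dist = dist.loc[tissues, tissues]
    iu = np.triu_indices(len(tissues), k=1)
    d = dist.loc[tissues, tissues].to_numpy()[iu]
    s = shared.counts.loc[tissues, tissues].to_numpy()[iu].astype(float)
    if len(d) < 3:
        raise ValidationError(f"need >= 3 tissue pairs, got {len(d)}")
    out: dict[str, float | None] = {"n_pairs": int(len(d))}
    if np.ptp(d) == 0 or np.ptp(s) == 0:
        out.update(pearson=None, spearman=None, degenerate=True)
        return out
    out["pearson"] = float(stats.pearsonr(d, s)[0])
    out["spearman"] = float(stats.spearmanr(d, s)[0])
    out["degenerate"] = False
    return out
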