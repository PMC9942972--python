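"""Synthetic FPKM cohorts with a planted two-attractor structure.

The generator emulates the statistical features the landscape analysis
relies on, with full ground truth for recovery tests:

* a gene universe in which a fixed fraction is structurally silent (FPKM
  exactly 0 in every sample, mirroring the ~28k untranscribed genes in a
  ~60k TCGA universe);
* log-normal baseline expression for the expressed genes (Gaussian in log2);
* a planted cancer axis: a set of differentially expressed (DE) genes whose
  differential-expression magnitudes are Pareto distributed in linear fold
  space (above a minimum of ``2**min_fold``), with random over/under signs —
  so the integrated expression distribution of the tumor center has a true
  power-law tail in e_diff, as observed in real tumor centers, and the
  planted log2 folds stay within a biologically realizable dynamic range;
* tumor samples displaced along the axis by a stage-dependent progression
  factor t ∈ (0, 1], normal samples scattered around the baseline;
* a weak aging signature: ~10 genes shifted in older normal samples only
  (tumor samples are drawn from the tumor attractor regardless of age);
* multi-tissue cohorts sharing a small pan-cancer core of DE genes with
  common signs, tissue-private DE genes otherwise, and tissue-specific
  baseline shifts that spread the landscape.

Everything is multiplicative in FPKM (additive Gaussian noise in log2), and
fully reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import STAGES, ExpressionMatrix, SampleTable, SignedGeneSet, ValidationError
from .pca import RefPCAModel


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted two-attractor generative model.

    Defaults are the desk-scale study conditions: 2,000 genes of which a
    quarter are silent, 50 normal and 50 tumor samples, Pareto(1.5) fold
    magnitudes above 1 log2 unit over 200 DE genes, log2 noise 0.5.
    """

    n_genes: int = 2_000
    zero_fraction: float = 0.25
    n_normal: int = 50
    n_tumor: int = 50
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    n_de: int = 200
    pareto_alpha: float = 1.5  # tail exponent of e_diff magnitudes (linear fold)
    min_fold: float = 1.0  # minimum |log2 fold| of a DE gene
    noise_sd: float = 0.5  # log2 units
    n_age_genes: int = 10
    age_effect: float = 1.5  # log2 shift in old normal samples
    age_median: float = 62.0  # years; ages are drawn around this threshold
    age_sd: float = 10.0
    stage_ranges: tuple[tuple[float, float], ...] = (
        (0.40, 0.55),
        (0.55, 0.70),
        (0.70, 0.85),
        (0.85, 1.00),
    )
    n_tissues: int = 15
    shared_core: int = 6
    tissue_shift_sd: float = 1.0  # log2 sd of per-tissue baseline offsets

    def validate(self) -> None:
        if not 0 <= self.zero_fraction < 1:
            raise ValidationError("zero_fraction must be in [0, 1)")
        n_expressed = self.n_genes - int(round(self.zero_fraction * self.n_genes))
        if self.n_de + self.n_age_genes > n_expressed:
            raise ValidationError(
                f"n_de + n_age_genes = {self.n_de + self.n_age_genes} exceeds the "
                f"{n_expressed} expressed genes"
            )
        if self.shared_core > self.n_de:
            raise ValidationError("shared_core cannot exceed n_de")
        for name in ("baseline_log2_sd", "age_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.pareto_alpha <= 0 or self.min_fold <= 0:
            raise ValidationError("pareto_alpha and min_fold must be > 0")
        if len(self.stage_ranges) != 4:
            raise ValidationError("stage_ranges must cover stages I-IV")
        for lo, hi in self.stage_ranges:
            if not 0 < lo <= hi <= 1:
                raise ValidationError("stage ranges must be within (0, 1] and ordered")

    @property
    def n_zero(self) -> int:
        return int(round(self.zero_fraction * self.n_genes))


# desk-scale 15-tissue cohort: private DE sets must stay disjoint across
# tissues, which bounds n_de by the expressed-gene pool
COHORT_SPEC = SyntheticSpec(n_de=90, n_normal=20, n_tumor=40)

# the low-noise regime used for exact cross-tissue recovery claims
LOW_NOISE_COHORT_SPEC = SyntheticSpec(n_de=90, n_normal=20, n_tumor=40, noise_sd=0.25)

TCGA_SCALE_SPEC = SyntheticSpec(
    n_genes=60_483,
    zero_fraction=0.46,
    n_de=2_500,
    n_normal=50,
    n_tumor=500,
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by the generator: the recovery targets."""

    axis: pd.Series  # unit vector w over all genes, nonzero only on DE genes
    de_set: SignedGeneSet
    progression: pd.Series  # t_s per sample; 0 for normal samples
    age_genes: tuple[str, ...]
    fold_magnitudes: pd.Series  # planted e_diff magnitude (> 1, Pareto) per DE gene
    tissue_code: str = "SIM"
    core_genes: tuple[str, ...] = field(default=())


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _draw_pareto(rng: np.random.Generator, n: int, alpha: float, x_min: float) -> np.ndarray:
    # inverse-CDF sampling: x = x_min * U^(-1/alpha)
    return x_min * rng.uniform(size=n) ** (-1.0 / alpha)


def generate_tissue(
    spec: SyntheticSpec = SyntheticSpec(),
    seed: int | np.random.SeedSequence = 0,
    tissue_code: str = "SIM",
    *,
    zero_genes: Sequence[str] | None = None,
    de_genes: Sequence[str] | None = None,
    de_signs: dict[str, int] | None = None,
    age_genes: Sequence[str] | None = None,
    baseline_log2: pd.Series | None = None,
    baseline_shift: pd.Series | None = None,
) -> tuple[ExpressionMatrix, SampleTable, SyntheticTruth]:
    """Generate one tissue's FPKM matrix, metadata and planted truth.

    The keyword-only arguments let :func:`generate_cohort` coordinate the
    gene partition across tissues; left as ``None`` they are drawn here.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    genes = _gene_ids(spec.n_genes)
    gene_index = pd.Index(genes)

    if zero_genes is None:
        perm = rng.permutation(spec.n_genes)
        zero_genes = [genes[i] for i in perm[: spec.n_zero]]
    zero_set = set(zero_genes)
    expressed = [g for g in genes if g not in zero_set]

    if de_genes is None:
        picks = rng.choice(len(expressed), size=spec.n_de + spec.n_age_genes, replace=False)
        de_genes = [expressed[i] for i in picks[: spec.n_de]]
        age_genes = [expressed[i] for i in picks[spec.n_de:]]
    elif age_genes is None:
        pool = [g for g in expressed if g not in set(de_genes)]
        picks = rng.choice(len(pool), size=spec.n_age_genes, replace=False)
        age_genes = [pool[i] for i in picks]

    # planted axis: Pareto e_diff magnitudes (linear fold space, minimum
    # 2**min_fold) with random signs; the log2 folds added to the baseline
    # are +/- log2(magnitude), so |log2 fold| >= min_fold
    magnitudes = _draw_pareto(rng, len(de_genes), spec.pareto_alpha, 2.0**spec.min_fold)
    signs = np.where(rng.uniform(size=len(de_genes)) < 0.5, 1, -1)
    if de_signs is not None:
        for i, g in enumerate(de_genes):
            if g in de_signs:
                signs[i] = de_signs[g]
    f = pd.Series(0.0, index=gene_index)
    f.loc[list(de_genes)] = np.log2(magnitudes) * signs
    w = f / np.linalg.norm(f.to_numpy())

    baseline = pd.Series(0.0, index=gene_index)
    if baseline_log2 is not None:
        baseline.loc[expressed] = baseline_log2.loc[expressed]
    else:
        baseline.loc[expressed] = rng.normal(
            spec.baseline_log2_mean, spec.baseline_log2_sd, size=len(expressed)
        )
    if baseline_shift is not None:
        baseline = baseline.add(baseline_shift.reindex(gene_index, fill_value=0.0))

    n_n, n_t = spec.n_normal, spec.n_tumor
    sample_ids = [f"{tissue_code}-N{i + 1:03d}" for i in range(n_n)] + [
        f"{tissue_code}-T{i + 1:03d}" for i in range(n_t)
    ]
    conditions = ["normal"] * n_n + ["tumor"] * n_t
    ages = np.round(rng.normal(spec.age_median, spec.age_sd, size=n_n + n_t)).clip(20, 95)

    stages = [pd.NA] * n_n + [STAGES[rng.integers(4)] for _ in range(n_t)]
    t_s = np.zeros(n_n + n_t)
    for j in range(n_n, n_n + n_t):
        lo, hi = spec.stage_ranges[STAGES.index(stages[j])]
        t_s[j] = rng.uniform(lo, hi)

    expressed_mask = ~gene_index.isin(zero_set)
    log2e = np.tile(baseline.to_numpy()[:, None], (1, n_n + n_t))
    noise = rng.normal(0.0, spec.noise_sd, size=(int(expressed_mask.sum()), n_n + n_t))
    log2e[expressed_mask, :] += noise
    log2e += f.to_numpy()[:, None] * t_s[None, :]
    old_normal = np.array(
        [c == "normal" and a >= spec.age_median for c, a in zip(conditions, ages)]
    )
    if old_normal.any() and len(age_genes) > 0:
        age_rows = gene_index.isin(set(age_genes))
        log2e[np.ix_(age_rows, old_normal)] += spec.age_effect

    fpkm = np.exp2(log2e)
    fpkm[~expressed_mask, :] = 0.0

    matrix = ExpressionMatrix(pd.DataFrame(fpkm, index=gene_index, columns=sample_ids))
    samples = SampleTable(
        pd.DataFrame(
            {
                "tissue_code": tissue_code,
                "condition": conditions,
                "age_years": ages,
                "stage": pd.array(stages, dtype="string"),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        axis=w,
        de_set=SignedGeneSet({g: int(s) for g, s in zip(de_genes, signs)}),
        progression=pd.Series(t_s, index=sample_ids),
        age_genes=tuple(age_genes),
        fold_magnitudes=pd.Series(magnitudes, index=list(de_genes)),
        tissue_code=tissue_code,
    )
    return matrix, samples, truth


def generate_cohort(
    spec: SyntheticSpec = COHORT_SPEC, seed: int | np.random.SeedSequence = 0
) -> list[tuple[ExpressionMatrix, SampleTable, SyntheticTruth]]:
    """Generate ``spec.n_tissues`` tissues sharing a pan-cancer DE core.

    One gene universe (and structural-zero set) is shared by all tissues.
    The ``shared_core`` genes appear, with identical signs, in every tissue's
    DE set; the remaining DE genes are tissue-private and pairwise disjoint,
    so intersections of recovered profiles isolate the core exactly. Each
    tissue receives its own baseline offset so the landscape of centers has
    tissue-differentiation spread.
    """
    spec.validate()
    if spec.n_tissues < 2:
        raise ValidationError("a cohort needs n_tissues >= 2")
    root = np.random.SeedSequence(seed if isinstance(seed, int) else seed.entropy)
    rng = np.random.default_rng(root.spawn(1)[0])
    genes = _gene_ids(spec.n_genes)

    perm = rng.permutation(spec.n_genes)
    zero_genes = [genes[i] for i in perm[: spec.n_zero]]
    expressed = [genes[i] for i in perm[spec.n_zero:]]

    n_private = spec.n_de - spec.shared_core
    need = spec.shared_core + spec.n_tissues * n_private
    if need > len(expressed):
        raise ValidationError(
            f"disjoint private DE sets need {need} expressed genes, have {len(expressed)}"
        )
    core = expressed[: spec.shared_core]
    core_signs = {
        g: int(s) for g, s in zip(core, np.where(rng.uniform(size=len(core)) < 0.5, 1, -1))
    }
    cursor = spec.shared_core

    # one baseline for the whole cohort: tissues differ only by their shift
    common_baseline = pd.Series(
        rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=len(expressed)),
        index=expressed,
    )

    out = []
    children = root.spawn(spec.n_tissues + 1)[1:]
    for t in range(spec.n_tissues):
        private = expressed[cursor: cursor + n_private]
        cursor += n_private
        shift = pd.Series(
            rng.normal(0.0, spec.tissue_shift_sd, size=len(expressed)), index=expressed
        )
        matrix, samples, truth = generate_tissue(
            spec,
            children[t],
            tissue_code=f"SIM{t + 1:02d}",
            zero_genes=zero_genes,
            de_genes=core + private,
            de_signs=core_signs,
            baseline_log2=common_baseline,
            baseline_shift=shift,
        )
        out.append((matrix, samples, replace(truth, core_genes=tuple(core))))
    return out


def truth_alignment(
    model: RefPCAModel, truth: SyntheticTruth, k: int | None = None
) -> dict[str, float]:
    """How well a fitted cancer axis recovers the planted one.

    Returns the absolute cosine between v_1 and the planted w, and the
    recall of planted DE genes among the top-k genes by |v1| (k defaults to
    the number of DE genes).
    """
    v1 = model.v1
    if list(v1.index) != list(truth.axis.index):
        raise ValidationError("model and truth gene universes differ")
    w = truth.axis.to_numpy()
    cosine = float(abs(v1.to_numpy() @ w))
    de = set(truth.de_set.genes)
    if k is None:
        k = len(de)
    top = set(v1.abs().nlargest(k).index)
    recall = len(top & de) / len(de) if de else float("nan")
    return {"cosine": cosine, "recall": recall, "k": float(k)}
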