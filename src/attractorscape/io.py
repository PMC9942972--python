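"""Reading, writing and validation of expression matrices, sample metadata and gene sets.

All tabular formats are plain tab-separated text: expression matrices carry
gene identifiers in the first column and sample identifiers in the header;
sample metadata is a TSV with named columns; signed gene sets are two-column
files (gene_id, ``+``/``-``). FPKM values must be finite and nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"
CONDITIONS = (NORMAL, TUMOR)
STAGES = ("I", "II", "III", "IV")

DEFAULT_EPSILON = 0.1


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates its contract."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene × sample matrix of nonnegative FPKM values.

    Genes are rows, samples are columns; both axes carry unique string
    identifiers. Construction validates finiteness and nonnegativity.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        object.__setattr__(self, "data", self.data.rename_axis(index="gene_id", columns=None))
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix must be numeric")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite expression for gene {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative expression ({values[i, j]}) for gene "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

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
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: tissue code, normal/tumor condition, age, stage.

    ``age_years`` and ``stage`` may be missing (NaN); ``condition`` is always
    one of ``normal``/``tumor``.
    """

    data: pd.DataFrame  # index sample_id; columns tissue_code, condition, age_years, stage

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("tissue_code", "condition"):
            if col not in self.data.columns:
                raise ValidationError(f"sample table missing required column {col!r}")
        bad = ~self.data["condition"].isin(CONDITIONS)
        if bad.any():
            sid = self.data.index[bad][0]
            raise ValidationError(
                f"sample {sid!r} has condition "
                f"{self.data.loc[sid, 'condition']!r}; expected one of {CONDITIONS}"
            )
        if "age_years" not in self.data.columns:
            self.data["age_years"] = np.nan
        if "stage" not in self.data.columns:
            self.data["stage"] = pd.Series([pd.NA] * len(self.data), index=self.data.index)
        ages = pd.to_numeric(self.data["age_years"], errors="raise")
        if (ages.dropna() < 0).any():
            raise ValidationError("negative age_years")
        object.__setattr__(self, "data", self.data.assign(age_years=ages))
        stages = self.data["stage"]
        known = stages.dropna()
        bad_stage = ~known.isin(STAGES)
        if bad_stage.any():
            sid = known.index[bad_stage][0]
            raise ValidationError(
                f"sample {sid!r} has stage {known[sid]!r}; expected I-IV or missing"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def condition_samples(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        return list(self.data.index[self.data["condition"] == condition])

    @property
    def normals(self) -> list[str]:
        return self.condition_samples(NORMAL)

    @property
    def tumors(self) -> list[str]:
        return self.condition_samples(TUMOR)

    def counts(self) -> tuple[int, int]:
        """(N_n, N_t): number of normal and tumor samples."""
        return len(self.normals), len(self.tumors)

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)].copy())


@dataclass(frozen=True)
class SignedGeneSet:
    """Genes annotated with an over (+1) / under (−1) expression sign."""

    signs: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, s in self.signs.items():
            if s not in (1, -1):
                raise ValidationError(f"gene {g!r} has sign {s!r}; expected +1 or -1")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.signs)

    def __len__(self) -> int:
        return len(self.signs)

    def __contains__(self, gene: str) -> bool:
        return gene in self.signs


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header: sample ids; first column: gene ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "sample")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed expression matrix: {exc}") from exc
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric expression value: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return ExpressionMatrix(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "gene_id"
    # repr round-trips float64 exactly through the text format
    df.to_csv(path, sep="\t", float_format=None)


def read_samples(path: str | Path) -> SampleTable:
    """Read sample metadata TSV (sample_id, tissue_code, condition[, age_years, stage])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"stage": "string"})
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'sample_id'")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    try:
        return SampleTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_samples(t: SampleTable, path: str | Path) -> None:
    df = t.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_gene_set(path: str | Path) -> SignedGeneSet:
    """Read a two-column gene set file: gene_id TAB sign (+ or -)."""
    signs: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("+", "-"):
            raise ValidationError(f"{path}:{lineno}: expected 'gene_id<TAB>+|-'")
        gene = parts[0]
        if gene in signs:
            raise ValidationError(f"{path}:{lineno}: duplicate gene {gene!r}")
        signs[gene] = 1 if parts[1] == "+" else -1
    return SignedGeneSet(signs)


def write_gene_set(s: SignedGeneSet, path: str | Path) -> None:
    lines = [f"{g}\t{'+' if sign > 0 else '-'}" for g, sign in s.signs.items()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def expression_range_summary(
    m: ExpressionMatrix, threshold: float = DEFAULT_EPSILON
) -> tuple[int, int]:
    """Summarize the dynamic range of a raw FPKM matrix.

    Returns ``(n_zero, n_above)`` where ``n_zero`` counts structurally silent
    genes (maximum raw value exactly 0) and ``n_above`` counts genes whose
    geometric-mean raw expression exceeds ``threshold`` (a gene with any zero
    has geometric mean 0). In TCGA-scale data roughly half the ~60k gene
    universe is silent and only ~30k genes exceed 0.1 FPKM.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    values = m.values
    n_zero = int((values.max(axis=1) == 0).sum())
    with np.errstate(divide="ignore"):
        logs = np.log(values)
    gmean = np.exp(np.where(np.isinf(logs).any(axis=1), -np.inf, logs.mean(axis=1)))
    n_above = int((gmean > threshold).sum())
    return n_zero, n_above
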