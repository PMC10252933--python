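"""Data model and validated readers/writers for tabular inputs and outputs.

The canonical orientation of every matrix is cell lines (rows) by genes
(columns), matching DepMap-style exports where the first column holds cell
line identifiers (``ACH-000001``) and the remaining headers are gene labels
of the form ``"SYMBOL (entrez-id)"``.  Missing values are first-class (empty
cells), never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneEffectMatrix",
    "DependencyProbabilityMatrix",
    "ExpressionMatrix",
    "LineageAnnotation",
    "ClinicalCohort",
    "AnnotationTable",
    "SurvivalCohort",
    "parse_gene_symbol",
    "load_matrix",
    "load_lineage_annotation",
    "load_annotation_table",
    "load_survival_table",
    "write_records",
    "read_records",
]


def parse_gene_symbol(label: str) -> str:
    """Return the bare symbol from a ``"SYMBOL (123)"`` style gene label.

    Labels without a parenthesised id pass through unchanged.  The full
    label remains the gene's identity everywhere; the symbol is a view.
    """
    label = label.strip()
    if label.endswith(")") and " (" in label:
        return label[: label.rindex(" (")]
    return label


def _check_axis_labels(labels: Sequence[str], axis: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen[lab] = 1
    if dups:
        raise ValueError(f"duplicate {axis} labels: {sorted(set(dups))}")


class _Matrix:
    """Base for lines-by-genes matrices backed by a pandas DataFrame."""

    def __init__(self, data: pd.DataFrame):
        _check_axis_labels(list(data.index), "cell-line")
        _check_axis_labels(list(data.columns), "gene")
        values = data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValueError("matrix contains non-finite (inf) values")
        self.data = data.astype(float)

    @property
    def line_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def gene_symbols(self) -> list[str]:
        return [parse_gene_symbol(g) for g in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, gene: str) -> pd.Series:
        if gene not in self.data.columns:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self.data[gene]

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return type(self) is type(other) and self.data.equals(other.data)


class GeneEffectMatrix(_Matrix):
    """Cell-line x gene essentiality scores (0 = non-essential scale anchor,
    -1 = median of common-essential genes)."""

    def __init__(self, data: pd.DataFrame, platform: str = "crispr"):
        if platform not in ("crispr", "rnai"):
            raise ValueError(f"platform must be 'crispr' or 'rnai', got {platform!r}")
        super().__init__(data)
        self.platform = platform


class DependencyProbabilityMatrix(_Matrix):
    """Per-(line, gene) probability that the line depends on the gene."""

    def __init__(self, data: pd.DataFrame):
        super().__init__(data)
        vals = self.data.to_numpy()
        finite = vals[~np.isnan(vals)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("dependency probabilities must lie in [0, 1]")


class ExpressionMatrix(_Matrix):
    """Cell-line x gene expression in log2(TPM+1) units (non-negative)."""

    def __init__(self, data: pd.DataFrame):
        super().__init__(data)
        vals = self.data.to_numpy()
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite < 0).any():
            raise ValueError("expression values must be non-negative")


@dataclass
class LineageAnnotation:
    """Mapping from cell-line id to its (single) lineage label."""

    mapping: dict[str, str]

    def __post_init__(self):
        if any(not lin for lin in self.mapping.values()):
            raise ValueError("empty lineage label")

    @property
    def lineages(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lin in self.mapping.values():
            out[lin] = out.get(lin, 0) + 1
        return out

    def lines_in(self, lineage: str) -> list[str]:
        return [l for l, lin in self.mapping.items() if lin == lineage]

    def __contains__(self, lineage: str) -> bool:
        return lineage in set(self.mapping.values())


@dataclass
class ClinicalCohort:
    """Linear-scale expression of one gene in tumor and normal samples."""

    gene: str
    tumor_values: np.ndarray
    normal_values: np.ndarray

    def __post_init__(self):
        self.tumor_values = np.asarray(self.tumor_values, dtype=float)
        self.normal_values = np.asarray(self.normal_values, dtype=float)
        if self.tumor_values.size == 0 or self.normal_values.size == 0:
            raise ValueError("both tumor and normal cohorts must be non-empty")
        if (self.tumor_values < 0).any() or (self.normal_values < 0).any():
            raise ValueError("clinical expression values must be non-negative")


@dataclass
class AnnotationTable:
    """Gene -> set of category labels plus an explicit background universe."""

    categories: dict[str, set[str]]
    background: set[str]

    def __post_init__(self):
        stray = set(self.categories) - self.background
        if stray:
            raise ValueError(
                f"annotated genes outside the background universe: {sorted(stray)[:5]}"
            )

    def genes_in_category(self, category: str) -> set[str]:
        return {g for g, cats in self.categories.items() if category in cats}

    @property
    def all_categories(self) -> set[str]:
        out: set[str] = set()
        for cats in self.categories.values():
            out |= cats
        return out


@dataclass
class SurvivalCohort:
    """Per-patient follow-up time, event indicator and expression covariate."""

    time: np.ndarray
    event: np.ndarray
    expression: np.ndarray
    gene: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.expression = np.asarray(self.expression, dtype=float)
        n = self.time.size
        if self.event.size != n or self.expression.size != n:
            raise ValueError("time, event and expression must have equal length")
        if (self.time < 0).any():
            raise ValueError("times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return self.time.size


# ---------------------------------------------------------------------------
# readers


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_axis_labels(header[1:], "header")  # pandas would mangle duplicates
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def _coerce_numeric(raw: pd.DataFrame) -> pd.DataFrame:
    out = raw.replace("", np.nan)
    coerced = out.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & out.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {raw.index[r]!r}, column {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    return coerced


def load_matrix(
    path,
    orientation: str = "lines_by_genes",
    kind: str = "effect",
    platform: str = "crispr",
    delimiter: str | None = None,
):
    """Load a delimited matrix into canonical lines-by-genes orientation.

    Parameters
    ----------
    orientation:
        How the file on disk is laid out: ``lines_by_genes`` (DepMap export
        style) or ``genes_by_lines``; the returned object is always canonical.
    kind:
        ``effect`` -> :class:`GeneEffectMatrix`, ``probability`` ->
        :class:`DependencyProbabilityMatrix`, ``expression`` ->
        :class:`ExpressionMatrix`.
    delimiter:
        Override the comma/tab auto-detection.
    """
    if orientation not in ("lines_by_genes", "genes_by_lines"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_table(path, delimiter)
    data = _coerce_numeric(raw)
    if orientation == "genes_by_lines":
        data = data.T
    if kind == "effect":
        return GeneEffectMatrix(data, platform=platform)
    if kind == "probability":
        return DependencyProbabilityMatrix(data)
    if kind == "expression":
        return ExpressionMatrix(data)
    raise ValueError(f"unknown matrix kind {kind!r}")


def load_lineage_annotation(path, delimiter: str | None = None) -> LineageAnnotation:
    """Read a two-column (cell line id, lineage) table.

    Duplicate consistent rows are deduplicated; a line id mapped to two
    different lineages is a hard error naming the id.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("lineage annotation needs two columns: line id, lineage")
    mapping: dict[str, str] = {}
    for line, lineage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if line in mapping and mapping[line] != lineage:
            raise ValueError(
                f"cell line {line!r} mapped to both {mapping[line]!r} and {lineage!r}"
            )
        mapping[line] = lineage
    return LineageAnnotation(mapping)


def load_annotation_table(path, delimiter: str | None = None) -> AnnotationTable:
    """Read a (gene, category) pair table; the background universe is the
    set of all genes appearing in the table."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    categories: dict[str, set[str]] = {}
    background: set[str] = set()
    for gene, cat in zip(df.iloc[:, 0], df.iloc[:, 1]):
        background.add(gene)
        if cat and not pd.isna(cat):
            categories.setdefault(gene, set()).add(cat)
    return AnnotationTable(categories, background)


def load_survival_table(path, delimiter: str | None = None) -> SurvivalCohort:
    """Read a (patient, time, event, expression) table into a cohort."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    return SurvivalCohort(
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        expression=df["expression"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# record tables


def write_records(records: Iterable, path, record_type=None) -> None:
    """Write a homogeneous sequence of record dataclasses as a TSV.

    Column order follows the dataclass field order; floats are serialized
    with full round-trip precision.  An empty sequence writes a header-only
    file when ``record_type`` is given (needed to know the columns).
    """
    records = list(records)
    if not records:
        if record_type is None:
            raise ValueError("empty sequence needs an explicit record_type")
        write_empty_records(record_type, path)
        return
    rtype = type(records[0])
    if not dataclasses.is_dataclass(rtype):
        raise TypeError("records must be dataclasses")
    if any(type(r) is not rtype for r in records):
        raise TypeError("mixed record types in write_records")
    cols = [f.name for f in fields(rtype)]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    df.to_csv(path, sep="\t", index=False)


def write_empty_records(record_type, path) -> None:
    """Write a header-only TSV for the given record dataclass type."""
    cols = [f.name for f in fields(record_type)]
    pd.DataFrame(columns=cols).to_csv(path, sep="\t", index=False)


def _convert(value, ftype):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if "str" in ftype:
            return None
        return value
    if "bool" in ftype:
        if isinstance(value, str):
            return value == "True"
        return bool(value)
    if "int" in ftype:
        return int(value)
    if "float" in ftype:
        return float(value)
    return str(value)


def read_records(path, record_type) -> list:
    """Read back a TSV written by :func:`write_records`."""
    df = pd.read_csv(path, sep="\t")
    specs = [(f.name, str(f.type)) for f in fields(record_type)]
    out = []
    for _, row in df.iterrows():
        kwargs = {name: _convert(row[name], ftype) for name, ftype in specs}
        out.append(record_type(**kwargs))
    return out
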