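"""Readers, writers and validated containers for the pipeline's tabular inputs.

Three inputs drive a run:

* a genes x samples expression matrix (TSV, FPKM-scale values, header row of
  sample ids, first column gene ids; gzip accepted transparently),
* a guide-gene list (two-column TSV: symbol, gene id),
* a transcription-factor family annotation (two-column TSV: gene id, family).

Gene identifiers are treated as opaque, case-sensitive strings (MSU
``LOC_Os`` convention). Missing values ("NA" or empty cells) and negative
expression values are hard errors: the analysis assumes a complete,
nonnegative matrix and silent imputation would corrupt every downstream
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GuideGeneSet",
    "TFFamilyAnnotation",
    "read_expression_matrix",
    "read_family_table",
    "read_guide_list",
    "write_expression_matrix",
]


@dataclass
class ExpressionMatrix:
    """A genes x ordered-samples matrix of nonnegative expression values.

    ``data`` is indexed by gene id (rows, unique) with sample ids as columns,
    in file order. The sample axis is an ordered developmental gradient
    (e.g. 11 leaf sections, base to tip), which is why at least 3 samples
    are required: the Pearson coefficient is uninformative below that.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.data.shape[1] < 3:
            raise ValueError(
                f"need at least 3 samples for correlation, got {self.data.shape[1]}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if np.isnan(values).any():
            raise ValueError("missing expression value (NA or empty cell)")
        if (values < 0).any():
            gene = self.data.index[np.where(values < 0)[0][0]]
            raise ValueError(f"negative expression value in gene {gene!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index


@dataclass
class GuideGeneSet:
    """Ordered (symbol, gene_id) pairs naming the guide genes.

    Symbols are display names (OsGI, Hd3a, ...) and need not be unique;
    gene ids must be. Resolvability against the matrix is checked at
    pipeline run time, not here.
    """

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("guide gene set is empty")
        ids = [g for _, g in self.entries]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(g for g in ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate guide gene id: {dup!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [g for _, g in self.entries]

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    def symbol_of(self, gene_id: str) -> str:
        for s, g in self.entries:
            if g == gene_id:
                return s
        raise KeyError(gene_id)

    def subset_by_symbols(self, symbols: list[str]) -> "GuideGeneSet":
        keep = [(s, g) for s, g in self.entries if s in set(symbols)]
        return GuideGeneSet(keep)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TFFamilyAnnotation:
    """Mapping gene id -> transcription-factor family name.

    Each gene belongs to exactly one family; a gene listed under two
    distinct families is a hard error at read time.
    """

    assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, fam in self.assignments.items():
            if not fam:
                raise ValueError(f"empty family name for gene {gene!r}")

    @property
    def families(self) -> set[str]:
        return set(self.assignments.values())

    def genes_in_family(self, family: str) -> set[str]:
        return {g for g, f in self.assignments.items() if f == family}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a TSV (optionally gzipped) expression matrix.

    First row: sample ids (header); first column: gene ids. Cells must be
    nonnegative numbers; "NA" or empty cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    # keep_default_na=False so "NA" survives as a string and fails numeric
    # conversion loudly instead of becoming NaN.
    raw = pd.read_csv(
        path, sep=delimiter, index_col=0, keep_default_na=False, na_values=[], dtype=str
    )
    raw.index = raw.index.astype(str)
    try:
        numeric = raw.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric or missing expression value in {path}: {exc}") from exc
    if numeric.isna().to_numpy().any():
        raise ValueError(f"missing expression value (empty cell) in {path}")
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with a header of sample ids (round-trips exactly)."""
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def _read_two_column(path: Path, what: str) -> list[tuple[str, str]]:
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    rows: list[tuple[str, str]] = []
    text = path.read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{what} line {lineno}: expected 2 tab-separated columns")
        rows.append((parts[0].strip(), parts[1].strip()))
    return rows


def read_family_table(path: str | Path) -> TFFamilyAnnotation:
    """Read a two-column (gene_id, family) TSV without header.

    Exact duplicate rows are tolerated; the same gene under two distinct
    families is a conflicting assignment and a hard error.
    """
    rows = _read_two_column(Path(path), "family annotation")
    assignments: dict[str, str] = {}
    for gene, family in rows:
        if not family:
            raise ValueError(f"empty family string for gene {gene!r}")
        if gene in assignments and assignments[gene] != family:
            raise ValueError(
                f"conflicting assignment for gene {gene!r}: "
                f"{assignments[gene]!r} vs {family!r}"
            )
        assignments[gene] = family
    return TFFamilyAnnotation(assignments)


def read_guide_list(path: str | Path) -> GuideGeneSet:
    """Read a two-column (symbol, gene_id) TSV without header, in file order."""
    rows = _read_two_column(Path(path), "guide list")
    if not rows:
        raise ValueError(f"guide list is empty: {path}")
    return GuideGeneSet(rows)
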