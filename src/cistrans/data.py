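"""Data model and I/O for allele-resolved expression count tables.

The pipeline starts where an allele-specific expression counter ends: one
row per gene carrying the read-pair counts of the two parental libraries
(``p1``, ``p2``), the two allele-assigned counts of the F1 hybrid library
(``h1``, ``h2``), the number of fixed SNPs that made allele assignment
possible, and an optional per-gene mapping-bias correction factor (the
multiplier on the null allelic ratio that absorbs residual alignment
preference for one parental allele; 1.0 means no residual bias).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneCountRecord",
    "LibraryTotals",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "read_gene_summary",
    "filter_min_parental",
    "library_totals",
    "records_to_frame",
]

#: canonical column order of the internal TSV format
COUNT_COLUMNS = ("gene_id", "p1", "p2", "h1", "h2", "n_snps", "bias_factor")


class CountTableError(ValueError):
    """Malformed count table: missing column or invalid row value."""


@dataclasses.dataclass(frozen=True)
class GeneCountRecord:
    """Allele-resolved counts for one gene.

    Attributes
    ----------
    gene_id : str
        Gene identifier.
    p1, p2 : int
        Read-pair counts in the two parental libraries.
    h1, h2 : int
        F1 read-pair counts assigned to the parent-1 / parent-2 allele.
    n_snps : int
        Number of fixed SNPs distinguishing the alleles (>= 1; allele
        assignment requires at least one diagnostic site).
    bias_factor : float
        Per-gene residual mapping-bias multiplier on the null allelic
        ratio; 1.0 when no bias information is available.
    """

    gene_id: str
    p1: int
    p2: int
    h1: int
    h2: int
    n_snps: int = 1
    bias_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "h1", "h2"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise CountTableError(
                    f"gene {self.gene_id!r}: {name}={v!r} is not a "
                    "non-negative integer"
                )
        if self.n_snps < 1:
            raise CountTableError(
                f"gene {self.gene_id!r}: n_snps={self.n_snps} < 1"
            )
        if not self.bias_factor > 0:
            raise CountTableError(
                f"gene {self.gene_id!r}: bias_factor={self.bias_factor} <= 0"
            )


@dataclasses.dataclass(frozen=True)
class LibraryTotals:
    """Column sums over a record set; the basis of the null library ratios.

    Totals are always computed over the *full* record set (all genes with
    allele assignment), before any coverage filtering: the null ratio of a
    test refers to whole-library sequencing depth, not to the filtered
    subset.
    """

    p1: int
    p2: int
    h1: int
    h2: int

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.h1, self.h2) <= 0:
            raise CountTableError(
                f"library totals must all be positive, got {self}"
            )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.p1, self.p2, self.h1, self.h2)


def library_totals(records: Sequence[GeneCountRecord]) -> LibraryTotals:
    """Column sums of a record collection."""
    return LibraryTotals(
        p1=sum(r.p1 for r in records),
        p2=sum(r.p2 for r in records),
        h1=sum(r.h1 for r in records),
        h2=sum(r.h2 for r in records),
    )


def _records_from_frame(df: pd.DataFrame) -> list[GeneCountRecord]:
    records = []
    for row in df.itertuples(index=False):
        gene_id = str(row.gene_id)
        vals = {}
        for name in ("p1", "p2", "h1", "h2", "n_snps"):
            raw = getattr(row, name)
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise CountTableError(
                    f"gene {gene_id!r}: {name}={raw!r} does not parse as an integer"
                ) from None
            if float(raw) != v:
                raise CountTableError(
                    f"gene {gene_id!r}: {name}={raw!r} is not an integer"
                )
            vals[name] = v
        records.append(
            GeneCountRecord(
                gene_id=gene_id,
                bias_factor=float(row.bias_factor),
                **vals,
            )
        )
    return records


def read_count_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[GeneCountRecord], LibraryTotals]:
    """Read the canonical tab-separated count table.

    Parameters
    ----------
    path
        TSV file with a header line; ``#``-prefixed lines are ignored.
        Required columns: ``gene_id p1 p2 h1 h2 n_snps``; ``bias_factor``
        is optional and defaults to 1.0.
    dialect
        Optional mapping from canonical column names to the names actually
        used in the file, e.g. ``{"p1": "ps88_count"}``.

    Returns
    -------
    (records, totals)
        One :class:`GeneCountRecord` per row, in file order, and the
        :class:`LibraryTotals` over *all* rows (pre-filter).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    required = ("gene_id", "p1", "p2", "h1", "h2", "n_snps")
    for col in required:
        if col not in df.columns:
            raise CountTableError(
                f"count table {path} is missing required column {col!r} "
                f"(found: {list(df.columns)})"
            )
    if "bias_factor" not in df.columns:
        df["bias_factor"] = 1.0
    df["bias_factor"] = df["bias_factor"].fillna(1.0)
    records = _records_from_frame(df)
    return records, library_totals(records)


def records_to_frame(records: Iterable[GeneCountRecord]) -> pd.DataFrame:
    """Record collection as a DataFrame in canonical column order."""
    return pd.DataFrame(
        [dataclasses.astuple(r) for r in records], columns=COUNT_COLUMNS
    )


def write_count_table(records: Iterable[GeneCountRecord], path: str | Path) -> None:
    """Serialize records to the canonical TSV format."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


# Default header mapping for the deposited gene summary spreadsheet.  The
# deposited table carries raw and normalized counts plus the published
# category / inheritance labels; only the raw counts feed the pipeline,
# the labels are kept as annotations for comparison.
GENE_SUMMARY_DIALECT: dict[str, str] = {
    "gene_id": "gene_id",
    "p1": "ps88_raw",
    "p2": "ps94_raw",
    "h1": "hybrid_ps88_raw",
    "h2": "hybrid_ps94_raw",
    "n_snps": "n_snps",
    "bias_factor": "bias_factor",
    "category": "regulatory_type",
    "inheritance": "inheritance_mode",
}


def read_gene_summary(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> tuple[list[GeneCountRecord], pd.DataFrame]:
    """Read a gene summary spreadsheet (raw counts + published labels).

    The column-name mapping ``dialect`` maps canonical names
    (``gene_id p1 p2 h1 h2 n_snps bias_factor category inheritance``)
    to the spreadsheet's own headers; unmapped optional columns fall back
    to defaults (``n_snps`` 1, ``bias_factor`` 1.0).

    Returns the records plus an annotation frame (gene_id, published
    category, published inheritance mode, and any magnitude columns
    present).  Published labels are never consumed by the pipeline's own
    inference; they exist only so recomputed calls can be compared with
    the deposited ones.
    """
    dmap = dict(GENE_SUMMARY_DIALECT)
    if dialect:
        dmap.update(dialect)
    try:
        df = pd.read_excel(path, sheet_name=sheet)
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise CountTableError(f"cannot read spreadsheet {path}: {exc}") from exc

    def col(name: str) -> str | None:
        c = dmap.get(name)
        return c if c in df.columns else None

    required = ("gene_id", "p1", "p2", "h1", "h2")
    missing = [n for n in required if col(n) is None]
    if missing:
        raise CountTableError(
            f"gene summary {path}: cannot locate columns for {missing} "
            f"(headers found: {list(df.columns)})"
        )
    out = pd.DataFrame({"gene_id": df[col("gene_id")].astype(str)})
    for name in ("p1", "p2", "h1", "h2"):
        out[name] = df[col(name)]
    out["n_snps"] = df[col("n_snps")] if col("n_snps") else 1
    out["bias_factor"] = df[col("bias_factor")] if col("bias_factor") else 1.0
    out["bias_factor"] = out["bias_factor"].fillna(1.0)
    records = _records_from_frame(out)

    annotations = pd.DataFrame({"gene_id": out["gene_id"]})
    for name in ("category", "inheritance"):
        c = col(name)
        annotations[name] = df[c].astype(str) if c else None
    return records, annotations


def filter_min_parental(
    records: Sequence[GeneCountRecord], threshold: int = 20
) -> list[GeneCountRecord]:
    """Keep genes with combined parental coverage ``p1 + p2 >= threshold``.

    Library totals are deliberately *not* recomputed after filtering;
    null ratios always use full-library sums.  Idempotent, order
    preserving; an empty result is allowed.
    """
    return [r for r in records if r.p1 + r.p2 >= threshold]
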