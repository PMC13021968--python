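"""Differential-expression table and RNAi-line catalog accounting.

The screen starts from a table of differentially expressed genes (DEGs) —
knockdown versus control log2 fold changes with BH-adjusted p-values — and an
RNAi-line catalog recording, for each DEG, which inducible lines exist, from
which library (KK, GD or TRiP), and whether driving them is lethal.  The
catalog accounting defines exactly which genes and lines enter the primary
behavioral screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "DEGRecord",
    "RNAiCatalogEntry",
    "read_deg_table",
    "write_deg_table",
    "read_catalog",
    "significant_degs",
    "catalog_accounting",
]

LIBRARIES = ("KK", "GD", "TRiP")


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result (knockdown vs control)."""

    gene_id: str
    log2fc: float
    padj: float
    base_expr: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ParseError(f"{self.gene_id}: log2fc must be finite, got {self.log2fc}")
        if not (0.0 <= self.padj <= 1.0):
            raise ParseError(f"{self.gene_id}: padj must lie in [0, 1], got {self.padj}")
        if self.base_expr is not None and self.base_expr < 0:
            raise ParseError(f"{self.gene_id}: base_expr must be nonnegative")

    @property
    def direction(self) -> str | None:
        """'up', 'down', or None when log2fc is exactly zero (no direction)."""
        if self.log2fc > 0:
            return "up"
        if self.log2fc < 0:
            return "down"
        return None


@dataclass(frozen=True)
class RNAiCatalogEntry:
    """One inducible RNAi line targeting one DEG.

    ``lethal`` means the driver x RNAi cross dies before testing; a lethal
    line is by definition one that was obtained, so lethal implies available.
    """

    gene_id: str
    line_id: str
    library: str
    available: bool = True
    lethal: bool = False

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise ParseError(
                f"{self.line_id}: library must be one of {LIBRARIES}, got {self.library!r}"
            )
        if self.lethal and not self.available:
            raise ParseError(f"{self.line_id}: a lethal line must be an available line")

    @property
    def tested(self) -> bool:
        return self.available and not self.lethal


def read_deg_table(path) -> list[DEGRecord]:
    """Read a DEG table (TSV with header gene_id, log2fc, padj[, base_expr]).

    Extra columns are ignored; row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    records: list[DEGRecord] = []
    has_base = "base_expr" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            log2fc = float(row.log2fc)
            padj = float(row.padj)
            base = float(row.base_expr) if has_base and not pd.isna(row.base_expr) else None
            if math.isnan(padj) or math.isnan(log2fc):
                raise ValueError("NaN value")
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {i + 1} ({row.gene_id}): {exc}") from exc
        try:
            records.append(DEGRecord(str(row.gene_id), log2fc, padj, base))
        except ParseError as exc:
            raise ParseError(f"{path}: row {i + 1}: {exc}") from exc
    return records


def write_deg_table(records: Iterable[DEGRecord], path) -> None:
    rows = [
        {"gene_id": r.gene_id, "log2fc": r.log2fc, "padj": r.padj, "base_expr": r.base_expr}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj", "base_expr"])
    if df["base_expr"].isna().all():
        df = df.drop(columns=["base_expr"])
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[RNAiCatalogEntry]:
    """Read an RNAi-line catalog (TSV: gene_id, line_id, library, available, lethal)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "line_id": str})
    required = {"gene_id", "line_id", "library", "available", "lethal"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            entries.append(
                RNAiCatalogEntry(
                    str(row.gene_id),
                    str(row.line_id),
                    str(row.library),
                    bool(int(row.available)),
                    bool(int(row.lethal)),
                )
            )
        except (TypeError, ValueError, ParseError) as exc:
            raise ParseError(f"{path}: row {i + 1}: {exc}") from exc
    return entries


def significant_degs(records: Sequence[DEGRecord], alpha: float = 0.05) -> set[str]:
    """Genes with adjusted p strictly below ``alpha``.

    The strict inequality matches the screen's stated threshold (adjusted
    p < 0.05); the result is independent of row order.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return {r.gene_id for r in records if r.padj < alpha}


def catalog_accounting(
    degs: set[str], catalog: Sequence[RNAiCatalogEntry]
) -> dict[str, int]:
    """Count lines and genes at each availability stage of the catalog.

    Returns the counts that define what enters the primary screen:

    - ``n_genes_with_lines``: genes with at least one available line
    - ``n_lines_obtained``: available lines
    - ``n_lethal_lines``: available lines whose cross is lethal
    - ``n_lines_tested``: available, non-lethal lines
    - ``n_genes_tested``: genes with at least one tested line
    """
    unknown = sorted({e.gene_id for e in catalog} - set(degs))
    if unknown:
        raise ValidationError(f"catalog entries for genes not in the DEG set: {unknown}")
    available = [e for e in catalog if e.available]
    tested = [e for e in available if not e.lethal]
    return {
        "n_genes_with_lines": len({e.gene_id for e in available}),
        "n_lines_obtained": len(available),
        "n_lethal_lines": sum(e.lethal for e in available),
        "n_lines_tested": len(tested),
        "n_genes_tested": len({e.gene_id for e in tested}),
    }
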