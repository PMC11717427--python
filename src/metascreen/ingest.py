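"""Ingestion of per-study gene tables into canonical gene lists.

A *source table* is one delimited text file from one study: a gene token per
row with optional (adjusted) P-values. Ingestion filters rows by
significance, maps tokens onto canonical identifiers through a user-supplied
alias map, and emits :class:`GeneList` objects whose members are compared for
presence/absence downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

CATEGORIES = ("mRNA", "smallRNA", "totalRNA", "protein-IP", "enrichment", "other")

UnresolvedPolicy = Literal["drop", "keep", "error"]


@dataclass(frozen=True)
class TableRow:
    gene_token: str
    p: float | None = None
    p_adj: float | None = None


@dataclass
class SourceTable:
    """Raw rows of one study-derived table, before significance filtering."""

    source_id: str
    rows: list[TableRow]
    publication_ref: str = ""
    category: str = "other"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        for row in self.rows:
            for value in (row.p, row.p_adj):
                if value is not None and not (0.0 <= value <= 1.0):
                    raise ValueError(
                        f"p-value {value} for {row.gene_token!r} outside [0, 1]"
                    )


@dataclass
class AliasMap:
    """Many-to-one mapping from gene tokens to canonical identifiers."""

    mapping: Mapping[str, str]
    policy: UnresolvedPolicy = "keep"

    def resolve(self, token: str) -> str | None:
        """Canonical id for *token*, or None when unresolved under ``drop``."""
        if token in self.mapping:
            return self.mapping[token]
        if self.policy == "keep":
            return token
        if self.policy == "drop":
            return None
        raise KeyError(f"unresolved gene token {token!r}")


@dataclass
class GeneList:
    """A study-derived list: canonical gene ids with provenance metadata."""

    list_id: str
    source_id: str
    category: str
    genes: frozenset[str]

    @property
    def size(self) -> int:
        """T_i, the total number of genes in the list."""
        return len(self.genes)

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0


def parse_table(
    path: str | Path,
    schema: Mapping[str, str | None],
    *,
    source_id: str | None = None,
    category: str = "other",
    publication_ref: str = "",
    sep: str | None = None,
) -> SourceTable:
    """Parse a delimited text table into a :class:`SourceTable`.

    ``schema`` must name the gene column under ``"gene"`` and may name
    ``"p"`` and ``"p_adj"`` columns. Unparseable p-values become absent
    rather than causing the row to be dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    if "gene" not in schema or not schema["gene"]:
        raise ValueError("schema must name a 'gene' column")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"empty table: {path}")

    def _column(key: str) -> pd.Series | None:
        name = schema.get(key)
        if name is None:
            return None
        if name not in df.columns:
            raise ValueError(f"column {name!r} ({key}) not found in {path}")
        return df[name]

    genes = _column("gene")
    assert genes is not None
    p_col = _column("p")
    padj_col = _column("p_adj")

    def _parse_p(value: object) -> float | None:
        try:
            v = float(value)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return None
        if not (0.0 <= v <= 1.0):
            return None
        return v

    rows = []
    for i in range(len(df)):
        token = genes.iloc[i]
        if pd.isna(token) or not str(token).strip():
            continue
        rows.append(
            TableRow(
                gene_token=str(token).strip(),
                p=_parse_p(p_col.iloc[i]) if p_col is not None else None,
                p_adj=_parse_p(padj_col.iloc[i]) if padj_col is not None else None,
            )
        )
    return SourceTable(
        source_id=source_id or path.stem,
        rows=rows,
        publication_ref=publication_ref,
        category=category,
    )


def filter_significant(
    table: SourceTable, alpha: float = 0.05, *, list_id: str | None = None
) -> GeneList:
    """Keep rows passing the significance filter and collapse to a gene set.

    The adjusted P-value governs when present; otherwise the raw P-value;
    rows carrying neither are retained. An all-filtered table yields a
    flagged-empty list rather than an error.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    kept = set()
    for row in table.rows:
        if row.p_adj is not None:
            keep = row.p_adj < alpha
        elif row.p is not None:
            keep = row.p < alpha
        else:
            keep = True
        if keep:
            kept.add(row.gene_token)
    return GeneList(
        list_id=list_id or table.source_id,
        source_id=table.source_id,
        category=table.category,
        genes=frozenset(kept),
    )


def standardize_names(
    gene_list: GeneList, aliases: AliasMap
) -> tuple[GeneList, dict]:
    """Replace tokens with canonical ids; report unresolved tokens.

    Returns the mapped list and a per-list report with the unresolved tokens
    and the number of collisions (distinct tokens mapping to one id).
    """
    mapped = set()
    unresolved = []
    for token in sorted(gene_list.genes):
        canon = aliases.resolve(token)
        if canon is None:
            unresolved.append(token)
        else:
            mapped.add(canon)
    report = {
        "list_id": gene_list.list_id,
        "n_input": len(gene_list.genes),
        "n_output": len(mapped),
        "unresolved": unresolved,
        "n_collisions": len(gene_list.genes) - len(unresolved) - len(mapped),
    }
    out = GeneList(
        list_id=gene_list.list_id,
        source_id=gene_list.source_id,
        category=gene_list.category,
        genes=frozenset(mapped),
    )
    return out, report


# ---------------------------------------------------------------------------
# canonical on-disk format: one row per (list, gene), plus a JSON manifest
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["list_id", "source_id", "category", "gene"]


def write_gene_lists(lists: Sequence[GeneList], path: str | Path) -> None:
    records = []
    for gl in lists:
        for gene in sorted(gl.genes):
            records.append((gl.list_id, gl.source_id, gl.category, gene))
    pd.DataFrame(records, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_lists(path: str | Path) -> list[GeneList]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene-list TSV missing columns {missing}")
    lists = []
    for list_id, grp in df.groupby("list_id", sort=True):
        lists.append(
            GeneList(
                list_id=str(list_id),
                source_id=str(grp["source_id"].iloc[0]),
                category=str(grp["category"].iloc[0]),
                genes=frozenset(grp["gene"].astype(str)),
            )
        )
    return lists


def write_manifest(lists: Sequence[GeneList], path: str | Path) -> None:
    manifest = {
        "n_lists": len(lists),
        "lists": [
            {
                "list_id": gl.list_id,
                "source_id": gl.source_id,
                "category": gl.category,
                "size": gl.size,
                "empty": gl.is_empty,
            }
            for gl in lists
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
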