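"""Loaders for the DepMap-style CSV dialects and signature gene lists."""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cohort import MutationRecord
from .errors import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "load_depmap_matrix",
    "load_expression",
    "load_mutation_table",
    "mutation_records",
    "load_gene_list",
]

_PAREN_ID = re.compile(r"\s*\(\d+\)\s*$")


def _strip_entrez(column: str) -> str:
    """'KRAS (3845)' -> 'KRAS'."""
    return _PAREN_ID.sub("", str(column)).strip().upper()


def load_depmap_matrix(path: str | Path) -> pd.DataFrame:
    """Cell line x gene CSV with 'SYMBOL (entrez)' or plain-symbol columns."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise EmptyInputError(f"{path}: no gene columns")
    df.columns = [_strip_entrez(c) for c in df.columns]
    dup = df.columns[df.columns.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene columns after symbol cleanup: {list(dup)[:5]}")
    return df


def load_expression(path: str | Path) -> pd.DataFrame:
    """Expression matrix on the log2(TPM+1) scale (DepMap dialect)."""
    df = load_depmap_matrix(path)
    if (df.min(numeric_only=True) < 0).any():
        raise FormatError(f"{path}: negative expression values; expected log2(TPM+1)")
    return df


_DEFAULT_MUTATION_COLUMNS = {
    "cell_line": "cell_line",
    "gene": "gene",
    "is_silent": "is_silent",
    "is_deleterious": "is_deleterious",
    "is_hotspot": "is_hotspot",
}


def load_mutation_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Mutation table with boolean silent/deleterious/hotspot flags.

    ``column_map`` maps the canonical names to a source dialect's column
    names (e.g. DepMap's ``DepMap_ID``/``Hugo_Symbol``/...).
    """
    mapping = dict(_DEFAULT_MUTATION_COLUMNS)
    if column_map:
        mapping.update(column_map)
    df = pd.read_csv(path)
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mutation column(s): {missing}")
    out = pd.DataFrame({canon: df[src] for canon, src in mapping.items()})
    for flag in ("is_silent", "is_deleterious", "is_hotspot"):
        out[flag] = out[flag].map(
            {True: True, False: False, "true": True, "false": False,
             "True": True, "False": False, 1: True, 0: False}
        )
        if out[flag].isna().any():
            raise FormatError(f"{path}: non-boolean values in {flag}")
    out["gene"] = out["gene"].astype(str).str.strip().str.upper()
    return out


def mutation_records(table: pd.DataFrame) -> list[MutationRecord]:
    return [
        MutationRecord(
            cell_line=str(r.cell_line), gene=str(r.gene),
            is_silent=bool(r.is_silent), is_deleterious=bool(r.is_deleterious),
            is_hotspot=bool(r.is_hotspot),
        )
        for r in table.itertuples(index=False)
    ]


def load_gene_list(path: str | Path, known_genes: Sequence[str] | None = None) -> list[str]:
    """One gene symbol per line; unmatched symbols are dropped with a log note."""
    symbols = [ln.strip().upper() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not symbols:
        raise EmptyInputError(f"{path}: empty gene list")
    if known_genes is not None:
        known = set(known_genes)
        dropped = [s for s in symbols if s not in known]
        if dropped:
            logger.info("%s: dropped %d unmatched symbol(s)", path, len(dropped))
        symbols = [s for s in symbols if s in known]
    seen: set[str] = set()
    unique = [s for s in symbols if not (s in seen or seen.add(s))]
    return unique
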