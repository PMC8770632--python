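"""Build a focal-gene-centered interaction network from a STRING-dialect edge list.

The pipeline is: parse protein-protein interactions, map proteins to gene
symbols (averaging duplicate scores between the same gene pair), discard
edges below a score percentile, and restrict the graph to the focal gene,
its direct partners (shell 1) and their partners (shell 2).
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    EmptyNetworkError,
    FormatError,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RawInteraction",
    "InteractionTable",
    "InteractionNetwork",
    "read_interactions",
    "read_aliases",
    "map_and_merge",
    "threshold_edges",
    "shell_restrict",
    "build_network",
]


@dataclass(frozen=True)
class RawInteraction:
    """One protein-protein interaction with its confidence score."""

    protein_a: str
    protein_b: str
    score: float


@dataclass
class InteractionTable:
    """Parsed interactions plus parse provenance.

    ``scale`` is ``"0-1000"`` (STRING combined_score convention) when any
    score exceeds 1, else ``"0-1"``.
    """

    records: list[RawInteraction]
    scale: str
    rejected_rows: list[int] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_rows)


def read_interactions(path: str | Path, dialect: str = "string_tsv") -> InteractionTable:
    """Parse a STRING-links-dialect file (protein1, protein2, combined_score).

    The file is space- or tab-separated with a header row. Malformed rows
    (wrong field count, non-numeric score) are rejected individually and
    logged with their 1-based row numbers; the remaining rows are kept.
    """
    if dialect != "string_tsv":
        raise ParameterError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: file is empty")
    header = lines[0].split()
    cols = {name.strip().lower(): i for i, name in enumerate(header)}
    required = ("protein1", "protein2", "combined_score")
    missing = [c for c in required if c not in cols]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; expected header "
            f"with columns {list(required)}"
        )
    ia, ib, isc = (cols[c] for c in required)
    records: list[RawInteraction] = []
    rejected: list[int] = []
    for row_no, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) < len(header):
            rejected.append(row_no)
            continue
        try:
            score = float(fields[isc])
        except ValueError:
            rejected.append(row_no)
            continue
        if score < 0:
            rejected.append(row_no)
            continue
        records.append(RawInteraction(fields[ia], fields[ib], score))
    if rejected:
        logger.warning("%s: rejected %d malformed row(s): %s", path, len(rejected), rejected)
    if not records:
        raise EmptyInputError(f"{path}: no parsable interaction rows")
    scale = "0-1000" if max(r.score for r in records) > 1 else "0-1"
    return InteractionTable(records=records, scale=scale, rejected_rows=rejected)


def _normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def read_aliases(path: str | Path) -> dict[str, str]:
    """Parse a STRING-aliases-dialect file into protein -> gene symbol.

    Columns: protein, alias, source (whitespace-separated, header present).
    The first-listed alias per protein wins; symbols are uppercased and
    whitespace-trimmed.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: file is empty")
    aliases: dict[str, str] = {}
    for line in lines[1:]:
        fields = line.split()
        if len(fields) < 2:
            continue
        protein, alias = fields[0], _normalize_symbol(fields[1])
        if protein not in aliases and alias:
            aliases[protein] = alias
    if not aliases:
        raise EmptyInputError(f"{path}: no alias rows")
    return aliases


def map_and_merge(table: InteractionTable | list[RawInteraction], aliases: dict[str, str]) -> pd.DataFrame:
    """Collapse protein interactions to a gene-level weighted edge list.

    Scores between the same unordered gene pair are replaced by their
    arithmetic mean; self-loops (both proteins mapping to the same gene)
    are removed and proteins without an alias are dropped. Weights are
    normalized to [0, 1] (scores on the 0-1000 scale are divided by 1000).

    Returns a DataFrame with columns ``gene_a``, ``gene_b`` (gene_a <
    gene_b), ``weight``; drop counts are recorded in ``DataFrame.attrs``.
    """
    if not aliases:
        raise ParameterError("alias map is empty")
    if isinstance(table, InteractionTable):
        records, scale = table.records, table.scale
    else:
        records = list(table)
        scale = "0-1000" if records and max(r.score for r in records) > 1 else "0-1"
    denom = 1000.0 if scale == "0-1000" else 1.0
    norm_aliases = {p: _normalize_symbol(g) for p, g in aliases.items()}
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    n_unmapped = 0
    n_self = 0
    for rec in records:
        ga = norm_aliases.get(rec.protein_a)
        gb = norm_aliases.get(rec.protein_b)
        if ga is None or gb is None:
            n_unmapped += 1
            continue
        if ga == gb:
            n_self += 1
            continue
        key = (ga, gb) if ga < gb else (gb, ga)
        sums[key] = sums.get(key, 0.0) + rec.score / denom
        counts[key] = counts.get(key, 0) + 1
    if not sums:
        raise EmptyNetworkError("no mappable gene-level interactions remain")
    keys = sorted(sums)
    edges = pd.DataFrame(
        {
            "gene_a": [k[0] for k in keys],
            "gene_b": [k[1] for k in keys],
            "weight": [sums[k] / counts[k] for k in keys],
        }
    )
    edges.attrs["n_dropped_unmapped"] = n_unmapped
    edges.attrs["n_self_loops_removed"] = n_self
    edges.attrs["score_scale"] = scale
    if n_unmapped:
        logger.warning("dropped %d interaction(s) with unmapped proteins", n_unmapped)
    return edges


def threshold_edges(edges: pd.DataFrame, percentile: float) -> pd.DataFrame:
    """Keep edges whose weight is >= the given percentile of all edge weights.

    The percentile uses linear interpolation between order statistics
    (numpy's default), and ties at the threshold survive (only scores
    strictly below the percentile are discarded).
    """
    if not 0 < percentile < 100:
        raise ParameterError(f"percentile must be in (0, 100), got {percentile}")
    if len(edges) == 0:
        raise EmptyNetworkError("no edges to threshold")
    threshold = float(np.percentile(edges["weight"].to_numpy(), percentile))
    kept = edges[edges["weight"] >= threshold].reset_index(drop=True)
    kept.attrs.update(edges.attrs)
    kept.attrs["score_threshold"] = threshold
    kept.attrs["score_percentile"] = percentile
    return kept


@dataclass
class InteractionNetwork:
    """Gene-level weighted undirected network centered on a focal gene.

    ``shell`` maps each gene to its breadth-first distance from the focal
    gene (0 = focal, 1 = direct partner, 2 = partner of a partner).
    """

    genes: list[str]
    edges: pd.DataFrame  # columns gene_a, gene_b, weight; gene_a < gene_b
    focal_gene: str
    shell: dict[str, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.focal_gene not in self.shell:
            raise ValueError("focal gene missing from shell map")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, weight=row.weight)
        return g

    def adjacency(self, mode: str = "binary") -> tuple[np.ndarray, list[str]]:
        """Dense adjacency matrix in the network's deterministic gene order."""
        if mode not in ("binary", "weighted"):
            raise ParameterError(f"unknown adjacency mode: {mode!r}")
        index = {g: i for i, g in enumerate(self.genes)}
        n = len(self.genes)
        a = np.zeros((n, n))
        for row in self.edges.itertuples(index=False):
            w = 1.0 if mode == "binary" else float(row.weight)
            i, j = index[row.gene_a], index[row.gene_b]
            a[i, j] = a[j, i] = w
        return a, list(self.genes)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.edges.to_csv(directory / "network_edges.tsv", sep="\t", index=False)
        sidecar = {
            "focal_gene": self.focal_gene,
            "genes": self.genes,
            "shell": self.shell,
            "provenance": self.provenance,
        }
        (directory / "network.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "InteractionNetwork":
        directory = Path(directory)
        edges = pd.read_csv(directory / "network_edges.tsv", sep="\t")
        if len(edges) == 0:
            edges = pd.DataFrame(columns=["gene_a", "gene_b", "weight"])
        meta = json.loads((directory / "network.json").read_text())
        return cls(
            genes=list(meta["genes"]),
            edges=edges,
            focal_gene=meta["focal_gene"],
            shell={g: int(s) for g, s in meta["shell"].items()},
            provenance=meta.get("provenance", {}),
        )


def shell_restrict(edges: pd.DataFrame, focal: str, shells: int = 2) -> InteractionNetwork:
    """Restrict the edge list to genes within ``shells`` BFS steps of ``focal``.

    Edges are retained iff both endpoints remain; gene order is
    lexicographic. An isolated focal gene yields a single-node network
    with a warning.
    """
    if shells < 1:
        raise ParameterError("shells must be >= 1")
    focal = _normalize_symbol(focal)
    adj: dict[str, set[str]] = {}
    for row in edges.itertuples(index=False):
        adj.setdefault(row.gene_a, set()).add(row.gene_b)
        adj.setdefault(row.gene_b, set()).add(row.gene_a)
    shell = {focal: 0}
    queue: deque[str] = deque([focal])
    while queue:
        gene = queue.popleft()
        dist = shell[gene]
        if dist >= shells:
            continue
        for nbr in adj.get(gene, ()):
            if nbr not in shell:
                shell[nbr] = dist + 1
                queue.append(nbr)
    if len(shell) == 1:
        logger.warning("focal gene %s has no retained interactions", focal)
    keep = set(shell)
    mask = edges["gene_a"].isin(keep) & edges["gene_b"].isin(keep)
    kept = edges[mask].reset_index(drop=True)
    provenance = dict(edges.attrs)
    provenance.update({"shells": shells, "n_genes": len(shell), "n_edges": len(kept)})
    return InteractionNetwork(
        genes=sorted(shell),
        edges=kept,
        focal_gene=focal,
        shell=shell,
        provenance=provenance,
    )


def build_network(
    edges_path: str | Path,
    aliases_path: str | Path,
    focal: str,
    score_percentile: float = 90.0,
    shells: int = 2,
) -> InteractionNetwork:
    """Full construction pipeline: parse, map, threshold, shell-restrict."""
    table = read_interactions(edges_path)
    aliases = read_aliases(aliases_path)
    edges = map_and_merge(table, aliases)
    edges = threshold_edges(edges, score_percentile)
    return shell_restrict(edges, focal, shells)
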