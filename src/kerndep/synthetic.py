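"""Synthetic STRING/DepMap-shaped data with planted predictive structure.

The generator emits a self-consistent bundle — protein-protein edge list
with confidence scores, protein->gene alias map, log2(TPM+1) expression
matrix, gene-effect and dependency-probability matrices, mutation table and
copy-number matrix — in the exact dialects the pipeline loaders accept, so
the whole workflow (network construction, kernel centrality, selection,
ensemble modeling, cohort classification) runs end to end with no external
download.

Planted structure: a configurable number of "planted" genes sit in shell 1
of the focal gene with top-decile interaction scores (so they survive the
90th-percentile edge filter), and the focal gene's knockout effect is a
weighted sum of their standardized expression plus a mutation shift and
Gaussian noise. Noise is calibrated by a target R^2 rather than a raw SD,
so the expected recoverable signal is scale-free. Following the DepMap
sign convention, more-negative gene effect means stronger dependency, and
the dependency probability is a steep logistic of the (negated, centered)
effect so roughly the most-dependent quarter of lines crosses the 0.5
dependency call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ParameterError, ValidationError

__all__ = ["SimulationConfig", "SyntheticBundle", "simulate_network",
           "simulate_expression", "simulate_dependency",
           "simulate_mutations_and_cn", "make_bundle", "write_bundle",
           "load_bundle"]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions.

    200 cell lines and a 500-gene network with 5 planted predictors at a
    designed R^2 of 0.5 are the conditions under which the recovery,
    exclusion and null properties of the pipeline are stated.
    """

    n_genes: int = 500
    n_cells: int = 200
    topology: str = "two_shell_planted"  # or "preferential_attachment"
    focal_gene: str = "KRAS"
    n_planted: int = 5
    n_shell1: int = 50  # shell-1 size for two_shell_planted (includes planted)
    effect_weights: tuple[float, ...] = (-1.0, -0.8, 0.6, -0.5, 0.4)
    target_r2: float = 0.5
    noise_sd: float | None = None  # overrides target_r2 when set
    adjacent_rho: float = 0.1  # latent-sharing weight; adjacent corr ~ sqrt(rho(1-rho))
    low_expression_fraction: float = 0.15
    missing_fraction: float = 0.0
    mutation_rate: float = 0.15
    hotspot_fraction: float = 0.8
    mutation_effect: float = -1.0
    n_amplified: int = 10
    amplified_copy_number: float = 9.0
    dependent_quantile: float = 0.25  # effect quantile mapped to prob 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 5:
            raise ParameterError("n_genes must be >= 5")
        if self.n_planted > self.n_genes - 1:
            raise ParameterError("more planted genes than available nodes")
        if self.topology not in ("two_shell_planted", "preferential_attachment"):
            raise ParameterError(f"unknown topology: {self.topology!r}")
        if self.topology == "two_shell_planted" and self.n_planted > self.n_shell1:
            raise ParameterError("planted genes exceed shell-1 slots")
        for rate in (self.low_expression_fraction, self.missing_fraction,
                     self.mutation_rate, self.hotspot_fraction):
            if not 0 <= rate <= 1:
                raise ParameterError("rates must be in [0, 1]")
        if len(self.effect_weights) != self.n_planted:
            raise ParameterError("effect_weights length must equal n_planted")


@dataclass
class SyntheticBundle:
    """All generated tables plus the ground truth needed to audit them."""

    config: SimulationConfig
    edges: pd.DataFrame  # protein1, protein2, combined_score
    aliases: pd.DataFrame  # protein, alias, source
    expression: pd.DataFrame  # cell line x gene, log2(TPM+1)
    gene_effect: pd.DataFrame  # cell line x gene
    dependency_prob: pd.DataFrame  # cell line x gene in [0, 1]
    mutations: pd.DataFrame  # cell_line, gene, is_silent, is_deleterious, is_hotspot
    copy_number: pd.DataFrame  # cell line x gene, linear scale
    ground_truth: dict = field(default_factory=dict)


def _gene_names(config: SimulationConfig) -> list[str]:
    others = [f"SYN{i:04d}" for i in range(1, config.n_genes)]
    return [config.focal_gene] + others


def _protein_id(gene: str) -> str:
    return f"9606.ENSP_{gene}"


def simulate_network(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Edge list + alias map; returns (edges, aliases, truth) where truth
    records gene names, planted genes and the backbone parent map.

    ``two_shell_planted`` builds a spanning backbone (focal -> shell 1 ->
    shell 2) whose edges score in the top decile (>= 900 on the 0-1000
    scale) and adds nine filler edges per backbone edge scoring below 890,
    so the 90th-percentile filter retains exactly the backbone and the
    planted genes stay in shell 1. ``preferential_attachment`` grows a
    Barabasi-Albert graph with uniform scores.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    genes = _gene_names(config)
    focal = genes[0]
    planted = genes[1:1 + config.n_planted]
    parent: dict[str, str] = {}
    backbone: list[tuple[str, str]] = []
    if config.topology == "two_shell_planted":
        n_shell1 = min(config.n_shell1, config.n_genes - 1)
        shell1 = genes[1:1 + n_shell1]
        shell2 = genes[1 + n_shell1:]
        for g in shell1:
            backbone.append((focal, g))
            parent[g] = focal
        # planted genes are dedicated focal partners (no shell-2 children),
        # which keeps them kernel-central across the beta schedule
        shell2_parents = shell1[config.n_planted:]
        if shell2 and not shell2_parents:
            raise ParameterError("two_shell_planted needs non-planted shell-1 genes "
                                 "to host shell 2; increase n_shell1")
        for g in shell2:
            p = shell2_parents[int(rng.integers(len(shell2_parents)))]
            backbone.append((p, g))
            parent[g] = p
    else:
        g = nx.barabasi_albert_graph(config.n_genes, m=2, seed=int(rng.integers(2**31 - 1)))
        mapping = dict(enumerate(genes))
        tree = nx.bfs_tree(g, 0)
        for u, v in tree.edges():
            parent[mapping[v]] = mapping[u]
        backbone = [(mapping[u], mapping[v]) for u, v in g.edges()]
    edges: list[tuple[str, str, int]] = []
    for a, b in backbone:
        lo, hi = (950, 1000) if focal in (a, b) and (a in planted or b in planted) else (900, 1000)
        edges.append((a, b, int(rng.integers(lo, hi + 1))))
    if config.topology == "two_shell_planted":
        existing = {frozenset((a, b)) for a, b, _ in edges}
        n_filler = 9 * len(backbone)
        while n_filler > 0:
            i, j = rng.integers(0, config.n_genes, size=2)
            if i == j:
                continue
            key = frozenset((genes[i], genes[j]))
            if key in existing:
                continue
            existing.add(key)
            edges.append((genes[i], genes[j], int(rng.integers(150, 891))))
            n_filler -= 1
    edge_df = pd.DataFrame(
        {
            "protein1": [_protein_id(a) for a, _, _ in edges],
            "protein2": [_protein_id(b) for _, b, _ in edges],
            "combined_score": [s for _, _, s in edges],
        }
    )
    alias_df = pd.DataFrame(
        {"protein": [_protein_id(g) for g in genes], "alias": genes,
         "source": ["synthetic"] * len(genes)}
    )
    truth = {"genes": genes, "focal_gene": focal, "planted_genes": planted,
             "parent": parent}
    return edge_df, alias_df, truth


def simulate_expression(truth: dict, config: SimulationConfig) -> pd.DataFrame:
    """Cell line x gene expression on the log2(TPM+1) scale.

    Per-gene right-skewed baselines (gamma), adjacent-gene correlation via
    a shared parent latent (child = sqrt(1-rho)*own + sqrt(rho)*parent's
    latent), a low-expression gene fraction to exercise the expression
    filter, and optional NaN injection. Planted genes are kept out of the
    low-expression set so the planted signal is observable.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    genes: list[str] = truth["genes"]
    planted = set(truth["planted_genes"])
    parent: dict[str, str] = truth["parent"]
    n_g, n_c = len(genes), config.n_cells
    cells = [f"SYN-{i:06d}" for i in range(1, n_c + 1)]
    baseline = rng.gamma(shape=2.0, scale=1.7, size=n_g)
    sd = rng.uniform(0.5, 1.5, size=n_g)
    eligible_low = [i for i, g in enumerate(genes)
                    if g not in planted and g != truth["focal_gene"]]
    n_low = int(round(config.low_expression_fraction * n_g))
    low_idx = rng.choice(eligible_low, size=min(n_low, len(eligible_low)), replace=False)
    baseline[low_idx] = rng.uniform(0.0, 0.05, size=len(low_idx))
    sd[low_idx] = 0.02
    for i, g in enumerate(genes):
        if g in planted:
            baseline[i] = max(baseline[i], 4.0)
    z = rng.standard_normal((n_c, n_g))  # per-gene latents
    idx = {g: i for i, g in enumerate(genes)}
    rho = config.adjacent_rho
    signal = np.array(z)
    for g, p in parent.items():
        signal[:, idx[g]] = (np.sqrt(1 - rho) * z[:, idx[g]]
                             + np.sqrt(rho) * z[:, idx[p]])
    values = baseline + sd * signal
    np.clip(values, 0.0, None, out=values)
    expr = pd.DataFrame(values, index=cells, columns=genes)
    if config.missing_fraction > 0:
        mask = rng.random(values.shape) < config.missing_fraction
        expr = expr.mask(mask)
    return expr


def simulate_dependency(
    expression: pd.DataFrame, truth: dict, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Gene-effect and dependency-probability matrices with ground truth.

    The focal gene's effect is sum_g w_g * z(expr_g) + mutation_effect*mut
    + noise; noise SD is set from the target R^2 (noise_sd overrides).
    Other genes' effects are independent noise on a comparable scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)))
    genes: list[str] = truth["genes"]
    planted: list[str] = truth["planted_genes"]
    focal = truth["focal_gene"]
    missing = [g for g in planted if g not in expression.columns]
    if missing:
        raise ValidationError(f"planted gene(s) absent from expression: {missing}")
    x = expression[planted].to_numpy(dtype=float)
    x = np.nan_to_num(x, nan=np.nanmean(x))
    mu, sigma = x.mean(axis=0), x.std(axis=0, ddof=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    zx = (x - mu) / sigma
    w = np.asarray(config.effect_weights, dtype=float)
    signal = zx @ w
    mut_flags = truth.get("mutant_cells")
    if mut_flags is not None:
        mut = np.array([c in set(mut_flags) for c in expression.index], dtype=float)
        signal = signal + config.mutation_effect * mut
    sig_sd = float(signal.std(ddof=0))
    if config.noise_sd is not None:
        noise_sd = config.noise_sd
    else:
        r2 = config.target_r2
        noise_sd = sig_sd * np.sqrt((1 - r2) / r2) if sig_sd > 0 else 1.0
    y = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    n_c = expression.shape[0]
    effects = rng.normal(0.0, max(noise_sd, 1e-12), size=(n_c, len(genes)))
    effect = pd.DataFrame(effects, index=expression.index, columns=genes)
    effect[focal] = y
    # steep logistic of the negated, centered effect: the most-dependent
    # `dependent_quantile` tail of each gene crosses probability 0.5
    prob = {}
    for g in genes:
        col = effect[g].to_numpy()
        center = np.quantile(col, config.dependent_quantile)
        scale = max(col.std(ddof=0), 1e-12) * 0.15
        prob[g] = expit(-(col - center) / scale)
    prob_df = pd.DataFrame(prob, index=expression.index)[genes]
    truth_out = dict(truth)
    truth_out.update(
        {
            "effect_weights": list(w),
            "noise_sd": float(noise_sd),
            "signal": {c: float(v) for c, v in zip(expression.index, signal)},
            "target_r2": None if config.noise_sd is not None else config.target_r2,
        }
    )
    return effect, prob_df, truth_out


def simulate_mutations_and_cn(
    config: SimulationConfig, cells: Sequence[str], genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Mutation table and copy-number matrix with known mutant/amplified sets.

    Focal-gene activating (non-silent, non-deleterious) mutations hit a
    seeded random subset at ``mutation_rate`` with ``hotspot_fraction``
    flagged as hotspots; silent and deleterious decoys are injected into
    otherwise wild-type lines. Copy numbers center at 2 with
    ``n_amplified`` lines carrying a focal-gene copy number whose relative
    value exceeds 3.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(3,)))
    cells = list(cells)
    genes = list(genes)
    focal = config.focal_gene
    n_mut = int(round(config.mutation_rate * len(cells)))
    order = rng.permutation(len(cells))
    mutant = [cells[i] for i in order[:n_mut]]
    rows = []
    for i, cl in enumerate(mutant):
        hotspot = rng.random() < config.hotspot_fraction
        rows.append((cl, focal, False, False, hotspot))
    # decoys on wild-type lines: silent and deleterious records must not
    # flip the wt call
    wt_pool = [cells[i] for i in order[n_mut:]]
    n_decoy = min(len(wt_pool), max(2, len(cells) // 20))
    for j, cl in enumerate(wt_pool[:n_decoy]):
        if j % 2 == 0:
            rows.append((cl, focal, True, False, False))  # silent
        else:
            rows.append((cl, focal, False, True, False))  # deleterious
    mutations = pd.DataFrame(
        rows, columns=["cell_line", "gene", "is_silent", "is_deleterious", "is_hotspot"]
    )
    cn = rng.normal(2.0, 0.1, size=(len(cells), len(genes)))
    np.clip(cn, 0.1, None, out=cn)
    cn_df = pd.DataFrame(cn, index=cells, columns=genes)
    amp_pool = [c for c in cells]
    amp_idx = rng.choice(len(amp_pool), size=min(config.n_amplified, len(amp_pool)),
                         replace=False)
    amplified = [amp_pool[i] for i in amp_idx]
    cn_df.loc[amplified, focal] = config.amplified_copy_number
    truth = {"mutant_cells": mutant, "amplified_cells": amplified,
             "decoy_cells": wt_pool[:n_decoy]}
    return mutations, cn_df, truth


def make_bundle(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Generate a complete, internally consistent bundle.

    Pure function of (config, seed): the same inputs always return the
    same tables.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": seed})
    edges, aliases, truth = simulate_network(config)
    expression = simulate_expression(truth, config)
    mutations, copy_number, mut_truth = simulate_mutations_and_cn(
        config, list(expression.index), truth["genes"]
    )
    truth.update(mut_truth)
    gene_effect, dependency_prob, truth = simulate_dependency(expression, truth, config)
    return SyntheticBundle(
        config=config, edges=edges, aliases=aliases, expression=expression,
        gene_effect=gene_effect, dependency_prob=dependency_prob,
        mutations=mutations, copy_number=copy_number, ground_truth=truth,
    )


def _matrix_to_depmap(df: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """DepMap column dialect: 'SYMBOL (entrez)' with a synthetic entrez id."""
    renamed = df.copy()
    renamed.columns = [f"{g} ({1000 + i})" for i, g in enumerate(genes)]
    return renamed


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write every table in the dialect its loader expects, plus ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": directory / "protein_links.txt",
        "aliases": directory / "protein_aliases.txt",
        "expression": directory / "expression.csv",
        "gene_effect": directory / "gene_effect.csv",
        "dependency_prob": directory / "dependency_prob.csv",
        "mutations": directory / "mutations.csv",
        "copy_number": directory / "copy_number.csv",
        "ground_truth": directory / "ground_truth.json",
    }
    bundle.edges.to_csv(paths["edges"], sep=" ", index=False)
    bundle.aliases.to_csv(paths["aliases"], sep="\t", index=False)
    genes = bundle.ground_truth["genes"]
    for key in ("expression", "gene_effect", "dependency_prob", "copy_number"):
        df: pd.DataFrame = getattr(bundle, key)
        _matrix_to_depmap(df, genes).to_csv(paths[key], index=True, index_label="")
    bundle.mutations.to_csv(paths["mutations"], index=False)
    truth = dict(bundle.ground_truth)
    truth["config"] = asdict(bundle.config)
    paths["ground_truth"].write_text(json.dumps(truth, indent=1))
    return paths


def load_bundle(directory: str | Path) -> SyntheticBundle:
    """Round-trip loader using the same dialects as the pipeline loaders."""
    from .io import load_depmap_matrix, load_mutation_table

    directory = Path(directory)
    truth = json.loads((directory / "ground_truth.json").read_text())
    config = SimulationConfig(**truth.pop("config"))
    edges = pd.read_csv(directory / "protein_links.txt", sep=r"\s+")
    aliases = pd.read_csv(directory / "protein_aliases.txt", sep="\t")
    load = lambda name: load_depmap_matrix(directory / name)  # noqa: E731
    return SyntheticBundle(
        config=config, edges=edges, aliases=aliases,
        expression=load("expression.csv"),
        gene_effect=load("gene_effect.csv"),
        dependency_prob=load("dependency_prob.csv"),
        mutations=load_mutation_table(directory / "mutations.csv"),
        copy_number=load("copy_number.csv"),
        ground_truth=truth,
    )
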