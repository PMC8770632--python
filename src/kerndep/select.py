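"""Predictor-set construction: expression filtering + top-k kernel centrality.

The selection stage is deliberately unsupervised — no operation here ever
sees the dependency variable. Candidate genes (typically the network's
genes) are reduced in three steps: drop genes with any missing expression,
drop genes whose mean expression across the cohort does not exceed the
configured percentile of the candidates' means, then keep the k genes with
the highest kernel closeness. One (expression percentile, beta, k)
combination defines one predictor set; the default grid (4 percentiles x
5 betas x 3 gene counts) enumerates 60 sets.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .diffusion import DEFAULT_BETA_BASE, DEFAULT_BETA_EXPONENTS, CentralityScores, beta_schedule
from .errors import ParameterError, SelectionError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "PredictorSet",
    "DiffusionKernelSelector",
    "drop_missing",
    "expression_filter",
    "select_predictors",
    "enumerate_grid",
    "DEFAULT_EXPRESSION_PERCENTILES",
    "DEFAULT_GENE_COUNTS",
]

DEFAULT_EXPRESSION_PERCENTILES = (25, 50, 75, 95)
DEFAULT_GENE_COUNTS = (100, 500, 1000)


@dataclass(frozen=True)
class SelectionConfig:
    """One hyperparameter combination of the selection grid."""

    expression_percentile: float
    beta: float
    n_genes: int


@dataclass
class PredictorSet:
    """An ordered gene list plus the configuration/provenance that produced it.

    ``config`` is a :class:`SelectionConfig` for kernel-selected sets or a
    plain name (``all_rna``, ``network_all``, ``signature:<name>``, ``rae``,
    ``mutation``) for the non-kernel comparison sets.
    """

    config: SelectionConfig | str
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("predictor set contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def drop_missing(expr: pd.DataFrame, genes: Sequence[str]) -> list[str]:
    """Genes present in the expression matrix with zero missing entries."""
    present = [g for g in genes if g in expr.columns]
    if not present:
        return []
    complete = expr[present].notna().all(axis=0)
    return [g for g in present if complete[g]]


def expression_filter(expr: pd.DataFrame, genes: Sequence[str], percentile: float) -> list[str]:
    """Genes whose mean expression strictly exceeds the given percentile.

    The reference distribution is the per-gene mean (over cohort cell
    lines) of the input genes themselves; the percentile uses linear
    interpolation. With all-equal summaries the strict rule empties the
    result and a warning is emitted.
    """
    if len(genes) == 0:
        raise ValidationError("gene list for expression filter is empty")
    summaries = expr[list(genes)].mean(axis=0)
    threshold = float(np.percentile(summaries.to_numpy(), percentile))
    kept = [g for g in genes if summaries[g] > threshold]
    if not kept:
        warnings.warn(
            "expression filter removed every gene (all summaries <= threshold)",
            stacklevel=2,
        )
    return kept


def select_predictors(
    centrality: CentralityScores | Mapping[str, float],
    eligible: Sequence[str],
    k: int,
) -> PredictorSet:
    """The k highest-closeness eligible genes, ties broken lexicographically."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if len(eligible) == 0:
        raise SelectionError("eligible gene set is empty")
    scores = centrality.scores if isinstance(centrality, CentralityScores) else pd.Series(centrality)
    missing = [g for g in eligible if g not in scores.index]
    if missing:
        raise SelectionError(f"eligible genes missing centrality scores: {missing[:5]}")
    ranked = sorted(eligible, key=lambda g: (-float(scores[g]), g))
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} eligible genes for k={k}; returning all",
            stacklevel=2,
        )
    chosen = ranked[:k]
    provenance = {"k": k, "n_eligible": len(eligible), "shortfall": len(ranked) < k}
    if isinstance(centrality, CentralityScores):
        provenance.update(
            {"beta": centrality.beta, "method": centrality.method, "focal": centrality.focal_gene}
        )
    return PredictorSet(config=f"topk:{k}", genes=chosen, provenance=provenance)


def enumerate_grid(
    percentiles: Sequence[float] = DEFAULT_EXPRESSION_PERCENTILES,
    betas: Sequence[float] | None = None,
    ks: Sequence[int] = DEFAULT_GENE_COUNTS,
) -> list[SelectionConfig]:
    """Cartesian hyperparameter grid, percentile-major then beta then k."""
    if betas is None:
        betas = beta_schedule(DEFAULT_BETA_BASE, DEFAULT_BETA_EXPONENTS)
    if not (len(percentiles) and len(betas) and len(ks)):
        raise ParameterError("all grid dimensions must be nonempty")
    return [
        SelectionConfig(expression_percentile=p, beta=b, n_genes=k)
        for p, b, k in itertools.product(percentiles, betas, ks)
    ]


class DiffusionKernelSelector(SelectorMixin, BaseEstimator):
    """Unsupervised feature selector: expression filter + top-k kernel closeness.

    Parameters
    ----------
    centrality : CentralityScores or mapping gene -> closeness
        Kernel-derived closeness for the candidate genes.
    candidate_genes : sequence of str, optional
        Genes to consider; defaults to every scored gene present in X.
    expression_percentile : float, default 25
        Minimum-mean-expression percentile (strict >) over the candidates.
    n_genes : int, default 500
        Number of genes kept by closeness ranking.

    ``fit`` expects a cell line x gene expression DataFrame (the dependency
    variable is never consulted). After fitting, ``selected_genes_`` holds
    the ordered predictor set and ``get_support``/``transform`` behave like
    any scikit-learn feature selector.
    """

    def __init__(
        self,
        centrality: CentralityScores | Mapping[str, float] | None = None,
        candidate_genes: Sequence[str] | None = None,
        expression_percentile: float = 25.0,
        n_genes: int = 500,
    ):
        self.centrality = centrality
        self.candidate_genes = candidate_genes
        self.expression_percentile = expression_percentile
        self.n_genes = n_genes

    def fit(self, X: pd.DataFrame, y=None) -> "DiffusionKernelSelector":
        if self.centrality is None:
            raise ParameterError("centrality scores are required")
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a cell line x gene DataFrame with gene columns")
        scores = (
            self.centrality.scores
            if isinstance(self.centrality, CentralityScores)
            else pd.Series(self.centrality)
        )
        if self.candidate_genes is not None:
            candidates = [g for g in self.candidate_genes if g in scores.index]
        else:
            candidates = [g for g in X.columns if g in scores.index]
        complete = drop_missing(X, candidates)
        if not complete:
            raise SelectionError("no candidate genes with complete expression")
        expressed = expression_filter(X, complete, self.expression_percentile)
        if not expressed:
            raise SelectionError("expression filter removed every candidate gene")
        pset = select_predictors(self.centrality, expressed, self.n_genes)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.selected_genes_ = list(pset.genes)
        selected = set(self.selected_genes_)
        self.support_ = np.array([g in selected for g in X.columns])
        self.predictor_set_ = PredictorSet(
            config=f"kernel:p{self.expression_percentile}:k{self.n_genes}",
            genes=list(pset.genes),
            provenance={
                "n_candidates": len(candidates),
                "n_complete": len(complete),
                "n_expressed": len(expressed),
                **pset.provenance,
            },
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise ValidationError("selector is not fitted")
        return self.support_

    def build_predictor_set(self, X: pd.DataFrame, config: SelectionConfig) -> PredictorSet:
        """Apply one grid configuration (centrality must match config.beta)."""
        self.expression_percentile = config.expression_percentile
        self.n_genes = config.n_genes
        self.fit(X)
        pset = self.predictor_set_
        pset.config = config
        return pset
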