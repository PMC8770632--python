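"""Diffusion (heat) kernel over the interaction network and kernel centrality.

The kernel is K = exp(beta * H), the matrix exponential of beta times the
negative graph Laplacian H = -(D - A). Because H is symmetric with zero row
sums, K is a symmetric stochastic matrix: K[i, j] is the fraction of heat
(or the probability mass of a continuous-time random walk) that flows from
node i to node j in "time" beta. Centrality of a gene is read off the
kernel, either as the focal gene's row (information flow from the focal
gene) or as a closeness over kernel-induced distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .net_build import InteractionNetwork

__all__ = [
    "KernelMatrix",
    "CentralityScores",
    "negative_laplacian",
    "diffusion_kernel",
    "kernel_series",
    "beta_schedule",
    "kernel_centrality",
]

DEFAULT_BETA_BASE = 0.75
DEFAULT_BETA_EXPONENTS = (1, 5, 10, 20, 30)


@dataclass
class KernelMatrix:
    """Dense diffusion kernel with its node order and parameters."""

    K: np.ndarray
    beta: float
    node_order: list[str]
    laplacian_mode: str = "binary"

    def __post_init__(self) -> None:
        k = self.K
        n = len(self.node_order)
        if k.shape != (n, n):
            raise ValidationError("kernel shape does not match node order")
        if not np.allclose(k, k.T, atol=1e-8):
            raise ValidationError("kernel is not symmetric")
        if k.min() < -1e-10:
            raise ValidationError("kernel has negative entries beyond tolerance")
        if not np.allclose(k.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("kernel rows do not sum to 1")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.node_order.index(pair[0])
        j = self.node_order.index(pair[1])
        return float(self.K[i, j])


@dataclass
class CentralityScores:
    """Per-gene closeness derived from a diffusion kernel."""

    scores: pd.Series  # index = gene, deterministic order
    method: str
    beta: float
    focal_gene: str | None = None
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, gene: str) -> float:
        return float(self.scores[gene])


def negative_laplacian(network: InteractionNetwork, mode: str = "binary") -> np.ndarray:
    """H = -(D - A) for the binary or weight-valued adjacency A."""
    if network.n_genes < 1:
        raise ValidationError("network has no genes")
    a, _ = network.adjacency(mode)  # raises ParameterError on unknown mode
    d = np.diag(a.sum(axis=1))
    return a - d


def diffusion_kernel(h: np.ndarray, beta: float, node_order: list[str] | None = None,
                     laplacian_mode: str = "binary") -> KernelMatrix:
    """K = exp(beta * H) via symmetric eigendecomposition.

    Exact to machine precision for symmetric H; tiny negative round-off
    entries are clipped to zero (they never exceed 1e-10 in magnitude).
    """
    if beta <= 0:
        raise ParameterError("beta must be > 0")
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValidationError("H must be square")
    if not np.allclose(h, h.T, atol=1e-8):
        raise ValidationError("H must be symmetric")
    w, v = np.linalg.eigh(h)
    k = (v * np.exp(beta * w)) @ v.T
    k = (k + k.T) / 2.0
    np.clip(k, 0.0, None, out=k)
    if node_order is None:
        node_order = [str(i) for i in range(h.shape[0])]
    return KernelMatrix(K=k, beta=beta, node_order=list(node_order),
                        laplacian_mode=laplacian_mode)


def kernel_series(h: np.ndarray, beta: float, terms: int = 60) -> np.ndarray:
    """Truncated power series I + beta*H + (beta^2/2!)H^2 + ... .

    Retained as an independent cross-check of the eigendecomposition path;
    not used by the pipeline itself.
    """
    h = np.asarray(h, dtype=float)
    n = h.shape[0]
    out = np.eye(n)
    term = np.eye(n)
    for m in range(1, terms):
        term = term @ (beta * h) / m
        out = out + term
    return out


def beta_schedule(base: float = DEFAULT_BETA_BASE,
                  exponents: tuple[int, ...] | list[int] = DEFAULT_BETA_EXPONENTS) -> list[float]:
    """The tested diffusion extents: base**n for each exponent n, in order."""
    if not 0 < base < 1:
        raise ParameterError("base must be in (0, 1)")
    if any(n <= 0 for n in exponents):
        raise ParameterError("exponents must be positive")
    return [base ** n for n in exponents]


def kernel_centrality(kernel: KernelMatrix, focal: str, method: str = "focal_row") -> CentralityScores:
    """Derive per-gene closeness from the kernel.

    ``focal_row``: closeness(i) = K[focal, i] for i != focal — the heat the
    focal gene sends to each gene. ``kernel_distance_closeness``:
    closeness(i) = 1 / sum_j d(i, j) with the kernel-induced distance
    d(i, j) = sqrt(K_ii + K_jj - 2 K_ij), defined for every gene.
    """
    if focal not in kernel.node_order:
        raise KeyError(f"focal gene {focal!r} not in kernel node order")
    order = kernel.node_order
    fi = order.index(focal)
    if method == "focal_row":
        genes = [g for g in order if g != focal]
        vals = [float(kernel.K[fi, order.index(g)]) for g in genes]
        scores = pd.Series(vals, index=genes, name="closeness")
    elif method == "kernel_distance_closeness":
        k = kernel.K
        diag = np.diag(k)
        sq = diag[:, None] + diag[None, :] - 2 * k
        np.clip(sq, 0.0, None, out=sq)
        dist = np.sqrt(sq)
        totals = dist.sum(axis=1)
        with np.errstate(divide="ignore"):
            closeness = np.where(totals > 0, 1.0 / totals, np.inf)
        scores = pd.Series(closeness, index=order, name="closeness")
    else:
        raise ParameterError(f"unknown centrality method: {method!r}")
    return CentralityScores(
        scores=scores,
        method=method,
        beta=kernel.beta,
        focal_gene=focal,
        provenance={"laplacian_mode": kernel.laplacian_mode},
    )
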