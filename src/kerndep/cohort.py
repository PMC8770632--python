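"""Cell-line cohort classification and binary predictor encoding.

Classification rules:

* wild-type vs mutant for a gene: a line is mutant iff it carries at least
  one non-silent, non-deleterious mutation in that gene (the pattern of a
  typical activating hotspot variant).
* dependent vs independent: dependency probability strictly above 0.5.
* amplified: relative copy number (gene copy number divided by the mean
  copy number over all genes of the same sample) strictly above 3.
* RAS-activating-event (RAE) markers: binary co-dependency calls on a
  configured marker gene list plus the focal-gene amplification flag.
* mutation predictors: three binary indicators (deleterious / hotspot /
  other), with hotspot and other restricted to non-silent, non-deleterious
  variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LookupError_, ValidationError

__all__ = [
    "MutationRecord",
    "classify_mutation_status",
    "classify_dependent",
    "relative_copy_number",
    "classify_amplified",
    "build_rae_matrix",
    "encode_mutation_predictors",
    "compare_groups",
]

DEPENDENCY_THRESHOLD = 0.5
AMPLIFICATION_THRESHOLD = 3.0


@dataclass(frozen=True)
class MutationRecord:
    """One mutation call for one cell line and gene."""

    cell_line: str
    gene: str
    is_silent: bool = False
    is_deleterious: bool = False
    is_hotspot: bool = False

    def __post_init__(self) -> None:
        if self.is_hotspot and self.is_silent:
            raise ValidationError(
                f"{self.cell_line}/{self.gene}: a silent variant cannot be a hotspot"
            )


def _activating(rec: MutationRecord) -> bool:
    return not rec.is_silent and not rec.is_deleterious


def classify_mutation_status(
    records: Iterable[MutationRecord], gene: str, cell_lines: Sequence[str]
) -> pd.Series:
    """Label every cohort line ``"mut"`` or ``"wt"`` for ``gene``.

    Mutant iff the line has >= 1 non-silent, non-deleterious record for the
    gene; lines absent from the records are wild-type.
    """
    gene = gene.upper()
    mutated = {
        r.cell_line for r in records if r.gene.upper() == gene and _activating(r)
    }
    return pd.Series(
        ["mut" if cl in mutated else "wt" for cl in cell_lines],
        index=list(cell_lines),
        name=f"{gene}_status",
    )


def classify_dependent(prob: float, threshold: float = DEPENDENCY_THRESHOLD) -> str:
    """``"dependent"`` iff prob is strictly above the threshold."""
    if not 0 <= prob <= 1:
        raise ValidationError(f"dependency probability must be in [0, 1], got {prob}")
    return "dependent" if prob > threshold else "independent"


def relative_copy_number(cn_row: pd.Series, gene: str) -> float:
    """Gene copy number divided by the sample's mean copy number.

    NaN entries are excluded from the mean.
    """
    if gene not in cn_row.index:
        raise LookupError_(f"gene {gene!r} absent from copy-number row")
    mean = float(cn_row.mean(skipna=True))
    if not mean > 0:
        raise ValidationError(f"non-positive mean copy number: {mean}")
    return float(cn_row[gene]) / mean


def classify_amplified(rel_cn: float, threshold: float = AMPLIFICATION_THRESHOLD) -> bool:
    """Amplified iff the relative copy number strictly exceeds the threshold."""
    return rel_cn > threshold


def build_rae_matrix(
    dependency_prob: pd.DataFrame,
    marker_genes: Sequence[str],
    amplification: pd.Series,
    threshold: float = DEPENDENCY_THRESHOLD,
) -> pd.DataFrame:
    """Binary cell line x marker matrix of RAS-activating events.

    One column per marker gene (dependency probability > threshold) plus a
    final ``amplification`` column; a derived boolean ``has_rae`` column
    flags lines with any marker set (it is not counted as a marker).
    """
    missing = [g for g in marker_genes if g not in dependency_prob.columns]
    if missing:
        raise LookupError_(f"marker gene(s) absent from dependency matrix: {missing}")
    out = pd.DataFrame(index=dependency_prob.index)
    for g in marker_genes:
        probs = dependency_prob[g]
        bad = probs.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValidationError(f"dependency probabilities for {g} outside [0, 1]")
        out[g] = (probs > threshold).astype(int)
    out["amplification"] = amplification.reindex(dependency_prob.index).fillna(False).astype(int)
    out["has_rae"] = (out.sum(axis=1) > 0)
    return out


def encode_mutation_predictors(
    records: Iterable[MutationRecord], gene: str, cell_lines: Sequence[str]
) -> pd.DataFrame:
    """Three binary mutation-status predictors per cell line.

    ``deleterious``: any deleterious record; ``hotspot``: any non-silent,
    non-deleterious hotspot record; ``other``: any non-silent,
    non-deleterious, non-hotspot record.
    """
    gene = gene.upper()
    out = pd.DataFrame(
        0, index=list(cell_lines), columns=["deleterious", "hotspot", "other"]
    )
    for rec in records:
        if rec.gene.upper() != gene or rec.cell_line not in out.index:
            continue
        if rec.is_deleterious:
            out.loc[rec.cell_line, "deleterious"] = 1
        if _activating(rec):
            out.loc[rec.cell_line, "hotspot" if rec.is_hotspot else "other"] = 1
    return out


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test between two groups.

    Exact p-value for combined n <= 20 without ties, tie-corrected normal
    approximation otherwise. Returns (U statistic, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
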