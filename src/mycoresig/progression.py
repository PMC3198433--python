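"""Monotone-pattern statistics over an ordered three-group design, percent
formatting, and signature-based sample clustering.

A gene follows the increasing pattern iff its three group means are strictly
ordered (mean_g1 < mean_g2 < mean_g3); under exchangeable group means each
of the 3! orderings is equally likely, so the null increasing fraction is
exactly 1/6.  Percents are rendered with one decimal, ties rounded half away
from zero.  Clustering is average-linkage agglomerative on 1 − Pearson
correlation between samples over per-gene standardized signature expression.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ProgressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "format_percent",
    "group_means",
    "monotone_table",
    "monotone_fraction",
    "pattern_enrichment_fold",
    "cluster_samples",
]


def format_percent(numerator: int, denominator: int) -> str:
    """100·num/den with exactly one decimal digit, half rounded away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def group_means(study: ProgressionStudy) -> pd.DataFrame:
    """Per-gene mean log2 expression per ordered group (columns in order)."""
    study.validate()
    expr = study.expression
    cols = {}
    for g in study.group_order:
        samples = expr.groups.index[expr.groups == g]
        cols[g] = expr.data[list(samples)].mean(axis=1)
    return pd.DataFrame(cols)[list(study.group_order)]


def monotone_table(study: ProgressionStudy) -> pd.DataFrame:
    """Per-gene strict increasing/decreasing flags over the ordered groups."""
    m = group_means(study).to_numpy()
    increasing = (m[:, 0] < m[:, 1]) & (m[:, 1] < m[:, 2])
    decreasing = (m[:, 0] > m[:, 1]) & (m[:, 1] > m[:, 2])
    return pd.DataFrame(
        {"increasing": increasing, "decreasing": decreasing},
        index=study.expression.data.index,
    )


def monotone_fraction(
    study: ProgressionStudy, genes: Iterable[str], direction: str = "increasing"
) -> tuple[int, int, str]:
    """(count, total, percent string) of genes with the strict monotone pattern.

    Genes absent from the matrix are dropped with a warning; the total is
    the number of genes present.
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    genes = list(dict.fromkeys(genes))
    table = monotone_table(study)
    present = [g for g in genes if g in table.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.warning("%d genes missing from progression matrix: %s",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    count = int(table.loc[present, direction].sum())
    return count, len(present), format_percent(count, len(present))


def pattern_enrichment_fold(signature_fraction: float, background_fraction: float) -> float:
    """Fold enrichment of the signature's monotone fraction over background."""
    if background_fraction <= 0:
        raise ValueError("background fraction must be positive")
    return signature_fraction / background_fraction


def signature_distance_matrix(
    matrix: ExpressionMatrix, signature: Iterable[str]
) -> np.ndarray:
    """Pairwise sample distances 1 − Pearson r over standardized signature rows."""
    sig = [g for g in dict.fromkeys(signature) if g in matrix.data.index]
    if not sig:
        raise ValueError("no signature gene present in the matrix")
    x = matrix.data.loc[sig].to_numpy()
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd == 0, 0.0, (x - mean) / sd)
    corr = np.corrcoef(z.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    # guard tiny negative round-off
    return np.clip(d, 0.0, 2.0)


def cluster_samples(
    matrix: ExpressionMatrix, signature: Iterable[str], k: int = 2
) -> tuple[list[str], pd.Series]:
    """Average-linkage clustering of samples on signature correlation distance.

    Returns (dendrogram leaf order as sample ids, cut-at-k labels per
    sample).  scipy's deterministic tie-handling (lowest cluster index
    first) makes the result reproducible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    samples = matrix.sample_ids
    if len(samples) < k:
        raise ValueError(f"fewer samples ({len(samples)}) than clusters ({k})")
    d = signature_distance_matrix(matrix, signature)
    condensed = squareform(d, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    order = [samples[i] for i in hierarchy.leaves_list(link)]
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return order, pd.Series(labels, index=samples, name="cluster")
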