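"""Differential response calling from replicate log2 expression matrices.

The same operation serves steady-state RNA and nuclear run-on
(transcription-rate) designs: a per-gene Welch two-sample t on log2 values,
Benjamini–Hochberg correction across genes, and direction calls that require
both a fold-change and a q-value threshold.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DifferentialResult, ExpressionMatrix

__all__ = ["benjamini_hochberg", "call_differential"]


def benjamini_hochberg(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """BH step-up q-values: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_differential(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_thresh: float = 0.585,
    q_thresh: float = 0.05,
) -> DifferentialResult:
    """Welch t per gene (B vs A) with BH correction and direction calls.

    ``lfc`` is mean(B) − mean(A) on the log2 scale.  A gene is called 'up'
    iff lfc ≥ +fc_thresh and q ≤ q_thresh, 'down' for the mirror image,
    otherwise 'unchanged'.  Genes with zero variance in both groups get
    p = 1 when the means are equal (0/0 guard) and p = 0 otherwise.
    """
    expr.validate()
    group_a, group_b = list(group_a), list(group_b)
    samples = set(expr.sample_ids)
    for name, grp in (("A", group_a), ("B", group_b)):
        unknown = set(grp) - samples
        if unknown:
            raise ValueError(f"group {name} has unknown sample ids: {sorted(unknown)}")
        if len(grp) < 2:
            raise ValueError(f"group {name} needs >= 2 samples, got {len(grp)}")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")

    a = expr.data[group_a].to_numpy()
    b = expr.data[group_b].to_numpy()
    lfc = b.mean(axis=1) - a.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # degenerate zero-variance genes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
        degenerate = ~np.isfinite(p)  # zero within-group variance in both groups
        if degenerate.any():
            equal_means = np.isclose(lfc, 0.0)
            p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
            t = np.where(
                degenerate, np.where(equal_means, 0.0, np.sign(lfc) * np.inf), t
            )

    q = benjamini_hochberg(p)
    call = np.full(len(lfc), "unchanged", dtype=object)
    call[(lfc >= fc_thresh) & (q <= q_thresh)] = "up"
    call[(lfc <= -fc_thresh) & (q <= q_thresh)] = "down"

    table = pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "q": q, "call": call}, index=expr.data.index
    )
    table.index.name = "gene_id"
    return DifferentialResult(table, fc_thresh, q_thresh).validate()
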