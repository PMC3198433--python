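"""Signature scoring across a heterogeneous expression compendium.

Per-sample signature score = mean of per-gene z-scores over the signature;
its Pearson correlation with the driver gene is tested against a null of
equally sized random gene sets.  Samples high on both axes (above a common
quantile) are 'double positive'; cell types enriched for double positives
are found with a hypergeometric test plus BH correction, and the tumor
composition of the double positives is summarized with one-decimal percents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CompendiumStudy
from .expression import benjamini_hochberg
from .progression import format_percent

logger = logging.getLogger(__name__)

__all__ = [
    "signature_score",
    "driver_signature_correlation",
    "random_geneset_pvalue",
    "classify_double_positive",
    "celltype_enrichment",
    "tumor_fraction",
    "CompendiumResult",
    "analyze_compendium",
]


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    """Per-row standardization; zero-variance rows contribute 0."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    return np.where(sd == 0, 0.0, z)


def signature_score(
    study: CompendiumStudy, signature: Iterable[str], exclude_driver: bool = True
) -> pd.Series:
    """Per-sample mean of standardized log2 expression over signature genes.

    Genes absent from the matrix are dropped with a warning; the driver gene
    is excluded by default to avoid self-correlation downstream.
    """
    study.validate()
    sig = list(dict.fromkeys(signature))
    if exclude_driver and study.driver_gene in sig:
        sig.remove(study.driver_gene)
        logger.warning("driver gene %r excluded from its own signature", study.driver_gene)
    present = [g for g in sig if g in study.expression.data.index]
    missing = sorted(set(sig) - set(present))
    if missing:
        logger.warning("%d signature genes missing from matrix: %s",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    z = _zscore_rows(study.expression.data.loc[present].to_numpy())
    return pd.Series(z.mean(axis=0), index=study.expression.sample_ids, name="score")


def driver_signature_correlation(study: CompendiumStudy, scores: pd.Series) -> float:
    """Pearson r between the signature score and the driver's expression."""
    driver = study.expression.data.loc[study.driver_gene]
    x = scores.loc[driver.index].to_numpy()
    y = driver.to_numpy()
    if len(x) < 3:
        raise ValueError("need >= 3 samples for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector in correlation")
    return float(np.corrcoef(x, y)[0, 1])


def random_geneset_pvalue(
    study: CompendiumStudy,
    signature_size: int,
    observed_r: float,
    b: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for the driver–signature correlation.

    Draws ``b`` uniform random gene sets of the signature's size (driver
    excluded), recomputes the correlation for each, and returns the
    one-sided (large-r) estimate ``(1 + #{r_null >= r_obs}) / (b + 1)``.
    """
    study.validate()
    if b < 1:
        raise ValueError("b must be >= 1")
    pool = [g for g in study.expression.gene_ids if g != study.driver_gene]
    if signature_size > len(pool):
        raise ValueError(
            f"signature size {signature_size} exceeds {len(pool)} available genes"
        )
    rng = np.random.default_rng(seed)
    z = _zscore_rows(study.expression.data.loc[pool].to_numpy())
    driver = study.expression.data.loc[study.driver_gene].to_numpy()
    dz = (driver - driver.mean()) / driver.std()
    n = z.shape[1]
    exceed = 0
    for _ in range(b):
        idx = rng.choice(len(pool), size=signature_size, replace=False)
        score = z[idx].mean(axis=0)
        sd = score.std()
        r_null = 0.0 if sd == 0 else float((score - score.mean()) @ dz / (n * sd))
        if r_null >= observed_r:
            exceed += 1
    return (1 + exceed) / (b + 1)


def classify_double_positive(
    study: CompendiumStudy, scores: pd.Series, quantile: float = 0.75
) -> pd.Series:
    """Flag samples above the q-quantile on both driver expression and score."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    driver = study.expression.data.loc[study.driver_gene]
    scores = scores.loc[driver.index]
    flags = (driver > driver.quantile(quantile)) & (scores > scores.quantile(quantile))
    return flags.rename("double_positive")


def celltype_enrichment(
    flags: pd.Series, celltype: pd.Series, fdr_target: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of flagged samples per cell type.

    For each type: p = P(X >= k) with X ~ Hypergeom(N total, K flagged,
    n in type); BH across types; 'enriched' marks q ≤ fdr_target.
    """
    missing = set(flags.index) ^ set(celltype.index)
    if missing:
        raise ValueError(f"flags and labels cover different samples: {sorted(missing)[:5]}")
    celltype = celltype.loc[flags.index]
    n_total = len(flags)
    k_flagged = int(flags.sum())
    rows = []
    for ct, idx in flags.groupby(celltype).groups.items():
        n_type = len(idx)
        k_type = int(flags.loc[idx].sum())
        p = float(stats.hypergeom.sf(k_type - 1, n_total, k_flagged, n_type))
        rows.append({"celltype": ct, "n_samples": n_type, "n_flagged": k_type, "p": p})
    table = pd.DataFrame(rows).sort_values("celltype", ignore_index=True)
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    table["enriched"] = table["q"] <= fdr_target
    return table


def tumor_fraction(
    flags: pd.Series, tumor: pd.Series
) -> tuple[tuple[int, int, str | None], tuple[int, int, str]]:
    """Tumor composition of double positives and of all samples.

    Returns ((tumor-and-flagged, flagged, percent or None), (tumor, total,
    percent)); the flagged percent is None when nothing is flagged.
    """
    tumor = tumor.loc[flags.index]
    n_dp = int(flags.sum())
    n_dp_tumor = int((flags & tumor).sum())
    n_total = len(flags)
    n_tumor = int(tumor.sum())
    dp_pct = format_percent(n_dp_tumor, n_dp) if n_dp > 0 else None
    return (n_dp_tumor, n_dp, dp_pct), (n_tumor, n_total, format_percent(n_tumor, n_total))


@dataclass
class CompendiumResult:
    """Bundle of all compendium statistics for one signature."""

    scores: pd.Series
    r: float
    p: float
    b: int
    seed: int
    double_positive: pd.Series
    enrichment: pd.DataFrame
    dp_tumor: tuple[int, int, str | None]
    overall_tumor: tuple[int, int, str]
    missing_genes: list[str] = field(default_factory=list)

    def validate(self) -> "CompendiumResult":
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation outside [-1, 1]")
        if not 1.0 / (self.b + 1) <= self.p <= 1.0:
            raise ValueError("permutation p outside [1/(B+1), 1]")
        return self


def analyze_compendium(
    study: CompendiumStudy,
    signature: Sequence[str],
    b: int = 1000,
    seed: int = 0,
    quantile: float = 0.75,
    fdr_target: float = 0.05,
) -> CompendiumResult:
    """Run the full compendium analysis for one signature."""
    sig = [g for g in signature if g != study.driver_gene]
    scores = signature_score(study, sig)
    r = driver_signature_correlation(study, scores)
    k = len([g for g in sig if g in study.expression.data.index])
    p = random_geneset_pvalue(study, k, r, b=b, seed=seed)
    flags = classify_double_positive(study, scores, quantile)
    enr = celltype_enrichment(flags, study.celltype, fdr_target)
    dp, overall = tumor_fraction(flags, study.tumor)
    missing = sorted(set(sig) - set(study.expression.data.index))
    return CompendiumResult(
        scores, r, p, b, seed, flags, enr, dp, overall, missing
    ).validate()
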