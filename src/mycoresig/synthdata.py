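"""Synthetic-data generator with planted ground truth.

Every input the pipeline consumes is generated here: a gene annotation with
promoter sequences (planted canonical E-boxes for bound genes), two-channel
tiling-array intensities, ChIP-seq read positions, and replicate log2
expression matrices for the two-condition (driver on/off), three-group
progression, and multi-cell-type compendium designs.

All randomness flows from ``SimulationConfig.seed`` through named streams, so
identical config + seed reproduces byte-identical outputs.  Effect-size
parameters set to zero yield exact nulls (no planted E-boxes, no IP
enrichment, exchangeable progression group means, driver-independent
signature genes), which downstream calibration tests rely on.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import (
    CompendiumStudy,
    ExpressionMatrix,
    GenomeAnnotation,
    GroundTruth,
    OrthologMap,
    ProgressionStudy,
    ReadSet,
    TilingProbeSet,
)

__all__ = [
    "gene_ids_for",
    "plant_truth",
    "make_annotation",
    "simulate_tiling",
    "simulate_chipseq",
    "simulate_expression",
    "simulate_bound_geneset",
    "make_ortholog_map",
]

# named RNG streams; every generator draws from default_rng((seed, STREAM, salt))
_S_TRUTH, _S_ANNOT, _S_TILING, _S_READS, _S_EXPR, _S_BOUND, _S_ORTHO = range(7)

_GENES_PER_CHROM = 1000
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(cfg: SimulationConfig, stream: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((int(cfg.seed), stream, int(salt)))


def gene_ids_for(cfg: SimulationConfig) -> list[str]:
    width = max(4, len(str(cfg.n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]


def plant_truth(cfg: SimulationConfig) -> GroundTruth:
    """Pick the planted gene sets: bound, up/down-regulated, signature, driver.

    The signature is a subset of bound ∩ up-regulated genes (the pipeline's
    end-to-end target).  Non-signature bound genes are split into a shared
    half and B-cell-only / ESC-only quarters so that cell-type-restricted
    target sets are non-trivial; half of each context-only subset responds
    up, half down.  The driver gene is a dedicated non-signature, non-bound
    gene whose compendium profile the signature tracks.
    """
    cfg.validate()
    rng = _rng(cfg, _S_TRUTH)
    ids = np.array(gene_ids_for(cfg))
    perm = rng.permutation(cfg.n_genes)

    n_bound = int(round(cfg.bound_fraction * cfg.n_genes))
    n_sig = min(cfg.compendium.signature_size, n_bound)
    n_de = int(round(cfg.de_fraction * cfg.n_genes))

    ordered = list(ids[perm])
    bound_list = ordered[:n_bound]
    bound = set(bound_list)
    signature = set(bound_list[:n_sig])  # signature genes are bound everywhere
    others = bound_list[n_sig:]
    n_shared = len(others) // 2
    n_bonly = (len(others) - n_shared) // 2
    shared = others[:n_shared]
    bcell_only = others[n_shared: n_shared + n_bonly]
    esc_only = others[n_shared + n_bonly:]
    context_bound = {
        "bcell": signature | set(shared) | set(bcell_only),
        "esc": signature | set(shared) | set(esc_only),
    }

    # context-only bound genes respond (half up, half down); shared extras are
    # bound-only, so the cross-context intersection stays exactly the signature
    up = set(signature) | set(bcell_only[: len(bcell_only) // 2]) | set(
        esc_only[: len(esc_only) // 2]
    )
    down = set(bcell_only[len(bcell_only) // 2:]) | set(
        esc_only[len(esc_only) // 2:]
    )
    pool = [g for g in ordered if g not in bound]
    extra_up = max(0, n_de - len(up))
    up |= set(pool[:extra_up])
    extra_down = max(0, n_de - len(down))
    down |= set(pool[extra_up: extra_up + extra_down])
    # driver: first gene that carries no planted role
    taken = bound | up | down
    driver = next(g for g in ids[perm[::-1]] if g not in taken)

    n_ct = cfg.compendium.n_celltypes
    ct_labels = [f"ct{i:03d}" for i in range(1, n_ct + 1)]
    enriched = set(
        rng.choice(ct_labels, size=cfg.compendium.n_enriched_celltypes, replace=False)
    )

    return GroundTruth(
        bound_genes=bound,
        de_genes_up=up,
        de_genes_down=down,
        monotone_genes=set(signature),
        signature_genes=signature,
        enriched_celltypes=enriched,
        driver_gene=driver,
        context_bound=context_bound,
    ).validate()


def make_annotation(
    cfg: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[GenomeAnnotation, dict[str, str], GroundTruth]:
    """Build the gene annotation and promoter sequences.

    One synthetic chromosome per 1000 genes; promoters are uniform-random
    ACGT with a canonical CACGTG planted at a recorded offset for every
    planted bound gene.  Returns (annotation, promoter sequences keyed by
    gene id, truth augmented with E-box offsets and planted region
    coordinates).
    """
    cfg.validate()
    if truth is None:
        truth = plant_truth(cfg)
    rng = _rng(cfg, _S_ANNOT)
    ids = gene_ids_for(cfg)
    up, down = cfg.promoter_window
    win = up + down
    margin = 1000
    slot = win + margin
    half = cfg.planted_region_bp // 2

    rows = []
    promoters: dict[str, str] = {}
    ebox_offsets: dict[str, int] = {}
    region_rows = []
    chrom_sizes: dict[str, int] = {}

    strands = rng.choice(np.array(["+", "-"]), size=cfg.n_genes)
    for i, gid in enumerate(ids):
        chrom = f"chr{i // _GENES_PER_CHROM + 1}"
        j = i % _GENES_PER_CHROM
        win_start = j * slot + margin // 2
        strand = strands[i]
        tss = win_start + (up if strand == "+" else down)
        seq = _BASES[rng.integers(0, 4, size=win)]
        if gid in truth.bound_genes:
            lo, hi = half, win - half - 6
            offset = int(rng.integers(lo, hi + 1))
            seq[offset: offset + 6] = np.frombuffer(b"CACGTG", dtype="S1")
            ebox_offsets[gid] = offset
            center = win_start + offset + 3
            region_rows.append(
                {"gene_id": gid, "chrom": chrom,
                 "start": center - half, "end": center + half}
            )
        promoters[gid] = seq.tobytes().decode("ascii")
        rows.append({"gene_id": gid, "chrom": chrom, "strand": strand, "tss": tss})
        chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), win_start + win + margin)

    annotation = GenomeAnnotation(pd.DataFrame(rows), chrom_sizes).validate()
    truth.ebox_offsets = ebox_offsets
    truth.planted_regions = pd.DataFrame(
        region_rows, columns=["gene_id", "chrom", "start", "end"]
    )
    truth.validate(annotation)
    return annotation, promoters, truth


def simulate_tiling(
    cfg: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    salt: int = 0,
    context: str | None = None,
) -> TilingProbeSet:
    """Two-channel tiling-array probe intensities over promoter windows.

    Probes tile each promoter window at ``probe_spacing_bp``.  Control
    replicates are Normal(baseline, noise_sd); IP replicates additionally
    gain ``binding_shift`` on probes overlapping the planted ~500 bp region
    of each bound gene.  ``salt`` separates independent hybridizations
    (e.g. two antibodies, a second cell context); ``context`` restricts the
    planted regions to that context's bound genes when the truth carries
    per-context bound subsets.
    """
    if len(annotation.genes) == 0:
        raise ValueError("empty annotation")
    if context is not None and context not in truth.context_bound:
        raise ValueError(f"unknown binding context {context!r}")
    rng = _rng(cfg, _S_TILING, salt)
    up, down = cfg.promoter_window
    intervals = annotation.promoter_intervals(up, down)

    chroms, starts = [], []
    for chrom, s, e in zip(intervals["chrom"], intervals["start"], intervals["end"]):
        p = np.arange(s, e - cfg.probe_length_bp + 1, cfg.probe_spacing_bp)
        starts.append(p)
        chroms.extend([chrom] * len(p))
    start = np.concatenate(starts) if starts else np.array([], dtype=int)
    probes = pd.DataFrame(
        {
            "chrom": chroms,
            "start": start,
            "end": start + cfg.probe_length_bp,
        }
    ).sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    probes["probe_id"] = [
        f"p_{c}_{s}" for c, s in zip(probes["chrom"], probes["start"])
    ]

    n_rep = cfg.n_rep_ip + cfg.n_rep_ctrl
    labels = ["IP"] * cfg.n_rep_ip + ["control"] * cfg.n_rep_ctrl
    intensities = cfg.baseline_log2 + rng.normal(
        0.0, cfg.noise_sd, size=(n_rep, len(probes))
    )

    if truth.planted_regions is not None and len(truth.planted_regions):
        planted = truth.planted_regions
        if context is not None:
            planted = planted[planted["gene_id"].isin(truth.context_bound[context])]
        in_region = np.zeros(len(probes), dtype=bool)
        ps = probes["start"].to_numpy()
        pe = probes["end"].to_numpy()
        pc = probes["chrom"].to_numpy()
        for _, reg in planted.iterrows():
            sel = (pc == reg["chrom"]) & (ps < reg["end"]) & (pe > reg["start"])
            in_region |= sel
        intensities[: cfg.n_rep_ip, :] += cfg.binding_shift * in_region

    return TilingProbeSet(probes, intensities, labels).validate()


def simulate_chipseq(
    cfg: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    n_reads: int,
    enrichment: float = 8.0,
    salt: int = 0,
) -> ReadSet:
    """ChIP-seq read start positions: uniform background plus planted peaks.

    Per-base sampling weight is 1 outside and ``enrichment`` inside the
    planted regions, so the expected window-count ratio planted/background
    equals ``enrichment``.  Exactly ``n_reads`` reads are emitted.
    """
    if n_reads < 0 or enrichment <= 0:
        raise ValueError("need n_reads >= 0 and enrichment > 0")
    rng = _rng(cfg, _S_READS, salt)
    if n_reads == 0:
        return ReadSet(pd.DataFrame(columns=["chrom", "pos", "strand"])).validate()

    regions = truth.planted_regions
    if regions is None:
        regions = pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])

    # background = genome minus planted regions, as explicit intervals
    bg_intervals: list[tuple[str, int, int]] = []
    for chrom, size in sorted(annotation.chrom_sizes.items()):
        pos = 0
        sub = regions[regions["chrom"] == chrom].sort_values("start")
        for _, r in sub.iterrows():
            if r["start"] > pos:
                bg_intervals.append((chrom, pos, int(r["start"])))
            pos = max(pos, int(r["end"]))
        if pos < size:
            bg_intervals.append((chrom, pos, size))

    reg_len = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    bg_len = np.array([e - s for _, s, e in bg_intervals], dtype=float)
    weights = np.concatenate([bg_len, reg_len * enrichment])
    counts = rng.multinomial(n_reads, weights / weights.sum())

    chroms: list[str] = []
    positions: list[np.ndarray] = []
    n_bg = len(bg_intervals)
    for (chrom, s, e), c in zip(bg_intervals, counts[:n_bg]):
        if c:
            positions.append(rng.integers(s, e, size=c))
            chroms.extend([chrom] * c)
    for (_, r), c in zip(regions.iterrows(), counts[n_bg:]):
        if c:
            positions.append(rng.integers(int(r["start"]), int(r["end"]), size=c))
            chroms.extend([r["chrom"]] * c)

    reads = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.concatenate(positions) if positions else np.array([], dtype=int),
        }
    )
    reads["strand"] = rng.choice(np.array(["+", "-"]), size=len(reads))
    reads = reads.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    return ReadSet(reads).validate()


def simulate_expression(
    cfg: SimulationConfig,
    truth: GroundTruth,
    design: str,
    gene_ids: Sequence[str] | None = None,
    salt: int = 0,
):
    """Replicate log2 expression for one of the three study designs.

    ``two_condition`` returns an :class:`ExpressionMatrix` (groups A = driver
    off, B = driver on; planted up/down genes shifted by ±``de_log2fc`` in B).
    ``progression`` returns a :class:`ProgressionStudy` (wt < pre < tum;
    planted monotone genes climb by ``de_log2fc / 2`` per group, a fraction
    ``monotone_fraction_bg`` of background genes gets sorted group means, the
    rest exchangeable i.i.d. means).  ``compendium`` returns a
    :class:`CompendiumStudy` (signature genes = driver_beta · driver latent +
    noise; enriched cell types receive a driver-level bias; tumor flags follow
    a logistic function of the driver latent with intercept solved so the
    marginal tumor fraction matches the config).
    """
    cfg.validate()
    if gene_ids is None:
        gene_ids = gene_ids_for(cfg)
    gene_ids = list(gene_ids)
    designs = {
        "two_condition": _expr_two_condition,
        "progression": _expr_progression,
        "compendium": _expr_compendium,
    }
    if design not in designs:
        raise ValueError(f"unknown design {design!r}; expected one of {sorted(designs)}")
    salt_offset = {"two_condition": 0, "progression": 1_000, "compendium": 2_000}[design]
    rng = _rng(cfg, _S_EXPR, salt_offset + salt)
    return designs[design](cfg, truth, gene_ids, rng)


def _baselines(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(cfg.baseline_log2, 0.5, size=n)


def _expr_two_condition(cfg, truth, gene_ids, rng) -> ExpressionMatrix:
    n = len(gene_ids)
    r = cfg.n_rep_expr
    samples = [f"A_{i+1}" for i in range(r)] + [f"B_{i+1}" for i in range(r)]
    base = _baselines(cfg, n, rng)
    values = base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n, 2 * r))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in truth.de_genes_up:
        if g in idx:
            values[idx[g], r:] += cfg.de_log2fc
    for g in truth.de_genes_down:
        if g in idx:
            values[idx[g], r:] -= cfg.de_log2fc
    data = pd.DataFrame(values, index=gene_ids, columns=samples)
    groups = pd.Series(["A"] * r + ["B"] * r, index=samples)
    return ExpressionMatrix(data, groups).validate()


_BETWEEN_GROUP_SD = 0.5  # sd of i.i.d. group means for background progression genes


def _expr_progression(cfg, truth, gene_ids, rng) -> ProgressionStudy:
    n = len(gene_ids)
    r = cfg.n_rep_expr
    order = ("wt", "pre", "tum")
    samples = [f"{g}_{i+1}" for g in order for i in range(r)]
    base = _baselines(cfg, n, rng)
    step = cfg.de_log2fc / 2.0

    means = base[:, None] + rng.normal(0.0, _BETWEEN_GROUP_SD, size=(n, 3))
    monotone_idx = np.array(
        [i for i, g in enumerate(gene_ids) if g in truth.monotone_genes], dtype=int
    )
    background = np.setdiff1d(np.arange(n), monotone_idx)
    n_forced = int(round(cfg.monotone_fraction_bg * len(background)))
    forced = rng.choice(background, size=n_forced, replace=False) if n_forced else []
    if len(forced):
        means[forced] = np.sort(means[forced], axis=1)
    if len(monotone_idx):
        means[monotone_idx] = base[monotone_idx, None] + step * np.arange(3)

    values = np.repeat(means, r, axis=1) + rng.normal(0.0, cfg.noise_sd, size=(n, 3 * r))
    data = pd.DataFrame(values, index=gene_ids, columns=samples)
    groups = pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)
    expr = ExpressionMatrix(data, groups).validate()
    return ProgressionStudy(expr, order).validate()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _tumor_intercept(d: np.ndarray, slope: float, target: float) -> float:
    """Solve mean(sigmoid(slope*d + b)) = target by bisection."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(slope * d + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _expr_compendium(cfg, truth, gene_ids, rng) -> CompendiumStudy:
    comp = cfg.compendium
    n, s = len(gene_ids), comp.n_samples
    if truth.driver_gene not in gene_ids:
        raise ValueError("driver gene missing from compendium gene universe")
    samples = [f"s{i:05d}" for i in range(1, s + 1)]
    ct_labels = [f"ct{i:03d}" for i in range(1, comp.n_celltypes + 1)]
    celltype = pd.Series(rng.choice(ct_labels, size=s), index=samples)

    d = rng.normal(0.0, 1.0, size=s)
    enriched_mask = celltype.isin(truth.enriched_celltypes).to_numpy()
    d = d + comp.celltype_driver_bias * enriched_mask

    beta = comp.resolved_beta()
    base = _baselines(cfg, n, rng)
    values = base[:, None] + rng.normal(0.0, comp.gene_noise_sd, size=(n, s))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in truth.signature_genes:
        if g in idx:
            values[idx[g]] += beta * d
    values[idx[truth.driver_gene]] = base[idx[truth.driver_gene]] + d

    b = _tumor_intercept(d, comp.tumor_dp_bias, comp.tumor_fraction)
    tumor = pd.Series(rng.random(s) < _sigmoid(comp.tumor_dp_bias * d + b), index=samples)

    data = pd.DataFrame(values, index=gene_ids, columns=samples)
    expr = ExpressionMatrix(data).validate()
    return CompendiumStudy(expr, celltype, tumor, truth.driver_gene).validate()


def simulate_bound_geneset(
    cfg: SimulationConfig,
    truth: GroundTruth,
    universe: Iterable[str],
    salt: int = 0,
    mouse: bool = False,
) -> set[str]:
    """Bound-gene set for an auxiliary context (cancer line or mESC).

    Always contains the planted signature genes, plus an independent random
    draw of ``context_extra_bound_fraction`` of the universe.  With
    ``mouse=True`` ids are returned in murine form (``m<gene_id>``).
    """
    rng = _rng(cfg, _S_BOUND, salt)
    universe = list(universe)
    n_extra = int(round(cfg.context_extra_bound_fraction * len(universe)))
    extras = set(rng.choice(universe, size=n_extra, replace=False)) if n_extra else set()
    bound = set(truth.signature_genes) | extras
    if mouse:
        bound = {f"m{g}" for g in bound}
    return bound


def make_ortholog_map(
    cfg: SimulationConfig, truth: GroundTruth, gene_ids: Sequence[str], salt: int = 0
) -> OrthologMap:
    """Human → murine id map (``g...`` → ``mg...``).

    A random ``ortholog_unmapped_fraction`` of non-signature genes is left
    unmapped; planted signature genes are always mapped so that species
    filtering is driven by binding evidence, not by map gaps.
    """
    rng = _rng(cfg, _S_ORTHO, salt)
    candidates = [g for g in gene_ids if g not in truth.signature_genes]
    n_unmapped = int(round(cfg.ortholog_unmapped_fraction * len(candidates)))
    unmapped = (
        set(rng.choice(candidates, size=n_unmapped, replace=False))
        if n_unmapped
        else set()
    )
    pairs = {g: f"m{g}" for g in gene_ids if g not in unmapped}
    return OrthologMap(pairs, unmapped).validate()
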