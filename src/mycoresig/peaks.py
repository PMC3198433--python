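"""Binding-region detection from tiling-array data, plus read-window scans
and E-box annotation.

The probe statistic is a shrunken two-sample t (per-probe pooled sd
regularized by the median pooled sd over all probes), smoothed by a centred
moving average over a fixed number of probes — the moving-average family of
tiling-array statistics.  Regions are maximal runs of probes above a
threshold, merged across short gaps; the empirical FDR comes from balanced
IP/control label swaps.  E-boxes (canonical CACGTG and degenerate CANNTG)
are scanned on a single strand, which suffices because both patterns are
closed under reverse complement.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    BindingRegionSet,
    GenomeAnnotation,
    MotifHit,
    ReadSet,
    ScoreTrack,
    TilingProbeSet,
)

__all__ = [
    "normalize_probes",
    "moving_average_statistic",
    "call_binding_regions",
    "estimate_fdr",
    "choose_threshold",
    "window_scan_reads",
    "assign_regions_to_genes",
    "scan_eboxes",
]

# a contiguity break is a probe gap wider than this multiple of the median spacing
_BREAK_GAP_FACTOR = 5


def normalize_probes(tiling: TilingProbeSet) -> TilingProbeSet:
    """Quantile-normalize replicate log2 intensities.

    Every replicate's sorted value vector is replaced by the mean of all
    replicates' sorted vectors; ties share the mean reference value of their
    rank span, so within-replicate rank order is preserved.
    """
    tiling.validate()
    x = tiling.intensities
    if x.shape[0] < 2:
        raise ValueError("quantile normalization needs >= 2 replicates")
    ref = np.sort(x, axis=1).mean(axis=0)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        order = np.argsort(x[i], kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(x.shape[1])
        vals = ref[ranks].astype(float)
        # average reference values over tied input values
        row = x[i]
        uniq, inv = np.unique(row, return_inverse=True)
        if len(uniq) < len(row):
            sums = np.bincount(inv, weights=vals)
            counts = np.bincount(inv)
            vals = (sums / counts)[inv]
        out[i] = vals
    return TilingProbeSet(tiling.probes, out, list(tiling.labels)).validate()


def _contiguous_segments(probes: pd.DataFrame) -> list[np.ndarray]:
    """Index runs of probes uninterrupted by chromosome changes or large gaps."""
    start = probes["start"].to_numpy()
    chrom = probes["chrom"].to_numpy()
    n = len(probes)
    if n == 0:
        return []
    spacing = np.diff(start)
    same = chrom[1:] == chrom[:-1]
    within = spacing[same]
    med = np.median(within) if len(within) else 0.0
    max_gap = _BREAK_GAP_FACTOR * med
    breaks = np.flatnonzero(~same | (spacing > max_gap)) + 1
    return [np.arange(a, b) for a, b in zip(np.r_[0, breaks], np.r_[breaks, n])]


def probe_t_statistic(tiling: TilingProbeSet) -> np.ndarray:
    """Shrunken per-probe t: (mean_IP − mean_ctrl) / (pooled sd + s0)."""
    ip = tiling.intensities[tiling.ip_index]
    ctrl = tiling.intensities[tiling.ctrl_index]
    n1, n2 = ip.shape[0], ctrl.shape[0]
    df = n1 + n2 - 2
    if df < 1:
        raise ValueError("need >= 3 replicates in total for a pooled variance")
    ss1 = ((ip - ip.mean(axis=0)) ** 2).sum(axis=0)
    ss2 = ((ctrl - ctrl.mean(axis=0)) ** 2).sum(axis=0)
    s = np.sqrt((ss1 + ss2) / df)
    s0 = np.median(s)
    if s0 == 0 and (s == 0).all():
        raise ValueError("all probes have zero pooled variance")
    return (ip.mean(axis=0) - ctrl.mean(axis=0)) / (s + s0)


def moving_average_statistic(tiling: TilingProbeSet, window_probes: int) -> ScoreTrack:
    """Per-probe moving-average statistic m.

    ``m_i`` is the mean of the shrunken t over the centred window of
    ``window_probes`` probes, truncated at chromosome boundaries and at
    contiguity breaks (gaps wider than 5× the median probe spacing).
    """
    if window_probes < 1 or window_probes % 2 == 0:
        raise ValueError("window_probes must be odd and >= 1")
    tiling.validate()
    t = probe_t_statistic(tiling)
    h = window_probes // 2
    m = np.empty_like(t)
    for seg in _contiguous_segments(tiling.probes):
        ts = t[seg]
        c = np.r_[0.0, np.cumsum(ts)]
        i = np.arange(len(ts))
        lo = np.maximum(i - h, 0)
        hi = np.minimum(i + h + 1, len(ts))
        m[seg] = (c[hi] - c[lo]) / (hi - lo)
    return ScoreTrack(tiling.probes, m).validate()


def call_binding_regions(
    track: ScoreTrack,
    threshold: float,
    max_gap_bp: int = 300,
    min_probes: int = 3,
) -> BindingRegionSet:
    """Runs of probes with m ≥ threshold, gap-merged and size-filtered.

    Within each contiguous probe segment (same chromosome, no gap wider than
    5× the median spacing), index-consecutive above-threshold probes form a
    run.  Runs whose genomic separation (next run's first probe start minus
    previous run's last probe end) is less than ``max_gap_bp`` are merged.
    Regions with fewer than ``min_probes`` above-threshold probes are
    dropped.  Region start/end are the first probe's start and last probe's
    end; the score is the maximum m over the region's probes.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if max_gap_bp < 0 or min_probes < 1:
        raise ValueError("need max_gap_bp >= 0 and min_probes >= 1")
    track.validate()
    p = track.probes
    starts = p["start"].to_numpy()
    ends = p["end"].to_numpy()
    chroms = p["chrom"].to_numpy()
    above = track.m >= threshold
    rows: list[dict] = []
    for seg in _contiguous_segments(p):
        mask = above[seg]
        if not mask.any():
            continue
        # maximal runs of index-consecutive above-threshold probes
        edges = np.flatnonzero(np.diff(mask.astype(int)))
        bounds = np.r_[0, edges + 1, len(mask)]
        runs = [
            seg[a:b]
            for a, b in zip(bounds[:-1], bounds[1:])
            if mask[a]
        ]
        merged = [list(runs[0])]
        for run in runs[1:]:
            prev = merged[-1]
            if starts[run[0]] - ends[prev[-1]] < max_gap_bp:
                prev.extend(run)
            else:
                merged.append(list(run))
        for probes_idx in merged:
            rows.append(
                {
                    "chrom": chroms[probes_idx[0]],
                    "start": int(starts[probes_idx[0]]),
                    "end": int(ends[probes_idx[-1]]),
                    "score": float(track.m[probes_idx].max()),
                    "n_probes": len(probes_idx),
                }
            )
    records = [c for c in rows if c["n_probes"] >= min_probes]
    regions = pd.DataFrame(
        records, columns=["chrom", "start", "end", "score", "n_probes"]
    )
    regions.insert(3, "region_id", [f"region_{i+1:05d}" for i in range(len(regions))])
    return BindingRegionSet(regions, threshold=threshold).validate()


def _balanced_swaps(
    labels: Sequence[str], n_swaps: int, rng: np.random.Generator
) -> list[list[str]]:
    labels = list(labels)
    ip = [i for i, l in enumerate(labels) if l == "IP"]
    ctrl = [i for i, l in enumerate(labels) if l == "control"]
    if len(ip) < 2 or len(ctrl) < 2:
        raise ValueError(
            "label-swap FDR needs >= 2 IP and >= 2 control replicates "
            "(simulate with n_rep >= 2 per class)"
        )
    k = min(len(ip) // 2, len(ctrl) // 2)
    k = max(k, 1)
    swaps = []
    for _ in range(n_swaps):
        out = list(labels)
        for i in rng.choice(ip, size=k, replace=False):
            out[i] = "control"
        for j in rng.choice(ctrl, size=k, replace=False):
            out[j] = "IP"
        swaps.append(out)
    return swaps


def estimate_fdr(
    tiling: TilingProbeSet,
    threshold: float,
    window_probes: int = 5,
    max_gap_bp: int = 300,
    min_probes: int = 3,
    n_swaps: int = 10,
    seed: int = 0,
) -> float:
    """Empirical FDR by balanced IP/control label swaps.

    Half of each replicate class is exchanged, the moving-average statistic
    recomputed, and regions re-called with the same parameters; the FDR
    estimate is ``min(1, mean null region count / observed count)``.  With
    zero observed regions the estimate is 0 if the null also yields none,
    else 1.
    """
    observed = len(
        call_binding_regions(
            moving_average_statistic(tiling, window_probes),
            threshold, max_gap_bp, min_probes,
        )
    )
    rng = np.random.default_rng(seed)
    null_counts = []
    for labels in _balanced_swaps(tiling.labels, n_swaps, rng):
        swapped = tiling.with_labels(labels)
        null_track = moving_average_statistic(swapped, window_probes)
        null_counts.append(
            len(call_binding_regions(null_track, threshold, max_gap_bp, min_probes))
        )
    null_mean = float(np.mean(null_counts))
    if observed == 0:
        return 0.0 if null_mean == 0 else 1.0
    return min(1.0, null_mean / observed)


def choose_threshold(
    tiling: TilingProbeSet,
    fdr_target: float,
    thresholds: Sequence[float] | None = None,
    window_probes: int = 5,
    max_gap_bp: int = 300,
    min_probes: int = 3,
    n_swaps: int = 10,
    seed: int = 0,
) -> tuple[float | None, pd.DataFrame]:
    """Sweep thresholds and pick the smallest whose estimated FDR ≤ target.

    Returns (threshold or None if unattainable, sweep table with columns
    threshold / n_regions / fdr).
    """
    track = moving_average_statistic(tiling, window_probes)
    if thresholds is None:
        finite = track.m[np.isfinite(track.m)]
        hi = float(np.quantile(finite, 0.999)) if len(finite) else 1.0
        thresholds = np.round(np.linspace(0.2, max(hi, 0.4), 12), 3)
    rows = []
    chosen = None
    for th in sorted(thresholds):
        n = len(call_binding_regions(track, th, max_gap_bp, min_probes))
        fdr = estimate_fdr(
            tiling, th, window_probes, max_gap_bp, min_probes, n_swaps, seed
        )
        rows.append({"threshold": th, "n_regions": n, "fdr": fdr})
        if chosen is None and fdr <= fdr_target and n > 0:
            chosen = float(th)
    return chosen, pd.DataFrame(rows)


def window_scan_reads(
    reads: ReadSet, window_bp: int = 100, step_bp: int = 25
) -> pd.DataFrame:
    """Sliding-window read counts: windows ``[k·step, k·step + window)``.

    Returns a table with columns chrom / start / end / count covering every
    window from position 0 through the last read on each chromosome.  Each
    read start falls in exactly ``window/step`` windows when the window is a
    multiple of the step (away from position 0).
    """
    if step_bp <= 0 or window_bp < step_bp:
        raise ValueError("need step_bp > 0 and window_bp >= step_bp")
    reads.validate()
    frames = []
    for chrom, grp in reads.reads.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        last_start = (int(pos.max()) // step_bp) * step_bp
        starts = np.arange(0, last_start + step_bp, step_bp)
        counts = np.searchsorted(pos, starts + window_bp, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_bp,
                    "count": counts,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "count"])
    return pd.concat(frames, ignore_index=True)


def assign_regions_to_genes(
    regions: BindingRegionSet,
    annotation: GenomeAnnotation,
    promoter_window: tuple[int, int] = (8000, 2000),
) -> BindingRegionSet:
    """Assign each region to every gene whose promoter window it overlaps.

    The window is ``[tss − upstream, tss + downstream)`` on the + strand and
    its mirror image on the − strand.  Regions overlapping no promoter are
    retained with an empty assignment.
    """
    up, down = promoter_window
    if up < 0 or down < 0:
        raise ValueError("promoter window bounds must be >= 0")
    prom = annotation.promoter_intervals(up, down)
    r = regions.regions
    assigned: list[tuple[str, ...]] = []
    for chrom, rs, re_ in zip(r["chrom"], r["start"], r["end"]):
        sub = prom[prom["chrom"] == chrom]
        hit = sub[(sub["start"] < re_) & (sub["end"] > rs)]
        assigned.append(tuple(hit["gene_id"]))
    out = r.copy()
    out["genes"] = assigned
    return BindingRegionSet(out, regions.threshold, regions.fdr).validate()


_EBOX_RE = re.compile(r"(?=(CA[ACGT][ACGT]TG))")
_SEQ_RE = re.compile(r"[ACGTN]*\Z")


def scan_eboxes(sequences: dict[str, str]) -> list[MotifHit]:
    """Find every E-box (CANNTG) occurrence in each region sequence.

    Overlapping matches are all reported.  Hits are classed 'canonical' for
    CACGTG and 'degenerate' otherwise, so the two counts are disjoint.  A
    single-strand scan suffices: both patterns equal their own reverse
    complements as pattern sets.  Ambiguous N bases never match.
    """
    hits: list[MotifHit] = []
    for region_id, seq in sequences.items():
        if not _SEQ_RE.match(seq):
            bad = next(i for i, c in enumerate(seq) if c not in "ACGTN")
            raise ValueError(
                f"region {region_id!r}: invalid character {seq[bad]!r} at position {bad}"
            )
        for m in _EBOX_RE.finditer(seq):
            hexamer = m.group(1)
            cls = "canonical" if hexamer == "CACGTG" else "degenerate"
            hits.append(MotifHit(region_id, cls, m.start(), hexamer))
    return hits
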