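"""Independent brute-force reference implementations.

Deliberately written as plain loops over the operation definitions, sharing
no code with the package, so equivalence tests are meaningful.
"""

from __future__ import annotations

import numpy as np


def quantile_norm_oracle(x: np.ndarray) -> np.ndarray:
    """Rows are replicates; every sorted row becomes the mean sorted row."""
    ref = np.mean(np.sort(x, axis=1), axis=0)
    out = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        order = sorted(range(x.shape[1]), key=lambda j: x[i, j])
        for rank, j in enumerate(order):
            out[i, j] = ref[rank]
        # average over ties
        for j in range(x.shape[1]):
            ties = [k for k in range(x.shape[1]) if x[i, k] == x[i, j]]
            out[i, j] = np.mean([out[i, k] for k in ties]) if len(ties) > 1 else out[i, j]
    return out


def shrunken_t_oracle(ip: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    n1, n2 = ip.shape[0], ctrl.shape[0]
    s = []
    for j in range(ip.shape[1]):
        ss = sum((v - ip[:, j].mean()) ** 2 for v in ip[:, j])
        ss += sum((v - ctrl[:, j].mean()) ** 2 for v in ctrl[:, j])
        s.append(np.sqrt(ss / (n1 + n2 - 2)))
    s = np.array(s)
    s0 = np.median(s)
    return (ip.mean(axis=0) - ctrl.mean(axis=0)) / (s + s0)


def moving_average_oracle(t: np.ndarray, segments: list[np.ndarray], window: int) -> np.ndarray:
    """Mean of t over the centred window, truncated at segment ends."""
    h = window // 2
    m = np.empty_like(t, dtype=float)
    for seg in segments:
        seg = list(seg)
        for pos, idx in enumerate(seg):
            lo = max(pos - h, 0)
            hi = min(pos + h + 1, len(seg))
            m[idx] = np.mean([t[seg[k]] for k in range(lo, hi)])
    return m


def region_call_oracle(
    starts: np.ndarray,
    ends: np.ndarray,
    segments: list[np.ndarray],
    m: np.ndarray,
    threshold: float,
    max_gap_bp: int,
    min_probes: int,
) -> list[tuple[int, int, int]]:
    """(start, end, n_probes) triples, mirroring the run/merge/filter rules."""
    regions = []
    for seg in segments:
        runs: list[list[int]] = []
        cur: list[int] = []
        for idx in seg:
            if m[idx] >= threshold:
                cur.append(idx)
            elif cur:
                runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
        merged: list[list[int]] = []
        for run in runs:
            if merged and starts[run[0]] - ends[merged[-1][-1]] < max_gap_bp:
                merged[-1] = merged[-1] + run
            else:
                merged.append(run)
        for probes in merged:
            if len(probes) >= min_probes:
                regions.append((int(starts[probes[0]]), int(ends[probes[-1]]), len(probes)))
    return regions


def window_count_oracle(positions: list[int], window: int, step: int, n_windows: int) -> list[int]:
    counts = []
    for k in range(n_windows):
        lo, hi = k * step, k * step + window
        counts.append(sum(1 for p in positions if lo <= p < hi))
    return counts


def assignment_oracle(
    regions: list[tuple[str, int, int]],
    genes: list[tuple[str, str, str, int]],  # (gene_id, chrom, strand, tss)
    upstream: int,
    downstream: int,
) -> list[set[str]]:
    out = []
    for chrom, rs, re in regions:
        hit = set()
        for gid, gchrom, strand, tss in genes:
            if gchrom != chrom:
                continue
            if strand == "+":
                ws, we = tss - upstream, tss + downstream
            else:
                ws, we = tss - downstream, tss + upstream
            if rs < we and re > ws:
                hit.add(gid)
        out.append(hit)
    return out


def ebox_oracle(seq: str) -> list[tuple[int, str]]:
    """(offset, class) for every CANNTG occurrence, canonical split out."""
    hits = []
    for i in range(len(seq) - 5):
        hexamer = seq[i: i + 6]
        if (
            hexamer[0] == "C" and hexamer[1] == "A"
            and hexamer[2] in "ACGT" and hexamer[3] in "ACGT"
            and hexamer[4] == "T" and hexamer[5] == "G"
        ):
            hits.append((i, "canonical" if hexamer == "CACGTG" else "degenerate"))
    return hits


def bh_oracle(p: list[float]) -> list[float]:
    """Naive O(m^2) BH step-up."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        rank = rank_pos + 1
        candidates = []
        for later_pos in range(rank_pos, m):
            j = order[later_pos]
            candidates.append(p[j] * m / (later_pos + 1))
        q[i] = min(1.0, min(candidates))
    return q


def signature_score_oracle(values: np.ndarray) -> np.ndarray:
    """Standardize each row (population sd), average; zero-sd rows give 0."""
    zs = []
    for row in values:
        sd = row.std()
        zs.append(np.zeros_like(row) if sd == 0 else (row - row.mean()) / sd)
    return np.mean(zs, axis=0)


def correlation_distance_oracle(z: np.ndarray) -> np.ndarray:
    """1 - Pearson r between columns of an already-standardized matrix."""
    n = z.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                r = np.corrcoef(z[:, i], z[:, j])[0, 1]
                d[i, j] = 1.0 - r
    return d


def strict_increasing_oracle(means: np.ndarray) -> bool:
    return means[0] < means[1] < means[2]
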