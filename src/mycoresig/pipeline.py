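"""End-to-end orchestration: simulate → peaks → differential → targets →
core signature → progression → compendium, with a reproducible manifest.

Stage outputs are written under ``config.out_dir``; the manifest records the
full configuration, every derived seed, all provenance tables, and SHA-256
digests of every written file, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, peaks, progression, synthdata, targets
from .compendium import analyze_compendium
from .config import PipelineConfig
from .containers import BindingRegionSet, TilingProbeSet
from .expression import call_differential

logger = logging.getLogger("mycoresig")

__all__ = ["run_pipeline", "call_peaks_stage"]

# salts separating independent simulated hybridizations / designs
SALT_TILING_SC, SALT_TILING_EPIT, SALT_TILING_ESC = 0, 1, 2
SALT_ANRO, SALT_RNA, SALT_ESC_EXPR = 0, 1, 2
SALT_BOUND_CANCER = (10, 11, 12)  # HeLa-like, K562-like, HepG2-like
SALT_BOUND_MOUSE = 20
CANCER_CONTEXTS = ("cancer-line-1", "cancer-line-2", "cancer-line-3")


def _setup_logging() -> None:
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)


def _log(stage: str, msg: str, *args) -> None:
    logger.info(msg, *args, extra={"stage": stage})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def call_peaks_stage(
    tiling: TilingProbeSet, cfg: PipelineConfig, seed: int
) -> tuple[BindingRegionSet, float, pd.DataFrame]:
    """Normalize, score, pick a threshold (sweep if unset), call regions, FDR."""
    norm = peaks.normalize_probes(tiling)
    if cfg.region_threshold is None:
        threshold, sweep = peaks.choose_threshold(
            norm, cfg.fdr_target,
            window_probes=cfg.ma_window_probes, max_gap_bp=cfg.max_gap_bp,
            min_probes=cfg.min_probes, n_swaps=cfg.n_fdr_swaps, seed=seed,
        )
        if threshold is None:
            raise RuntimeError(
                f"no threshold in the sweep reached the FDR target {cfg.fdr_target}"
            )
    else:
        threshold, sweep = cfg.region_threshold, pd.DataFrame()
    track = peaks.moving_average_statistic(norm, cfg.ma_window_probes)
    regions = peaks.call_binding_regions(
        track, threshold, cfg.max_gap_bp, cfg.min_probes
    )
    fdr = peaks.estimate_fdr(
        norm, threshold, cfg.ma_window_probes, cfg.max_gap_bp,
        cfg.min_probes, cfg.n_fdr_swaps, seed,
    )
    regions = BindingRegionSet(regions.regions, threshold, fdr).validate()
    return regions, threshold, sweep


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    _setup_logging()
    config.validate()
    sim = config.simulation
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "files": {}}

    def _fail(stage: str, exc: Exception) -> RuntimeError:
        err = RuntimeError(f"stage {stage!r} failed: {exc}")
        err.__cause__ = exc
        return err

    # ---- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        truth = synthdata.plant_truth(sim)
        annotation, promoters, truth = synthdata.make_annotation(sim, truth)
        gene_ids = annotation.gene_ids
        tiling_sc = synthdata.simulate_tiling(
            sim, annotation, truth, SALT_TILING_SC, context="bcell"
        )
        tiling_epit = synthdata.simulate_tiling(
            sim, annotation, truth, SALT_TILING_EPIT, context="bcell"
        )
        tiling_esc = synthdata.simulate_tiling(
            sim, annotation, truth, SALT_TILING_ESC, context="esc"
        )
        anro = synthdata.simulate_expression(sim, truth, "two_condition", gene_ids, SALT_ANRO)
        rna = synthdata.simulate_expression(sim, truth, "two_condition", gene_ids, SALT_RNA)
        esc_expr = synthdata.simulate_expression(
            sim, truth, "two_condition", gene_ids, SALT_ESC_EXPR
        )
        reads = synthdata.simulate_chipseq(
            sim, annotation, truth, config.chipseq_reads, config.chipseq_enrichment
        )
        cancer_bound = [
            synthdata.simulate_bound_geneset(sim, truth, gene_ids, salt)
            for salt in SALT_BOUND_CANCER
        ]
        ortholog = synthdata.make_ortholog_map(sim, truth, gene_ids)
        mouse_bound = synthdata.simulate_bound_geneset(
            sim, truth, gene_ids, SALT_BOUND_MOUSE, mouse=True
        )
        mouse_ids = [m for m in (ortholog.get(g) for g in gene_ids) if m is not None]
        mouse_truth = replace(
            truth,
            monotone_genes={f"m{g}" for g in truth.monotone_genes},
            signature_genes=set(),
            de_genes_up=set(),
            de_genes_down=set(),
            bound_genes=set(),
            ebox_offsets={},
            planted_regions=None,
        )
        # a small probe dropout emulates genes without murine probe sets
        drop_rng = np.random.default_rng((sim.seed, 99))
        keep = [
            m for m in mouse_ids if drop_rng.random() >= sim.mouse_probe_dropout
        ]
        mouse_truth.monotone_genes &= set(keep)
        prog = synthdata.simulate_expression(sim, mouse_truth, "progression", keep)
        comp = synthdata.simulate_expression(sim, truth, "compendium", gene_ids)
        _log(stage, "simulated %d genes, %d planted signature genes",
             sim.n_genes, len(truth.signature_genes))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise _fail(stage, exc)

    io.write_annotation(annotation, out / "annotation.tsv")
    io.write_fasta(promoters, out / "promoters.fasta")
    io.write_truth(truth, out / "ground_truth.json")
    io.write_probes(tiling_sc, out / "tiling_sc.tsv")
    io.write_reads_bed(reads, out / "chipseq_reads.bed")
    manifest["stages"][stage] = {
        "n_genes": sim.n_genes,
        "planted_bound": len(truth.bound_genes),
        "planted_signature": len(truth.signature_genes),
        "seed": sim.seed,
    }

    # ---- peak calling per context -----------------------------------------
    stage = "callpeaks"
    try:
        bound_by_context: dict[str, set[str]] = {}
        assigned_by_context: dict[str, BindingRegionSet] = {}
        peak_info: dict[str, dict] = {}
        for name, tiling in (
            ("bcell_sc", tiling_sc), ("bcell_epit", tiling_epit), ("esc", tiling_esc)
        ):
            regions, threshold, _ = call_peaks_stage(tiling, config, sim.seed)
            assigned = peaks.assign_regions_to_genes(
                regions, annotation, sim.promoter_window
            )
            assigned_by_context[name] = assigned
            bound_by_context[name] = assigned.assigned_genes()
            peak_info[name] = {
                "n_regions": len(assigned),
                "n_genes": len(bound_by_context[name]),
                "threshold": threshold,
                "fdr": assigned.fdr,
            }
            io.write_regions(assigned, out / f"regions_{name}.bed")
            _log(stage, "%s: %d regions in %d genes (threshold %.3g, FDR %.3g)",
                 name, len(assigned), len(bound_by_context[name]), threshold,
                 assigned.fdr if assigned.fdr is not None else float("nan"))
        region_seqs = _region_sequences(
            assigned_by_context["bcell_sc"], annotation, promoters, sim
        )
        hits = peaks.scan_eboxes(region_seqs)
        io.write_motif_hits(hits, out / "ebox_hits.tsv")
        scan = peaks.window_scan_reads(reads, config.scan_window_bp, config.scan_step_bp)
        scan.to_csv(out / "read_window_counts.tsv", sep="\t", index=False)
        manifest["stages"][stage] = peak_info
    except Exception as exc:  # noqa: BLE001
        raise _fail(stage, exc)

    # ---- differential expression ------------------------------------------
    stage = "de"
    try:
        a = [s for s in anro.sample_ids if s.startswith("A_")]
        b = [s for s in anro.sample_ids if s.startswith("B_")]
        anro_res = call_differential(anro, a, b, config.fc_thresh, config.q_thresh)
        rna_res = call_differential(rna, a, b, config.fc_thresh, config.q_thresh)
        esc_res = call_differential(esc_expr, a, b, config.fc_thresh, config.q_thresh)
        anro_res.table.to_csv(out / "anro_differential.tsv", sep="\t")
        rna_res.table.to_csv(out / "rna_differential.tsv", sep="\t")
        manifest["stages"][stage] = {
            "anro_up": len(anro_res.up), "anro_down": len(anro_res.down),
            "rna_up": len(rna_res.up), "rna_down": len(rna_res.down),
            "esc_up": len(esc_res.up), "esc_down": len(esc_res.down),
        }
        _log(stage, "run-on: %d up / %d down; RNA: %d up / %d down",
             len(anro_res.up), len(anro_res.down), len(rna_res.up), len(rna_res.down))
    except Exception as exc:  # noqa: BLE001
        raise _fail(stage, exc)

    # ---- target sets and core signature -----------------------------------
    stage = "targets"
    try:
        prov: list[dict] = []
        consensus = targets.consensus_bound(
            bound_by_context["bcell_sc"], bound_by_context["bcell_epit"], prov
        )
        bcell = targets.direct_targets("B-cell", consensus, anro_res, rna_res)
        shared = targets.shared_upregulated(
            bcell, bound_by_context["esc"], esc_res.up, prov
        )
        core = targets.intersect_core(
            shared, cancer_bound, ortholog, mouse_bound,
            contexts=["B-cell", "ESC", *CANCER_CONTEXTS, "mouse-ESC"],
        )
        restricted_b = targets.cell_restricted(bcell, bound_by_context["esc"])
        esc_targets = targets.TargetSet(
            "ESC", esc_res.up & bound_by_context["esc"],
            esc_res.down & bound_by_context["esc"], bound_by_context["esc"],
        ).validate()
        restricted_esc = targets.cell_restricted(esc_targets, consensus)
        io.write_gene_set(core.genes, out / "core_signature.txt")
        io.write_ortholog_map(ortholog, out / "ortholog_map.tsv")
        io.write_json(
            {"provenance": prov + bcell.provenance + core.provenance},
            out / "target_provenance.json",
        )
        manifest["stages"][stage] = {
            "consensus_bound": len(consensus),
            "bcell_induced": len(bcell.induced),
            "bcell_repressed": len(bcell.repressed),
            "shared_upregulated": len(shared),
            "core_stage1": core.provenance[0]["output_size"],
            "core_signature": len(core.genes),
            "bcell_restricted": len(restricted_b.induced | restricted_b.repressed),
            "esc_restricted": len(restricted_esc.induced | restricted_esc.repressed),
            "recovered_planted": sorted(truth.signature_genes) == core.genes,
        }
        _log(stage, "core signature: %d genes (planted %d, recovered exactly: %s)",
             len(core.genes), len(truth.signature_genes),
             manifest["stages"][stage]["recovered_planted"])
    except Exception as exc:  # noqa: BLE001
        raise _fail(stage, exc)

    # ---- progression -------------------------------------------------------
    stage = "progression"
    try:
        mouse_core = [m for m in (ortholog.get(g) for g in core.genes) if m is not None]
        inc = progression.monotone_fraction(prog, mouse_core, "increasing")
        all_genes = prog.expression.gene_ids
        bg = progression.monotone_fraction(prog, all_genes, "increasing")
        fold = progression.pattern_enrichment_fold(inc[0] / inc[1], bg[0] / bg[1])
        order, labels = progression.cluster_samples(
            prog.expression, mouse_core, config.cluster_k
        )
        pd.DataFrame({"sample_id": order}).to_csv(
            out / "cluster_order.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "signature_increasing": list(inc),
            "background_increasing": list(bg),
            "enrichment_fold": fold,
        }
        _log(stage, "signature increasing %d/%d (%s%%) vs background %s%%, fold %.2f",
             inc[0], inc[1], inc[2], bg[2], fold)
    except Exception as exc:  # noqa: BLE001
        raise _fail(stage, exc)

    # ---- compendium --------------------------------------------------------
    stage = "compendium"
    try:
        result = analyze_compendium(
            comp, core.genes, b=config.permutation_b, seed=sim.seed,
            quantile=config.dp_quantile, fdr_target=config.enrichment_fdr,
        )
        result.scores.to_frame().to_csv(out / "compendium_scores.tsv", sep="\t")
        result.enrichment.to_csv(out / "celltype_enrichment.tsv", sep="\t", index=False)
        dp, overall = result.dp_tumor, result.overall_tumor
        manifest["stages"][stage] = {
            "r": result.r,
            "permutation_p": result.p,
            "b": result.b,
            "n_double_positive": int(result.double_positive.sum()),
            "enriched_celltypes": sorted(
                result.enrichment.loc[result.enrichment["enriched"], "celltype"]
            ),
            "dp_tumor": list(dp),
            "overall_tumor": list(overall),
        }
        _log(stage, "driver-signature r = %.3f (p = %.3g); %s%% of double "
             "positives are tumors vs %s%% overall",
             result.r, result.p, dp[2], overall[2])
    except Exception as exc:  # noqa: BLE001
        raise _fail(stage, exc)

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _region_sequences(regions, annotation, promoters, sim) -> dict[str, str]:
    """Extract region sequences from the promoter FASTA they fall in."""
    up, down = sim.promoter_window
    prom = annotation.promoter_intervals(up, down)
    prom = prom.set_index("gene_id")
    out: dict[str, str] = {}
    for _, r in regions.regions.iterrows():
        for gid in r["genes"]:
            w = prom.loc[gid]
            lo = max(int(r["start"]) - int(w["start"]), 0)
            hi = min(int(r["end"]) - int(w["start"]), len(promoters[gid]))
            if hi > lo:
                out[r["region_id"]] = promoters[gid][lo:hi]
                break
    return out
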