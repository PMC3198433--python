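"""Generate the synthetic study: annotation, promoters, tiling arrays for
three contexts, ChIP-seq reads, expression matrices, auxiliary bound sets,
ortholog map, and the planted ground truth.

Writes everything under results/analysis/data/ in plain-text formats.
"""

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from analysis_config import DATA, load_config

from mycoresig import io, synthdata
from mycoresig.pipeline import (
    SALT_ANRO, SALT_BOUND_CANCER, SALT_BOUND_MOUSE, SALT_ESC_EXPR,
    SALT_RNA, SALT_TILING_EPIT, SALT_TILING_ESC, SALT_TILING_SC,
)


def main() -> None:
    cfg = load_config()
    sim = cfg.simulation
    DATA.mkdir(parents=True, exist_ok=True)

    truth = synthdata.plant_truth(sim)
    annotation, promoters, truth = synthdata.make_annotation(sim, truth)
    gene_ids = annotation.gene_ids
    io.write_annotation(annotation, DATA / "annotation.tsv")
    io.write_fasta(promoters, DATA / "promoters.fasta")
    io.write_truth(truth, DATA / "ground_truth.json")

    for name, salt, context in (
        ("tiling_bcell_sc", SALT_TILING_SC, "bcell"),
        ("tiling_bcell_epit", SALT_TILING_EPIT, "bcell"),
        ("tiling_esc", SALT_TILING_ESC, "esc"),
    ):
        tiling = synthdata.simulate_tiling(sim, annotation, truth, salt, context)
        io.write_probes(tiling, DATA / f"{name}.tsv")

    reads = synthdata.simulate_chipseq(
        sim, annotation, truth, cfg.chipseq_reads, cfg.chipseq_enrichment
    )
    io.write_reads_bed(reads, DATA / "chipseq_reads.bed")

    for name, salt in (("anro", SALT_ANRO), ("rna", SALT_RNA), ("esc_expr", SALT_ESC_EXPR)):
        expr = synthdata.simulate_expression(sim, truth, "two_condition", gene_ids, salt)
        io.write_expression(expr, DATA / f"{name}.tsv")
        io.write_sample_metadata(expr.groups.to_frame("group"), DATA / f"{name}_samples.tsv")

    for i, salt in enumerate(SALT_BOUND_CANCER, start=1):
        io.write_gene_set(
            synthdata.simulate_bound_geneset(sim, truth, gene_ids, salt),
            DATA / f"bound_cancer_{i}.txt",
        )
    io.write_gene_set(
        synthdata.simulate_bound_geneset(sim, truth, gene_ids, SALT_BOUND_MOUSE, mouse=True),
        DATA / "bound_mouse_esc.txt",
    )
    ortholog = synthdata.make_ortholog_map(sim, truth, gene_ids)
    io.write_ortholog_map(ortholog, DATA / "ortholog_map.tsv")

    # mouse progression: murine ids with a small probe dropout
    mouse_ids = [m for m in (ortholog.get(g) for g in gene_ids) if m is not None]
    drop_rng = np.random.default_rng((sim.seed, 99))
    keep = [m for m in mouse_ids if drop_rng.random() >= sim.mouse_probe_dropout]
    mouse_truth = replace(
        truth, monotone_genes={f"m{g}" for g in truth.monotone_genes} & set(keep),
        signature_genes=set(), de_genes_up=set(), de_genes_down=set(),
        bound_genes=set(), ebox_offsets={}, planted_regions=None,
    )
    prog = synthdata.simulate_expression(sim, mouse_truth, "progression", keep)
    io.write_expression(prog.expression, DATA / "progression.tsv")
    io.write_sample_metadata(
        prog.expression.groups.to_frame("group"), DATA / "progression_samples.tsv"
    )

    comp = synthdata.simulate_expression(sim, truth, "compendium", gene_ids)
    io.write_expression(comp.expression, DATA / "compendium.tsv")
    io.write_sample_metadata(
        pd.DataFrame({"celltype": comp.celltype, "tumor": comp.tumor}),
        DATA / "compendium_samples.tsv",
    )

    print(
        f"simulated {sim.n_genes} genes: {len(truth.bound_genes)} bound, "
        f"{len(truth.signature_genes)} planted core-signature genes, "
        f"driver gene {truth.driver_gene}; data under {DATA}"
    )


if __name__ == "__main__":
    main()
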