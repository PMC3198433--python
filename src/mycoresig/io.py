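"""Plain-text readers/writers for every pipeline artifact.

Conventions: TSV for tables (pandas), FASTA for sequences (Biopython), BED
(0-based half-open) for intervals and reads, JSON for ground truth and run
manifests, one-id-per-line text for gene sets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    BindingRegionSet,
    ExpressionMatrix,
    GenomeAnnotation,
    GroundTruth,
    MotifHit,
    OrthologMap,
    ReadSet,
    TilingProbeSet,
)

__all__ = [
    "write_annotation", "read_annotation",
    "write_fasta", "read_fasta",
    "write_probes", "read_probes",
    "write_reads_bed", "read_reads_bed",
    "write_expression", "read_expression",
    "write_sample_metadata", "read_sample_metadata",
    "write_gene_set", "read_gene_set",
    "write_regions", "read_regions",
    "write_motif_hits",
    "write_ortholog_map", "read_ortholog_map",
    "write_truth", "read_truth",
    "write_json",
]


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    df = annotation.genes[["gene_id", "chrom", "strand", "tss"]].copy()
    df.to_csv(path, sep="\t", index=False)
    sizes = pd.DataFrame(
        sorted(annotation.chrom_sizes.items()), columns=["chrom", "size"]
    )
    sizes.to_csv(Path(path).with_suffix(".chrom_sizes.tsv"), sep="\t", index=False)


def read_annotation(path: str | Path) -> GenomeAnnotation:
    genes = pd.read_csv(path, sep="\t")
    sizes = pd.read_csv(Path(path).with_suffix(".chrom_sizes.tsv"), sep="\t")
    chrom_sizes = dict(zip(sizes["chrom"], sizes["size"]))
    return GenomeAnnotation(genes, chrom_sizes).validate()


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_probes(tiling: TilingProbeSet, path: str | Path) -> None:
    df = tiling.probes.copy()
    counts: dict[str, int] = {}
    for row, label in zip(tiling.intensities, tiling.labels):
        counts[label] = counts.get(label, 0) + 1
        df[f"{label}_{counts[label]}"] = row
    df.to_csv(path, sep="\t", index=False)


def read_probes(path: str | Path) -> TilingProbeSet:
    df = pd.read_csv(path, sep="\t")
    meta = ["chrom", "start", "end", "probe_id"]
    rep_cols = [c for c in df.columns if c not in meta]
    labels = [c.rsplit("_", 1)[0] for c in rep_cols]
    intensities = df[rep_cols].to_numpy().T
    return TilingProbeSet(df[meta].copy(), intensities, labels).validate()


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    r = reads.reads
    bed = pd.DataFrame(
        {
            "chrom": r["chrom"],
            "start": r["pos"],
            "end": r["pos"] + 1,
            "name": [f"read_{i+1}" for i in range(len(r))],
            "score": 0,
            "strand": r["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_reads_bed(path: str | Path) -> ReadSet:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    reads = pd.DataFrame(
        {"chrom": bed["chrom"], "pos": bed["start"], "strand": bed["strand"]}
    ).sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    return ReadSet(reads).validate()


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_expression(path: str | Path, groups: pd.Series | None = None) -> ExpressionMatrix:
    data = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(data, groups).validate()


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


def read_gene_set(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_regions(regions: BindingRegionSet, bed_path: str | Path) -> None:
    """6-column BED (score = 1000·min(m_max/10, 1)) plus a detail sidecar TSV."""
    r = regions.regions
    bed = pd.DataFrame(
        {
            "chrom": r["chrom"],
            "start": r["start"],
            "end": r["end"],
            "name": r["region_id"],
            "score": (1000 * np.minimum(r["score"] / 10.0, 1.0)).round().astype(int),
            "strand": ".",
        }
    )
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    side = r.copy()
    if "genes" in side.columns:
        side["genes"] = [",".join(g) for g in side["genes"]]
    side["threshold"] = regions.threshold
    side["fdr"] = regions.fdr if regions.fdr is not None else ""
    side.to_csv(Path(bed_path).with_suffix(".details.tsv"), sep="\t", index=False)


def read_regions(bed_path: str | Path) -> BindingRegionSet:
    side = pd.read_csv(Path(bed_path).with_suffix(".details.tsv"), sep="\t")
    threshold = float(side["threshold"].iloc[0]) if len(side) else float("nan")
    fdr_col = side["fdr"] if "fdr" in side else None
    fdr = None
    if fdr_col is not None and len(side) and pd.notna(fdr_col.iloc[0]) and fdr_col.iloc[0] != "":
        fdr = float(fdr_col.iloc[0])
    regions = side.drop(columns=["threshold", "fdr"])
    if "genes" in regions.columns:
        regions["genes"] = [
            tuple(g.split(",")) if isinstance(g, str) and g else ()
            for g in regions["genes"].fillna("")
        ]
    return BindingRegionSet(regions, threshold, fdr).validate()


def write_motif_hits(hits: list[MotifHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "region_id": h.region_id,
                "motif_class": h.motif_class,
                "offset": h.offset,
                "hexamer": h.hexamer,
            }
            for h in hits
        ],
        columns=["region_id", "motif_class", "offset", "hexamer"],
    ).to_csv(path, sep="\t", index=False)


def write_ortholog_map(ortholog: OrthologMap, path: str | Path) -> None:
    rows = [{"human_id": h, "mouse_id": m} for h, m in sorted(ortholog.pairs.items())]
    rows += [{"human_id": h, "mouse_id": ""} for h in sorted(ortholog.unmapped)]
    pd.DataFrame(rows, columns=["human_id", "mouse_id"]).to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    pairs = {
        h: m for h, m in zip(df["human_id"], df["mouse_id"]) if m != ""
    }
    unmapped = {h for h, m in zip(df["human_id"], df["mouse_id"]) if m == ""}
    return OrthologMap(pairs, unmapped).validate()


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "bound_genes": sorted(truth.bound_genes),
        "de_genes_up": sorted(truth.de_genes_up),
        "de_genes_down": sorted(truth.de_genes_down),
        "monotone_genes": sorted(truth.monotone_genes),
        "signature_genes": sorted(truth.signature_genes),
        "enriched_celltypes": sorted(truth.enriched_celltypes),
        "driver_gene": truth.driver_gene,
        "context_bound": {k: sorted(v) for k, v in truth.context_bound.items()},
        "ebox_offsets": truth.ebox_offsets,
        "planted_regions": (
            truth.planted_regions.to_dict(orient="records")
            if truth.planted_regions is not None
            else None
        ),
    }
    write_json(payload, path)


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    regions = payload.get("planted_regions")
    return GroundTruth(
        bound_genes=set(payload["bound_genes"]),
        de_genes_up=set(payload["de_genes_up"]),
        de_genes_down=set(payload["de_genes_down"]),
        monotone_genes=set(payload["monotone_genes"]),
        signature_genes=set(payload["signature_genes"]),
        enriched_celltypes=set(payload["enriched_celltypes"]),
        driver_gene=payload.get("driver_gene"),
        context_bound={
            k: set(v) for k, v in payload.get("context_bound", {}).items()
        },
        ebox_offsets=payload.get("ebox_offsets", {}),
        planted_regions=(
            pd.DataFrame(regions, columns=["gene_id", "chrom", "start", "end"])
            if regions is not None
            else None
        ),
    ).validate()


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
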