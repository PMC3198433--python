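"""Shared in-memory containers for the signature-derivation pipeline.

Coordinates are 0-based half-open (BED convention) throughout.  Expression
values are log2-scale.  Containers validate their own invariants on
construction via :meth:`validate`, which every pipeline stage calls on its
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "TilingProbeSet",
    "ScoreTrack",
    "ReadSet",
    "BindingRegionSet",
    "MotifHit",
    "ExpressionMatrix",
    "DifferentialResult",
    "GroundTruth",
    "TargetSet",
    "OrthologMap",
    "CoreSignature",
    "CompendiumStudy",
    "ProgressionStudy",
]


@dataclass
class GenomeAnnotation:
    """Gene annotation: one row per gene with chromosome, strand and TSS.

    ``genes`` columns: ``gene_id``, ``chrom``, ``strand`` (+/-), ``tss``
    (0-based position of the transcription start site).  ``chrom_sizes``
    maps chromosome name to length in bp.
    """

    genes: pd.DataFrame
    chrom_sizes: dict[str, int]

    def validate(self) -> "GenomeAnnotation":
        required = {"gene_id", "chrom", "strand", "tss"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {sorted(set(dup))[:5]}")
        if not set(self.genes["strand"]) <= {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        for chrom, grp in self.genes.groupby("chrom"):
            size = self.chrom_sizes.get(chrom)
            if size is None:
                raise ValueError(f"chromosome {chrom} has no recorded size")
            if (grp["tss"] < 0).any() or (grp["tss"] >= size).any():
                raise ValueError(f"TSS outside chromosome bounds on {chrom}")
        return self

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def promoter_intervals(self, upstream_bp: int, downstream_bp: int) -> pd.DataFrame:
        """Promoter window per gene, strand-mirrored, clipped at chromosome ends.

        + strand: ``[tss - upstream, tss + downstream)``; − strand the mirror
        image ``[tss - downstream, tss + upstream)``.
        """
        g = self.genes
        plus = g["strand"].to_numpy() == "+"
        tss = g["tss"].to_numpy()
        start = np.where(plus, tss - upstream_bp, tss - downstream_bp)
        end = np.where(plus, tss + downstream_bp, tss + upstream_bp)
        sizes = g["chrom"].map(self.chrom_sizes).to_numpy()
        out = pd.DataFrame(
            {
                "gene_id": g["gene_id"].to_numpy(),
                "chrom": g["chrom"].to_numpy(),
                "start": np.clip(start, 0, sizes),
                "end": np.clip(end, 0, sizes),
            }
        )
        return out


@dataclass
class TilingProbeSet:
    """Tiling-array probes plus a replicate × probe matrix of log2 intensities.

    ``probes`` columns: ``chrom``, ``start``, ``end``, ``probe_id``, sorted by
    (chrom, start).  ``intensities`` has one row per replicate, aligned with
    ``labels`` ('IP' or 'control').
    """

    probes: pd.DataFrame
    intensities: np.ndarray
    labels: list[str]

    def validate(self) -> "TilingProbeSet":
        if self.intensities.shape != (len(self.labels), len(self.probes)):
            raise ValueError(
                f"intensity matrix {self.intensities.shape} does not match "
                f"{len(self.labels)} replicates x {len(self.probes)} probes"
            )
        if not set(self.labels) <= {"IP", "control"}:
            raise ValueError("replicate labels must be 'IP' or 'control'")
        if "IP" not in self.labels or "control" not in self.labels:
            raise ValueError("need at least one IP and one control replicate")
        if not np.isfinite(self.intensities).all():
            bad = np.argwhere(~np.isfinite(self.intensities))[0]
            pid = self.probes["probe_id"].iloc[bad[1]]
            raise ValueError(f"non-finite intensity at probe {pid!r}")
        p = self.probes
        order = p.sort_values(["chrom", "start"], kind="stable")
        if not (order.index == p.index).all():
            raise ValueError("probes must be sorted by (chrom, start)")
        return self

    @property
    def ip_index(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == "IP"])

    @property
    def ctrl_index(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == "control"])

    def with_labels(self, labels: Sequence[str]) -> "TilingProbeSet":
        """Same data under a different replicate labelling (for label swaps)."""
        return TilingProbeSet(self.probes, self.intensities, list(labels)).validate()


@dataclass
class ScoreTrack:
    """Per-probe moving-average statistic *m*, aligned with a TilingProbeSet."""

    probes: pd.DataFrame
    m: np.ndarray

    def validate(self) -> "ScoreTrack":
        if len(self.m) != len(self.probes):
            raise ValueError("score track length does not match probe table")
        if not np.isfinite(self.m).all():
            raise ValueError("non-finite moving-average statistic")
        return self

    def display_scale(self) -> np.ndarray:
        """2**m, the intensity-like transform used for track display."""
        return np.exp2(self.m)


@dataclass
class ReadSet:
    """Sequencing read start positions per chromosome, sorted ascending.

    ``reads`` columns: ``chrom``, ``pos`` (0-based start), ``strand``.
    """

    reads: pd.DataFrame

    def validate(self) -> "ReadSet":
        r = self.reads
        if len(r) == 0:
            return self
        if (r["pos"] < 0).any():
            raise ValueError("negative read position")
        for _, grp in r.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("reads must be sorted by position within chromosome")
        return self

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class BindingRegionSet:
    """Called binding regions with scores, empirical FDR, and gene assignments.

    ``regions`` columns: ``chrom``, ``start``, ``end``, ``region_id``,
    ``score`` (max m over the region), ``n_probes``, and after gene
    assignment a ``genes`` column holding a tuple of gene ids.
    """

    regions: pd.DataFrame
    threshold: float
    fdr: float | None = None

    def validate(self) -> "BindingRegionSet":
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR {self.fdr} outside [0, 1]")
        r = self.regions
        for _, grp in r.groupby("chrom"):
            s = grp.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError("regions overlap within a set")
        return self

    def __len__(self) -> int:
        return len(self.regions)

    def assigned_genes(self) -> set[str]:
        if "genes" not in self.regions.columns:
            return set()
        out: set[str] = set()
        for genes in self.regions["genes"]:
            out.update(genes)
        return out


@dataclass
class MotifHit:
    """A single E-box match inside a region sequence."""

    region_id: str
    motif_class: str  # 'canonical' (CACGTG) or 'degenerate' (other CANNTG)
    offset: int  # 0-based within the region sequence
    hexamer: str


@dataclass
class ExpressionMatrix:
    """genes × samples log2 expression with optional sample group labels."""

    data: pd.DataFrame
    groups: pd.Series | None = None

    def validate(self) -> "ExpressionMatrix":
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("non-finite expression value")
        if self.groups is not None:
            unknown = set(self.groups.index) - set(self.data.columns)
            if unknown:
                raise ValueError(f"group labels for unknown samples: {sorted(unknown)[:5]}")
        return self

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DifferentialResult:
    """Per-gene differential call table: lfc, t, p, BH q, call."""

    table: pd.DataFrame  # index: gene_id; columns lfc, t, p, q, call
    fc_thresh: float
    q_thresh: float

    def validate(self) -> "DifferentialResult":
        t = self.table
        if not ((t["q"] >= 0) & (t["q"] <= 1)).all():
            raise ValueError("q-values outside [0, 1]")
        if not set(t["call"]) <= {"up", "down", "unchanged"}:
            raise ValueError("unknown call label")
        return self

    def genes(self, call: str) -> set[str]:
        return set(self.table.index[self.table["call"] == call])

    @property
    def up(self) -> set[str]:
        return self.genes("up")

    @property
    def down(self) -> set[str]:
        return self.genes("down")


@dataclass
class GroundTruth:
    """Planted truth emitted by the generator, consumed only by tests/reports."""

    bound_genes: set[str]
    de_genes_up: set[str]
    de_genes_down: set[str]
    monotone_genes: set[str]
    signature_genes: set[str]
    enriched_celltypes: set[str]
    driver_gene: str | None = None
    # per-context bound subsets (e.g. 'bcell', 'esc'); empty dict = all shared
    context_bound: dict[str, set[str]] = field(default_factory=dict)
    # bookkeeping for calibration tests: where binding was planted
    ebox_offsets: dict[str, int] = field(default_factory=dict)
    planted_regions: pd.DataFrame | None = None  # gene_id, chrom, start, end

    def validate(self, annotation: GenomeAnnotation | None = None) -> "GroundTruth":
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("a gene is planted both up and down")
        if not self.signature_genes <= (self.bound_genes & self.de_genes_up):
            raise ValueError("signature genes must be planted bound and up-regulated")
        for ctx, genes in self.context_bound.items():
            if not genes <= self.bound_genes:
                raise ValueError(f"context {ctx!r} bound set outside bound_genes")
            if not self.signature_genes <= genes:
                raise ValueError(f"signature genes missing from context {ctx!r}")
        if annotation is not None:
            universe = set(annotation.gene_ids)
            for name in ("bound_genes", "de_genes_up", "de_genes_down",
                         "monotone_genes", "signature_genes"):
                extra = getattr(self, name) - universe
                if extra:
                    raise ValueError(f"{name} outside annotation: {sorted(extra)[:5]}")
        return self


@dataclass
class TargetSet:
    """Direction-labelled direct-target sets for one cellular context."""

    context: str
    induced: set[str]
    repressed: set[str]
    bound: set[str]
    provenance: list[dict] = field(default_factory=list)

    def validate(self) -> "TargetSet":
        if self.induced & self.repressed:
            raise ValueError("induced and repressed sets intersect")
        if not (self.induced | self.repressed) <= self.bound:
            raise ValueError("responsive genes must be bound in their context")
        return self


@dataclass
class OrthologMap:
    """Partial human → murine gene-id mapping."""

    pairs: dict[str, str]
    unmapped: set[str] = field(default_factory=set)

    def validate(self) -> "OrthologMap":
        if self.unmapped & set(self.pairs):
            raise ValueError("gene listed both mapped and unmapped")
        return self

    def get(self, human_id: str) -> str | None:
        return self.pairs.get(human_id)


@dataclass
class CoreSignature:
    """The cross-context core target signature with derivation provenance."""

    genes: list[str]
    contexts: list[str]
    provenance: list[dict] = field(default_factory=list)

    def validate(self) -> "CoreSignature":
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        return self


@dataclass
class CompendiumStudy:
    """Large multi-cell-type expression compendium with a named driver gene."""

    expression: ExpressionMatrix
    celltype: pd.Series  # sample -> label
    tumor: pd.Series  # sample -> bool
    driver_gene: str

    def validate(self) -> "CompendiumStudy":
        self.expression.validate()
        samples = set(self.expression.sample_ids)
        if set(self.celltype.index) != samples or set(self.tumor.index) != samples:
            raise ValueError("every sample needs a cell-type label and tumor flag")
        if self.driver_gene not in self.expression.data.index:
            raise ValueError(f"driver gene {self.driver_gene!r} not in matrix")
        return self


@dataclass
class ProgressionStudy:
    """Three-group ordered design: group_order[0] < [1] < [2] severity."""

    expression: ExpressionMatrix
    group_order: tuple[str, str, str]

    def validate(self) -> "ProgressionStudy":
        self.expression.validate()
        if self.expression.groups is None:
            raise ValueError("progression study requires sample group labels")
        counts = self.expression.groups.value_counts()
        for g in self.group_order:
            if counts.get(g, 0) == 0:
                raise ValueError(f"empty group {g!r}")
        return self
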