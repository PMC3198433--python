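"""Configuration objects for the simulator and the end-to-end pipeline.

Defaults encode the study conditions the pipeline is meant to emulate:
a 51-gene core signature, an 8129-sample / 312-cell-type compendium with a
57.7% marginal tumor fraction and a driver–signature population correlation
of 0.47, a ~25% background fraction of monotonically increasing genes in the
three-group progression design, and promoter tiling at 35 bp spacing over a
−8 kb…+2 kb window around each TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["CompendiumConfig", "SimulationConfig", "PipelineConfig", "beta_for_target_r"]


def beta_for_target_r(r: float, k: int, gene_noise_sd: float = 1.0) -> float:
    """Regression slope giving population correlation ``r`` between driver and
    a k-gene mean-z signature score under the generator's linear model.

    Each signature gene is ``beta * d + e`` with ``e ~ N(0, gene_noise_sd^2)``
    and driver latent ``d ~ N(0, 1)``; the score is the mean of per-gene
    z-scores, so ``r = beta / sqrt(beta^2 + gene_noise_sd^2 / k)``.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError("target correlation must be in [0, 1)")
    if r == 0.0:
        return 0.0
    return math.sqrt((gene_noise_sd**2 / k) * r**2 / (1.0 - r**2))


@dataclass
class CompendiumConfig:
    """Shape of the synthetic multi-cell-type compendium."""

    n_samples: int = 8129
    n_celltypes: int = 312
    signature_size: int = 51
    driver_beta: float | None = None  # None -> solved from target_r
    target_r: float = 0.47
    gene_noise_sd: float = 1.0
    n_enriched_celltypes: int = 8
    celltype_driver_bias: float = 1.5
    tumor_fraction: float = 0.577
    tumor_dp_bias: float = 3.0  # logistic slope of tumor probability on driver level

    def resolved_beta(self) -> float:
        if self.driver_beta is not None:
            return self.driver_beta
        return beta_for_target_r(self.target_r, self.signature_size, self.gene_noise_sd)

    def validate(self) -> "CompendiumConfig":
        if self.n_samples <= 0 or self.n_celltypes <= 0 or self.signature_size <= 0:
            raise ValueError("compendium counts must be positive")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.n_enriched_celltypes > self.n_celltypes:
            raise ValueError("more enriched cell types than cell types")
        return self


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    ``binding_shift`` is the additive log2 IP enrichment over a planted
    ~500 bp region centred on the planted E-box; ``noise_sd`` is the Gaussian
    sd of log2 intensities/expression; ``de_log2fc`` the planted expression
    shift; fractions are of ``n_genes``.
    """

    seed: int = 0
    n_genes: int = 2000
    promoter_window: tuple[int, int] = (8000, 2000)  # (upstream, downstream) of TSS
    probe_spacing_bp: int = 35
    probe_length_bp: int = 25
    n_rep_ip: int = 3
    n_rep_ctrl: int = 3
    n_rep_expr: int = 6
    bound_fraction: float = 0.10
    binding_shift: float = 1.5
    planted_region_bp: int = 500
    noise_sd: float = 0.3
    baseline_log2: float = 8.0
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    monotone_fraction_bg: float = 0.10
    ortholog_unmapped_fraction: float = 0.05
    mouse_probe_dropout: float = 0.05
    context_extra_bound_fraction: float = 0.05
    compendium: CompendiumConfig = field(default_factory=CompendiumConfig)

    def validate(self) -> "SimulationConfig":
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.probe_spacing_bp < 1:
            raise ValueError("probe_spacing_bp must be >= 1")
        for name in ("bound_fraction", "de_fraction", "monotone_fraction_bg",
                     "ortholog_unmapped_fraction", "mouse_probe_dropout",
                     "context_extra_bound_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_rep_ip", "n_rep_ctrl", "n_rep_expr",
                     "probe_length_bp", "planted_region_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        up, down = self.promoter_window
        if up < 0 or down < 0 or up + down < self.planted_region_bp:
            raise ValueError("promoter window must be non-negative and fit a planted region")
        self.compendium.validate()
        return self


_SIM_TUPLE_FIELDS = ("promoter_window",)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: simulation knobs plus stage tunables."""

    out_dir: str = "results/pipeline"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # peak calling
    ma_window_probes: int = 5
    region_threshold: float | None = None  # None -> chosen by FDR sweep
    fdr_target: float = 0.10
    max_gap_bp: int = 300
    min_probes: int = 3
    n_fdr_swaps: int = 10
    # differential expression
    fc_thresh: float = 0.585
    q_thresh: float = 0.05
    # compendium
    permutation_b: int = 1000
    dp_quantile: float = 0.75
    enrichment_fdr: float = 0.05
    # progression clustering
    cluster_k: int = 2
    # ChIP-seq display scan
    scan_window_bp: int = 100
    scan_step_bp: int = 25
    chipseq_reads: int = 200_000
    chipseq_enrichment: float = 8.0

    def validate(self) -> "PipelineConfig":
        self.simulation.validate()
        if self.ma_window_probes < 1 or self.ma_window_probes % 2 == 0:
            raise ValueError("ma_window_probes must be odd and >= 1")
        if not 0.0 < self.fdr_target <= 1.0:
            raise ValueError("fdr_target must be in (0, 1]")
        if not 0.0 < self.dp_quantile < 1.0:
            raise ValueError("dp_quantile must be in (0, 1)")
        if self.permutation_b < 1:
            raise ValueError("permutation_b must be >= 1")
        if self.scan_step_bp <= 0 or self.scan_window_bp < self.scan_step_bp:
            raise ValueError("need scan_step_bp > 0 and scan_window_bp >= scan_step_bp")
        return self

    # ---- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["promoter_window"] = list(d["simulation"]["promoter_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        comp = dict(sim.pop("compendium", {}))
        _reject_unknown(comp, CompendiumConfig, "simulation.compendium")
        _reject_unknown(sim, SimulationConfig, "simulation", skip={"compendium"})
        _reject_unknown(d, cls, "pipeline", skip={"simulation"})
        if "promoter_window" in sim:
            sim["promoter_window"] = tuple(sim["promoter_window"])
        sim_cfg = SimulationConfig(**sim, compendium=CompendiumConfig(**comp))
        return cls(**d, simulation=sim_cfg).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _reject_unknown(d: dict, cls: type, where: str, skip: set[str] = frozenset()) -> None:
    known = set(cls.__dataclass_fields__) - skip  # type: ignore[attr-defined]
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")
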