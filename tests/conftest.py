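import numpy as np
import pandas as pd
import pytest

from mycoresig import CompendiumConfig, SimulationConfig
from mycoresig import synthdata
from mycoresig.containers import ScoreTrack, TilingProbeSet


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    params = dict(
        seed=seed,
        n_genes=60,
        compendium=CompendiumConfig(
            n_samples=300, n_celltypes=20, signature_size=10, n_enriched_celltypes=2
        ),
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_world(small_cfg):
    truth = synthdata.plant_truth(small_cfg)
    annotation, promoters, truth = synthdata.make_annotation(small_cfg, truth)
    return small_cfg, annotation, promoters, truth


def random_tiling(
    rng: np.random.Generator,
    n_probes: int = 20,
    n_ip: int = 2,
    n_ctrl: int = 2,
    n_chroms: int = 1,
    spacing: int = 35,
) -> TilingProbeSet:
    """Small random tiling instance with occasional large (segment-breaking) gaps."""
    chroms = sorted(rng.choice([f"chr{i}" for i in range(1, n_chroms + 1)], n_probes))
    starts = []
    pos = 0
    prev = None
    for c in chroms:
        if c != prev:
            pos = 0
            prev = c
        pos += spacing if rng.random() > 0.15 else spacing * 40
        starts.append(pos)
    probes = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": np.array(starts) + 25,
            "probe_id": [f"p{i}" for i in range(n_probes)],
        }
    )
    intensities = rng.normal(8.0, 1.0, size=(n_ip + n_ctrl, n_probes))
    labels = ["IP"] * n_ip + ["control"] * n_ctrl
    return TilingProbeSet(probes, intensities, labels).validate()


def track_from(probes: pd.DataFrame, m) -> ScoreTrack:
    return ScoreTrack(probes, np.asarray(m, dtype=float)).validate()
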