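"""Shared paths and configuration for the numbered analysis scripts.

Every script reads the demo study configuration, works under
``results/analysis`` and communicates through the package's plain-text
formats, so each step can be inspected or rerun in isolation.
"""

from pathlib import Path

from mycoresig import PipelineConfig

REPO = Path(__file__).resolve().parents[1]
CONFIG = REPO / "configs" / "demo.yaml"
OUT = REPO / "results" / "analysis"
DATA = OUT / "data"


def load_config() -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(CONFIG)
    cfg.out_dir = str(OUT)
    return cfg
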