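"""Test the core signature on the three-group progression design
(wild-type -> premalignant -> malignant): strict monotone-pattern
fractions, enrichment fold over the array background, and signature-based
sample clustering.

Finding (demo scale): nearly all signature genes rise strictly across the
three groups, against a ~25% background fraction (planted: 10% forced
increasing plus the 1/6 exchangeable null), a greater-than-threefold
enrichment; clustering on the signature separates malignant from wild-type
samples.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from analysis_config import DATA, OUT, load_config

import pandas as pd

from mycoresig import io
from mycoresig.containers import ProgressionStudy
from mycoresig.progression import (
    cluster_samples,
    monotone_fraction,
    pattern_enrichment_fold,
)


def main() -> None:
    cfg = load_config()
    meta = io.read_sample_metadata(DATA / "progression_samples.tsv")
    expr = io.read_expression(DATA / "progression.tsv", meta["group"])
    study = ProgressionStudy(expr, ("wt", "pre", "tum")).validate()

    ortholog = io.read_ortholog_map(DATA / "ortholog_map.tsv")
    core = io.read_gene_set(OUT / "core_signature.txt")
    mouse_core = sorted(m for m in (ortholog.get(g) for g in core) if m is not None)

    inc = monotone_fraction(study, mouse_core, "increasing")
    bg = monotone_fraction(study, expr.gene_ids, "increasing")
    fold = pattern_enrichment_fold(inc[0] / inc[1], bg[0] / bg[1])

    order, labels = cluster_samples(expr, mouse_core, cfg.cluster_k)
    pd.DataFrame(
        {"sample_id": order, "cluster": [labels[s] for s in order],
         "group": [meta.loc[s, "group"] for s in order]}
    ).to_csv(OUT / "cluster_order.tsv", sep="\t", index=False)

    print(f"signature genes with murine probes: {inc[1]} of {len(core)}")
    print(f"strictly increasing: {inc[0]}/{inc[1]} ({inc[2]}%) of the signature "
          f"vs {bg[0]}/{bg[1]} ({bg[2]}%) of the array background")
    print(f"enrichment fold: {fold:.2f} (>3 indicates the signature tracks progression)")


if __name__ == "__main__":
    main()
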