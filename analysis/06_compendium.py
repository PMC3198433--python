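"""Score the core signature across the multi-cell-type compendium: Pearson
correlation with the driver gene against a random-gene-set permutation
null, double-positive classification at the 75th percentile, cell-type
enrichment of double positives, and their tumor composition.

Finding (demo scale): the signature score tracks the driver across
heterogeneous cell types (r near the planted 0.47, permutation p at its
lower bound), the planted driver-high cell types are flagged as enriched,
and double-positive samples are overwhelmingly tumors against a ~58%
tumor background.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from analysis_config import DATA, OUT, load_config

from mycoresig import io
from mycoresig.compendium import analyze_compendium
from mycoresig.containers import CompendiumStudy


def main() -> None:
    cfg = load_config()
    meta = io.read_sample_metadata(DATA / "compendium_samples.tsv")
    expr = io.read_expression(DATA / "compendium.tsv")
    truth = io.read_truth(DATA / "ground_truth.json")
    study = CompendiumStudy(
        expr, meta["celltype"], meta["tumor"].astype(bool), truth.driver_gene
    ).validate()

    core = sorted(io.read_gene_set(OUT / "core_signature.txt"))
    result = analyze_compendium(
        study, core, b=cfg.permutation_b, seed=cfg.simulation.seed,
        quantile=cfg.dp_quantile, fdr_target=cfg.enrichment_fdr,
    )
    result.scores.to_frame().to_csv(OUT / "compendium_scores.tsv", sep="\t")
    result.enrichment.to_csv(OUT / "celltype_enrichment.tsv", sep="\t", index=False)

    dp, overall = result.dp_tumor, result.overall_tumor
    enriched = sorted(result.enrichment.loc[result.enrichment["enriched"], "celltype"])
    print(f"driver-signature correlation r = {result.r:.3f} "
          f"(permutation p = {result.p:.4g}, B = {result.b})")
    print(f"double positives: {dp[1]} samples, {dp[0]} tumors ({dp[2]}%) "
          f"vs {overall[2]}% tumors overall")
    print(f"enriched cell types at FDR {cfg.enrichment_fdr:.0%}: {enriched} "
          f"(planted: {sorted(truth.enriched_celltypes)})")


if __name__ == "__main__":
    main()
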