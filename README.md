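# mycoresig

Deriving a **cell-type- and species-independent core target signature** for
a driver transcription factor, and testing what that signature does — as a
reusable, fully tested pipeline exercised end-to-end on synthetic data with
planted ground truth.

The motivating biology is the MYC/E-box system: a transcription factor
whose binding (ChIP on promoter tiling arrays, read out with a
moving-average statistic and an empirical label-swap FDR), transcriptional
response (array-based nuclear run-on), and steady-state RNA response are
intersected to define *direct targets*; the induced targets are then
filtered through binding evidence from additional human cell contexts and,
via an ortholog map, a second species, yielding a core signature. Three
downstream statistics characterize such a signature:

- **Compendium correlation** — the per-sample signature score (mean of
  per-gene z-scores) versus the driver's expression across a large
  heterogeneous compendium, with a permutation p-value from random gene
  sets of the same size;
- **Double-positive enrichment** — cell types over-represented among
  samples high on both driver and signature (hypergeometric + BH), and the
  tumor composition of those samples;
- **Progression patterns** — the fraction of signature genes with strictly
  increasing group means across an ordered wild-type → premalignant →
  malignant design (null: exactly 1/6 under exchangeability), its fold
  enrichment over background, and signature-based sample clustering.

Who this is for: anyone who wants the *procedure* — peak calling on tiling
probes, evidence intersection with provenance, signature scoring with
honest nulls — as importable, tested code, with a generator that plants
known truth so every stage's error rates can be checked.

## Worked example

The demo study (200 genes, 20-gene planted signature) runs end-to-end from
one config:

```bash
mycoresig run --config configs/demo.yaml
```

or as stepwise analysis scripts that communicate through plain-text files:

```bash
python analysis/01_simulate.py
python analysis/02_call_peaks.py
python analysis/03_differential.py
python analysis/04_core_signature.py
python analysis/05_progression.py
python analysis/06_compendium.py
```

which prints (seed 1):

```
bcell_sc: 48 regions in 48 genes (threshold 0.632, estimated FDR 10.000%)
...
consensus binding: 42 genes (48 SC-like / 43 Epit-like antibody)
B-cell direct targets: 23 induced, 4 repressed
shared up-regulated with stem cells: 20
core signature after cancer-line + mouse filters: 20 genes (planted 20; recovered exactly: True)
cell-type-restricted targets: 6 B-cell, 8 stem-cell
strictly increasing: 20/20 (100.0%) of the signature vs 55/184 (29.9%) of the array background
enrichment fold: 3.35 (>3 indicates the signature tracks progression)
driver-signature correlation r = 0.514 (permutation p = 0.005, B = 199)
double positives: 75 samples, 75 tumors (100.0%) vs 57.5% tumors overall
enriched cell types at FDR 5%: ['ct024', 'ct026', 'ct028'] (planted: ['ct024', 'ct026', 'ct028'])
```

Reading this: peak calling found essentially one region per planted bound
gene at the 10% FDR target; the two-antibody consensus, run-on + RNA
intersection, and cross-context filters reduced 42 consensus-bound genes to
exactly the 20 planted core genes; the signature rises monotonically across
the progression groups more than 3× as often as background; and across the
heterogeneous compendium the signature score tracks the driver (r ≈ 0.5, p
at the permutation floor), with double-positive samples almost all tumors
against a 57.5% tumor background, concentrated in the three planted cell
types.

Individual stages are also available as subcommands (`mycoresig callpeaks`,
`scanreads`, `eboxes`, `de`, `compendium`, `progression`, `cluster`) over
the same file formats; see `mycoresig --help`.

## Layout

```
src/mycoresig/      library: synthdata, peaks, expression, targets,
                    compendium, progression, pipeline, io, cli
analysis/           numbered narrative drivers over the library
configs/demo.yaml   the end-to-end demo study
scripts/acceptance.py  full-scale recomputation of the headline numbers
docs/methods.md     models, assumptions, parameter rationale, limitations
tests/              unit, property, calibration and acceptance tests
```
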