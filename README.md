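# nichequant

Spatial immune-niche quantification and phase-2 trial correlative
statistics, exercised entirely on synthetic and bundled summary data.

The package covers the analysis chain of a single-arm neoadjuvant trial
with multiplex-immunofluorescence (mIF) correlatives:

- **`nichequant.synth`** — synthetic tissues (background Poisson cells plus
  planted niche discs with analytic true coverage) and synthetic clinical
  cohorts (planted partial-response counts, log-normal analyte fold
  changes, Bernoulli ctDNA detection flags), all deterministic under a seed.
- **`nichequant.phenotype`** — per-cell phenotype calls (DAPI gating,
  thresholds explicit or per-tissue Otsu "auto"; TCF1 evaluated inside
  CD8+ cells only) and percent-of-DAPI composition fractions.
- **`nichequant.spatial`** — sliding-window density grids, immune-niche
  detection (default: both ≥ 16 MHC-II+/mm² and ≥ 4 TCF1+CD8+/mm² inside
  the same 1-mm² window, 250 µm stride), niche coverage, nearest-neighbor
  distances, and GeoJSON immunomap export.
- **`nichequant.clinical`** — RECIST 1.1 target-lesion classification,
  objective response rate with Clopper–Pearson CI, exact operating
  characteristics of a two-stage futility design, Kaplan–Meier estimation,
  adverse-event tabulation.
- **`nichequant.correlative`** — baseline-anchored fold changes, exact/
  asymptotic Wilcoxon signed-rank and Mann–Whitney tests, Spearman
  correlation (optional exact permutation), ctDNA detection-rate and
  variant-table summaries.
- **`nichequant.datasets`** — the bundled trial summary tables (best
  responses, adverse events, detection flags, variants) used by the worked
  examples.

## CLI

```sh
nichequant simulate --out run/ --seed 1          # synthetic bundle + truth
nichequant phenotype --cells run/cells.csv --out run/pheno.csv
nichequant niches --pheno run/pheno.csv --mask run/tumor_mask.geojson --out run/grid.csv
nichequant immunomap --pheno run/pheno.csv --mask run/tumor_mask.geojson --out run/map.geojson
nichequant clinical --lesions run/lesions.csv --survival run/survival.csv \
    --design n1=11,stop=0,n=17,reject=3 --out run/clinical.json
nichequant correlate --panel run/panel.csv --flags run/flags.csv --out run/corr.json
nichequant report --out run/                     # full pipeline from one config
nichequant validate --cells run/cells.csv        # schema / unit sanity checks
```

Exit codes: 0 success, 2 validation failure, 3 stage failure.  `report`
accepts `--config cfg.yaml`; reruns with the same config and seed are
byte-identical.

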