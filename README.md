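# stereovary

Stereological maturity analysis of fish ovary cross-sections.

The package implements a quantitative-histology pipeline for assessing
female maturity in teleosts:

- **`stereovary.stages`** — the ordered germ-cell stage taxonomy (oogonia
  `og` through hydrated oocyte `ho`, plus the post-ovulatory follicle `POF`)
  with per-stage follicle-diameter distributions and zona pellucida
  thicknesses, and the display grouping `pca / cao / vit / pho / ho / POF`.
- **`stereovary.synthetic`** — a synthetic section generator that packs
  non-overlapping circular follicles into a rendered ovary section (wall,
  lumen, germinal epithelium, blood vessels) with *exact* pixel-count ground
  truth, plus a fish-population generator whose maturity-by-length follows a
  configurable logistic curve.
- **`stereovary.stereology`** — gray-level tissue segmentation (Otsu or
  fixed threshold), a systematic uniform random point grid of 500–600
  in-mask points, point annotation against a label image, and the %GCS
  estimator (each germ structure's share of germ-cell points, in exact
  rational arithmetic).
- **`stereovary.staging`** — most-advanced-stage classification, two binary
  maturity rules (`vit_presence`, used for the ogive, and `cao_presence`),
  the A–D maturity-phase call with D > C > B > A precedence, and grouped
  summary tables (by month, 1-cm length class, or visual phase).
- **`stereovary.biometrics`** — gonadosomatic index and
  nuclear/cytoplasmic-ratio computations.
- **`stereovary.ogive`** — maximum-likelihood logistic ogive of maturity on
  length, L50 = −intercept/slope, non-parametric case bootstrap with
  percentile confidence intervals, and Nagelkerke's R².
- **`stereovary.io` / `stereovary.cli`** — CSV/TIFF/JSON I/O, YAML run
  configuration, and a subcommand CLI.

## CLI

```sh
stereovary simulate-section --width 1200 --height 900 \
    --composition '{"pca": 0.6, "cao": 0.4}' --seed 1 --out section.tiff
stereovary simulate-population --n-fish 151 --true-l50 20.6 --seed 1 --out pop.csv
stereovary grid --image section.png --seed 2 --out grid.csv
stereovary estimate --annotations readings.csv --out composition.csv
stereovary stage --annotations readings.csv --biometrics bio.csv --out staged.csv
stereovary summarize --staged staged.csv --group-by month --out-prefix summary
stereovary ogive --staged staged.csv --seed 3 --out ogive.json
stereovary run --config run.yaml
```

`stereovary run` executes the whole pipeline (synthetic mode generates a
population and emulates the stereology read; annotations mode consumes
point-annotation and biometrics CSVs) and writes staged records, summary
tables, an ogive report under both maturity rules, and a `manifest.json`
naming the seed and config hash.

## Annotation format

Point annotations are CSV with columns `slide_id, point_id, x, y, structure`.
The structure vocabulary is `og po1 po2 cao vit1 vit2 vit3 pho ho POF`
(germ structures counted in %GCS), `aoa aob lysis` (atresia/lysis, counted
but excluded from the germ denominator), and
`wall epithelium lumen blood_vessel unknown`. A mapping table can translate
arbitrary raw labels into this vocabulary.
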