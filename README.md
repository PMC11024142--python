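# cupid

Tissue-of-origin classification from cfDNA methylation-enrichment
sequencing counts.

The package implements the full model-building pipeline:

1. **`genome_windows`** — tile a genome into fixed 300-bp windows,
   annotate CpG density, and mask over-represented windows (top 0.1% of
   pooled control counts plus top-1% neighbours).
2. **`fragment_counts`** — filter paired-end fragments (MAPQ of either
   mate ≥ 10, reference span 90–1000 bp), assign them to windows by
   midpoint, and derive NRPM (normalised reads per million, CNV-corrected)
   and blind-calibrated beta views.
3. **`qc_metrics`** — relative CpG enrichment (relH) and the hyperstable
   fraction (share of a designated always-methylated window panel with
   beta ≥ 0.8); samples failing relH < 2.5 or hyperstable fraction < 0.4
   are gated out.
4. **`array_conversion`** — regroup methylation-array cohorts into the
   30-class scheme (shipped as `config/class_map.tsv`), collapse probe
   betas onto windows (max per window), learn a (CpG density, beta) →
   expected-NRPM calibration table from pooled non-cancer controls, and
   draw pseudo enrichment-seq counts from array betas.
5. **`mixture_simulator`** — in-silico cfDNA samples: converted tumour
   arrays spiked into NCC profiles at 0.5–10% tumour fraction (NCC–NCC
   pairs at 15–50%), multinomial at a random depth.
6. **`dmr_selection`** — pairwise Welch tests on per-window betas with
   Benjamini–Hochberg control (FDR 0.001), keeping the top/bottom 250
   windows per class pair by mean-beta difference.
7. **`ensemble`** — a bagged ensemble of gradient-boosted sub-classifiers
   (each trained on mixtures from 80% of arrays / 80% of NCCs, 200 trees,
   50% row subsampling, ~10% feature subsampling), mean-score prediction
   with the >0.5 call rule and non-cancer override, held-out scoring,
   Hand–Till multi-class AUROC, and cohort evaluation summaries.
8. **`synthetic_data`** — a deterministic toy generator (genome with
   stratified CpG densities, class-specific methylation signatures,
   logistic density-dependent enrichment) so every stage is testable
   offline.
9. **`pipeline`** / **`cli`** — YAML-configured orchestration with a
   reproducibility manifest.

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (worked
evaluation examples, call-rule soundness over 10⁵ score simplexes,
Hand–Till vs. a brute-force oracle, planted-marker DMR retrieval with an
all-null grid, mixture-simulator statistics, conversion round-trip
recovery, an end-to-end toy run reaching held-out AUROC ≥ 0.95 with
tumour-fraction monotonicity, and QC gate boundaries). All fixtures are
generated programmatically.

## CLI

```sh
cupid tile --fasta ref.fa --window-size 300 --out windows.bed
cupid count --fragments s1.bed --windows windows.bed --out counts.tsv
cupid beta --counts counts.tsv --windows windows.bed --out beta.tsv
cupid qc --fragments s1.bed --fasta ref.fa --beta beta.tsv --panel panel.bed --out qc.tsv
cupid calibration --ncc-counts ncc.tsv --windows windows.bed --out table.tsv
cupid --seed 7 convert --beta arrays.tsv --table table.tsv --windows windows.bed --out conv.tsv
cupid dmr --beta arrays.tsv --classes labels.tsv --fdr 0.001 --n-top 250 --out catalog.tsv
cupid --seed 17 mix --arrays conv.tsv --array-labels labels.tsv --nccs ncc.tsv --out-prefix mixtures
cupid --seed 21 train --mixtures mixtures --dmr-regions dmr_regions.bed --out model/
cupid predict --model model/ --counts sample_counts.tsv --out predictions.tsv
cupid evaluate --predictions predictions.tsv --truth truth.tsv
cupid run --config toy.yaml --out rundir/   # full synthetic end-to-end
```

`cupid run` executes tile → mask → qc → calibrate → convert → dmr → mix →
train → held-out evaluation on synthetic data and writes a
`manifest.json` capturing seeds, parameters, and artifact hashes; reruns
with the same config are bit-identical.

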