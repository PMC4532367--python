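# hifbind

Analysis pipeline for dissecting isoform-specific transcription-factor DNA
binding and its prognostic associations, built around ChIP-seq peak sets for
two competing factor isoforms (e.g. HIF-1α vs HIF-2α), their co-factor
signal, matched RNA-seq, and a clinical expression cohort.

The pipeline covers:

- **Consensus peak definition and quantification** (`peak_quant`): dual-caller
  intersection, RPKM normalisation, filtering against the 99.99th percentile
  of random background regions, cross-condition scatter/equity summaries,
  and an SVD-based PCA biplot.
- **Motif likelihood scanning** (`motif_nlr`): the normalised likelihood-ratio
  score — per window, the arithmetic mean over motif positions of
  PWM(b,i)/B(b); per region, the maximum over windows and strands, reported
  as log2. Includes a LOO-CV-smoothed trend of scores against co-factor rank
  and a Mann-Whitney differential-distribution test between site sets.
  A conventional product-form likelihood ratio is available via
  `--nlr-form product`.
- **Site annotation** (`site_annotation`): nearest-TSS links with signed
  summit-to-TSS distances, gene-class breakdowns, ≥3-fold isoform-specific
  site classification (pseudocount ε=1), and 10-kb gene capture.
- **Differential expression** (`expression_de`): per-gene two-group negative
  binomial likelihood-ratio test (df-corrected Pearson dispersion,
  F(1, n−2) reference — asymptotically the 1-df chi-square), median-of-ratios
  size factors, and the signed ranking statistic π = log2FC · (−log10 p).
- **Pre-ranked GSEA** (`gsea`): weighted running-sum enrichment score with a
  gene-set permutation null (add-one-corrected, sign-matched p-values) and a
  two-tail report.
- **Prognosis** (`prognosis_spca`): 0–4 clinical stratification score,
  Kaplan-Meier estimator, a fast vectorised univariate Cox solver (Efron
  ties), univariate screening, a supervised-PCA gene predictor (SVD weights,
  hazard-oriented sign), leave-one-out cross-validation, and median-split
  evaluation.
- **Synthetic data** (`synthetic_data`): seeded generators that reproduce the
  statistical structure every stage assumes (fold-gapped site sets, coupled
  co-factor signal, rank-dependent motif planting, binding-coupled DE, a
  latent-factor survival cohort), so the whole pipeline is testable offline.
- **I/O** (`io_formats`): BED3/narrowPeak, JASPAR flat-text PWMs, FASTA,
  typed TSV tables. Coordinates are 0-based half-open throughout.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, calibration, and planted-structure recovery); the rest are
per-module unit and property tests.

## CLI

Everything is exposed under a single `hifbind` entry point:

```sh
hifbind simulate --outdir sim/ --seed 13            # full synthetic dataset
hifbind quantify --peaks-a a.bed --peaks-b b.bed \
    --signal signal.tsv --background bg.tsv --tail 0.0001 --out matrix.tsv
hifbind pca --matrix matrix.tsv --out biplot.tsv
hifbind scan-motifs --fasta peaks.fa --pwm jaspar.txt \
    --motif MA0259.1 --motif MA0491.1 --both-strands --out scans.tsv
hifbind annotate --peaks peaks.bed --genes genes.tsv --matrix matrix.tsv \
    --out-links links.tsv --out-calls calls.tsv
hifbind de --counts counts.tsv --groups groups.tsv --out de.tsv
hifbind rank --de de.tsv --out ranked.tsv            # accepts external DE tables
hifbind gsea --ranked ranked.tsv --sets sets.gmt --nperm 10000 --seed 17 --out gsea.tsv
hifbind stratify --clinical clinical.tsv --out groups.tsv
hifbind spca --expr expr.tsv --clinical clinical.tsv --loo \
    --out-model model.json --out-scores scores.tsv
```

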