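# tcsp — T cell subtype profiling of bulk RNA-seq

`tcsp` estimates the mRNA fractions of five functional T-cell subtypes —
naïve (N), activated (A), exhausted (EX), effector memory (EM) and central
memory (CM) — in bulk RNA-seq samples. It covers the full workflow:

1. **Signature construction** (`tcsp.signature`) — builds the five-subtype
   signature matrix S from labeled reference CPM profiles: per-subtype
   log2 fold-difference ranking, coefficient-of-variation and minimum-CPM
   gates, mean-CPM model assembly, and filtering of genes broadly expressed
   in a tumor background (cell-line) panel.
2. **Deconvolution** (`tcsp.deconvolve`) — solves the linear mixture
   `B = S × F` per sample with no-intercept linear epsilon-SVR after
   normalizing both sides by the per-gene maximum of S; reports raw 0–100
   estimates, their sum, sum-normalized fractions and composite ratios
   such as EX/EM.
3. **Synthetic data** (`tcsp.synthesis`) — seeded generators for reference
   profiles with planted markers, tumor background panels, and count-level
   titrations/mixtures with known ground-truth fractions.
4. **Biomarker harness** (`tcsp.biomarker`) — bootstrap out-of-bag
   cross-validation of projection + classifier pipelines over subtype or
   gene-set features, mean-OOB ROC/AUC, model selection, Kaplan–Meier /
   log-rank stratification at score 0.5, and one-sided Mann–Whitney tests
   (exact by enumeration for small samples).

## CLI

```sh
# simulate a seeded synthetic dataset with ground truth
tcsp simulate reference  --seed 5 --out sim/reference
tcsp simulate background --seed 5 --out sim/background
tcsp simulate titration  --seed 5 --out sim/titration

# build the signature model from labeled reference counts
tcsp build-shem \
  --counts sim/reference/reference_counts.tsv \
  --labels sim/reference/reference_labels.tsv \
  --background sim/background/background_cpm.tsv \
  --origins sim/background/background_origins.tsv \
  --out model/shem.tsv

# estimate subtype fractions of bulk samples
tcsp estimate --counts sim/titration/titration_counts.tsv \
  --model model/shem.tsv --normalized --ratios EX/EM --out estimates.tsv

# evaluate a titration against its ground truth
tcsp titrate --model model/shem.tsv \
  --titration sim/titration/titration_counts.tsv \
  --truth sim/titration/ground_truth.json --out titrate_out/

# bootstrap out-of-bag biomarker selection
tcsp biomarker --features features.tsv --labels labels.tsv \
  --survival survival.tsv --grid default --n-boot 200 --seed 7 --out bm_out/
```

All tables are tab-separated text with gene symbols in the first column.
Every command writes a `run_manifest.json` (version, effective config,
seed, input checksums); identical seeds give byte-identical outputs.

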