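# spatialprot

Replicate-free spatial tumor-proteomics inference, as a tested and reusable
pipeline: from PSM-level TMT reporter-ion tables through differential
expression calling with a two-component empirical-null model, cross-specimen
recurrence, spatial profile soft clustering, ranked enrichment,
compartment-shift testing, and mtDNA qPCR quantification. A synthetic-data
generator provides ground truth for every stage.

## Stages

| Module | What it does |
| --- | --- |
| `spatialprot.core` / `spatialprot.io` | Domain types (PSM tables, design tables, protein matrices, annotations, qPCR Ct tables) and TSV/GMT readers and writers |
| `spatialprot.simulate` | Synthetic experiments with planted effects, channel loadings, additive–multiplicative noise, contaminant/decoy rows, compartment shifts, spatial gradients, correlated transcript fold changes, and technical-duplicate Ct tables |
| `spatialprot.preprocess` | Contaminant/decoy/intensity filtering (strict > 1000 in all relevant channels), affine + generalized-log variance-stabilizing normalization, median peptide→protein summarization (≥ 2 proteotypic peptides), quantile normalization, LFQ fold changes |
| `spatialprot.diffexp` | Median-centered log2 ratios per patient, Grenander density estimation, two-component empirical-null fit (σ₀, η₀, local fdr, tail-area q-values), calls at q < 0.2, recurrence across specimens, averaged-fold-change analysis, protein-only filtering, transcriptome concordance |
| `spatialprot.spatial` | Sample Pearson correlation, average-linkage hierarchical clustering on 1 − r, profile standardization, fuzzy c-means with seeded restarts, elbow (minimum-centroid-distance) selection of the cluster number |
| `spatialprot.annotation` | Minimal-hypergeometric ranked enrichment with exact DP p-values (both directions), Wilcoxon rank-sum compartment-shift test |
| `spatialprot.qpcr` | ΔΔCt relative mtDNA quantification with technical-replicate averaging (efficiency fixed at 2.0; targets reported separately) |
| `spatialprot.pipeline` / `spatialprot.cli` | End-to-end orchestration from one YAML config with per-stage seed substreams, content digests, and a machine-readable run report |

Statistical notes: the normalization is a deliberately simplified
affine-calibration + glog transform (same model class as vsn-style
variance stabilization, with a transparent trimmed-regression estimator),
and the two-component fit is one faithful instantiation of the
empirical-null approach (truncated half-normal MLE for σ₀ at the 0.75
quantile of |z|, Grenander mixture density, BH-monotonized tail-area
q-values). All synthetic noise magnitudes are defaults chosen for
testability, not estimates from any real data set.

## CLI

```sh
spatialprot simulate --seed 4 --out-dir sim/
spatialprot preprocess --psm sim/psm.tsv --design sim/design.tsv \
    --min-intensity 1000 --min-peptides 2 --out matrix.tsv
spatialprot diffexp --matrix matrix.tsv --design sim/design.tsv \
    --contrast tumor:peritumor --q 0.2 --out calls.tsv
spatialprot cluster --matrix matrix.tsv --sectors ch00,ch01,ch02 --c-range 1:8
spatialprot enrich --ranking fc.tsv --gmt sets.gmt --p 0.001 --out enrich.tsv
spatialprot shift --fc fc.tsv --annot annot.tsv --compartment mitochondrion
spatialprot mtdna --ct ct.tsv --targets MT-RNR1,MT-TL1 --reference B2M --pairs pairs.tsv
spatialprot run --config run.yaml --out-dir out/
```

`spatialprot --version` prints the parameter defaults. All file formats are
UTF-8 tab-delimited text with `#` comments and `NA` for missing values; gene
sets use the standard GMT dialect.

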