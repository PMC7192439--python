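# ribotempo

Sliding-window codon-usage tempo models and their association with
ribosome-footprint (RFP) occupancy, exercised end to end on synthetic data
with known ground truth.

The package implements:

* **Codon-usage measures** (`ribotempo.orfeome_io`) — genome-wide
  within-family frequencies, high-expression ("High-Phi") frequencies from
  ROC-SEMPPR ΔM/Δη parameters at φ = 5.623, CAI-style relative adaptiveness
  weights, and tAI-style weights, plus CDS FASTA reading and
  name-and-length gene matching.
* **Five tempo models** (`ribotempo.cub_models`) — ORFeome %MinMax,
  High-Phi %MinMax, traditional CAI, High-Phi CAI, and tAI, all as sliding
  windows (default (-5, +4)) producing per-codon scores where lower means
  slower, plus pooled bottom-decile slow calling.
* **RFP track processing** (`ribotempo.rfp_processing`) — 20-codon end
  trimming, the strict >200-net-count / >100-nonzero filters, per-gene mean
  normalization, bedGraph→per-codon mapping against a stranded CDS
  annotation, FPKM-proportional multimap assignment, and density ranking.
* **Window determination** (`ribotempo.window_classifier`) — fast/slow
  labeling under median / mean / 90th-percentile cutoffs, windowed
  codon-count features, and a class-balanced logistic classifier scored by
  stratified 5-fold cross-validation over window sizes 1–21 plus (-5, +3).
* **Association statistics** (`ribotempo.association`) — per-gene
  one-tailed Wilcoxon rank-sum tests (slow bin greater, ≥30 observations
  per bin), Fisher's combined probability test, the All / Dense-500 /
  Intersect gene partitions, and a 100-iteration count-shuffling null.
* **A-site enrichment** (`ribotempo.enrichment`) — top-10% occupancy
  splits, per-codon Fisher's exact tests at 0.05/61, cross-dataset
  consensus lists, and deviation scores (frequency − 1/n_syn) per usage
  measure.
* **Reproducibility** (`ribotempo.reproducibility`) — per-gene Pearson
  correlations between datasets, pairwise mean-correlation matrices, and
  rank-sum comparisons between experiment-condition groups.
* **Synthetic data** (`ribotempo.synthetic_data`) — ORFeome generation with
  tunable codon skew, negative-binomial count tracks with planted slow
  codons, log-normal positional fields, and a simulation-calibrated
  between-replicate correlation.

## CLI

All stages are exposed under a single `ribotempo` entry point:

```bash
# synthetic dataset with planted ground truth
ribotempo simulate --n-genes 200 --replicates 14 --rho 0.16 \
    --beta 1.0 --slow-codons GGA,CCG --seed 1 --out sim/

# codon-usage tables from an ORFeome (+ High-Phi with --roc-semppr TSV)
ribotempo tables --orfeome sim/orfeome.fasta --out tables/

# per-codon model scores with bottom-decile slow calls
ribotempo score --orfeome sim/orfeome.fasta --model minmax \
    --table tables/orfeome_freq.tsv --window -5:4 --out scores.tsv

# trim/filter/normalize count tracks (TSV or bedGraph + BED6)
ribotempo tracks --counts sim/tracks_rep00.tsv --out kept.tsv

# window-size sweep of the fast/slow classifier
ribotempo windows --orfeome sim/orfeome.fasta --counts sim/tracks_rep00.tsv \
    --cutoffs median,mean,p90 --sizes 1:21 --seed 0 --out windows.tsv

# Wilcoxon + Fisher association over all partitions, with shuffle null
ribotempo associate --orfeome sim/orfeome.fasta --counts sim/tracks_rep00.tsv \
    --tables-dir tables/ --out association.tsv

# consensus over/under-enriched A-site codons across datasets
ribotempo enrich --orfeome sim/orfeome.fasta --counts-dir reps/ --out enrich.json

# pairwise cross-dataset correlations (optionally with a CHX label TSV)
ribotempo reproduce --counts-dir reps/ --out pairs.tsv
```

## Data formats

Plain text throughout: FASTA ORFeomes; `gene_id<TAB>pos<TAB>count` track
TSVs; `codon<TAB>value` parameter TSVs; bedGraph (0-based half-open) with
BED6 CDS annotations; JSON ground-truth sidecars for simulations.
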