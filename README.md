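# splicefold

Sequence and RNA-structure analysis of **SF3B1-mutation-sensitive cryptic 3'
splice sites**, with a synthetic-data generator so the whole pipeline runs and
is tested end to end without any sequencing download.

## The problem

The spliceosome factor SF3B1 helps select 3' splice sites; the recurrent
K700E mutation (common in myelodysplastic syndrome) shifts selection toward
*cryptic* acceptors — non-canonical AG dinucleotides near the annotated one.
Only a subset of junctions is consistently mis-spliced across mutant samples.
This package implements the analysis that characterizes what distinguishes
those **sensitive (MT)** junctions from cryptic acceptors that are used but
**resistant (WT)** to the mutation:

1. **Classification** — sensitive sites are alternative-acceptor events with
   FDR < 0.1 and |ΔPSI| > 0.05 shared by ≥ 2 mutant datasets; resistant sites
   are novel-acceptor junctions from wild-type samples passing the junction
   filters (anchor ≥ 8 nt, intron length in [50, 500000]) with no detected
   change anywhere. A permutation test measures how unlikely the observed
   cross-dataset sharing is for random junction sets.
2. **Sequence features** — GC content in the 150 nt upstream, intron length,
   cryptic-to-canonical distance, per-position nucleotide probabilities, and
   3'SS strength as the log-odds of the 23-mer window (last 20 intronic +
   first 3 exonic bases) under a first-order splice-site model vs background.
3. **SHAPE-MaP reactivity** — per-nucleotide reactivity as the
   modified-minus-untreated mutation-rate difference with Poisson errors,
   box-plot normalization clamped to [0, 4], correlation-gated replicate
   merging, and the NAG-motif statistics: reactivity of N/A/G (positions
   −3/−2/−1), the ±150 nt median reference, and the A−N magnitude.
4. **Structure** — a self-contained SHAPE-directed folding engine (reduced
   nearest-neighbor energy model; Deigan pseudo-energies
   ΔG(i) = m·ln(r_i+1) + b): Zuker-style MFE with deterministic traceback,
   McCaskill pair probabilities under pairing-distance constraints
   (accessibility averaged over max distances 27–34), paired-base counts over
   −120…+15, ensemble diversity ED = Σ p_ij(1−p_ij), and a ScanFold-style
   windowed thermodynamic z-score (window 200, step 20, dinucleotide-shuffled
   nulls).
5. **Group comparisons** — per-base class aggregates, subsampling bootstrap
   (the larger pool sampled down to the smaller group's size, 1000×), and
   Wilcoxon rank tests with Benjamini–Hochberg adjustment.

The folding engine is validated *exactly* against exhaustive enumeration of
all nested structures on short sequences — MFE to 1e-9 and every pair
probability to 1e-6.

## Worked example

```python
from splicefold.pipeline import run_pipeline
summary = run_pipeline(outdir="out", seed=11)
```

generates a synthetic cohort (30 MT + 30 WT + 15 control junctions, three
mutant datasets, probing depth 10000), classifies it, and runs every
comparison. With seed 11 the summary reports:

```
classification: precision 1.0, recall 1.0, overlap p = 0.000999
GC(150 nt upstream of cryptic site): MT 0.378 vs WT 0.508   (bootstrap p = 0.000999)
NAG magnitude (r_A - r_N):           MT -0.016 vs WT 1.012  (Wilcoxon p = 6.7e-11)
paired bases over -120..+15:         MT 26.0  vs WT 49.3    (Wilcoxon p = 2.7e-11)
ensemble diversity over -120..+15:   MT  8.29 vs WT  2.22   (Wilcoxon p = 4.0e-8)
```

Read: the planted sensitive set is recovered perfectly; MT junctions sit in
low-GC extended pyrimidine tracts, show little reactivity differentiation
between the NAG's A and N, pair less and populate more alternative structures
— the direction of every contrast the analysis is designed to detect.
`out/` contains the FASTA, event tables, reactivity tables, dot-bracket
structures, per-figure TSVs (`fig1d.tsv`, `fig3h.tsv`, `fig5d.tsv`, …) and
`summary.json`.

The same stages are exposed on the command line:

```bash
splicefold synth --outdir data --seed 7
splicefold classify --events data/events_ds0.tsv --events data/events_ds1.tsv \
    --events data/events_ds2.tsv --junctions data/junctions.tsv \
    --annotation data/annotation.gff3 --out classified.tsv
splicefold pipeline --outdir out --seed 11
```

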