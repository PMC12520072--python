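# Methods

This note documents the models, defaults and design choices behind
`splicefold`, and what the synthetic benchmark does and does not show.

## Coordinates

Splice-site positions are counted with no position 0: −1 is the acceptor G,
−2 the A, −3 the N of the NAG motif, +1 the first exonic base. "Upstream"
always means 5' on the sense strand; minus-strand loci are expected to be
supplied as sense-strand windows.

## Classification

Sensitive (MT) cryptic acceptors: events with `fdr < 0.1` and `|dpsi| > 0.05`
(two-sided — gained and lost usage both count) shared by ≥ 2 datasets, keyed
by (chrom, strand, cryptic-acceptor coordinate). Resistant (WT) acceptors:
novel-acceptor junctions sharing an annotated donor, with anchor ≥ 8 nt,
intron length in [50, 500000], read support ≥ 1, and absent from *every*
per-dataset significant list (not just the shared set) — "resistant" means no
detected change anywhere. The overlap test draws, per dataset, a random key
set of matched size from a user-supplied universe and counts keys shared by
≥ 2 sets; empirical p uses add-one smoothing, so the smallest attainable p
with 1000 resamples is 1/1001.

## Sequence features

GC content is (G+C)/(unambiguous bases) over positions −150…−1 (window
configurable). 3'SS strength is scored on the 23-mer covering −20…−1 and
+1…+3. The default scorer is a first-order (dinucleotide-dependent) log-odds
model in bits, trained on annotated-acceptor windows against a background
model (uniform, or trained on supplied windows — the pipeline uses
dinucleotide-shuffled copies of the training windows). The score is additive
over positions; ambiguous bases contribute 0. A genuine MaxEntScan-style
scorer can be plugged in wherever a `score_window` method is accepted. Raw
log-odds are reported, not percentiles. Note the model scores fresh draws
from its own training distribution slightly below zero (the O(1/N)
estimation bias of any fitted model); with thousands of training windows the
bias is ~0.01 bits.

## SHAPE reactivity

Raw reactivity: `mod_mut/mod_depth − unt_mut/unt_depth`, standard error
`sqrt(mod_mut/mod_depth² + unt_mut/unt_depth²)` (Poisson counting errors in
quadrature). Positions with either channel below `min_depth` (default 1000)
are masked and stay missing through all statistics; no imputation.

Normalization is the community box-plot rule: exclude values above
Q3 + 1.5·IQR or the top 10%, whichever removes fewer; divide everything by
the mean of the top decile of the remainder; clamp to [0, 4] (negatives to
0). The divisor is recorded. The rule is scale-invariant, and on uniform(0,1)
draws leaves the post-exclusion top-decile mean at 1 by construction.

Replicates merge by depth-weighted averaging of raw rates when all pairwise
Spearman correlations (co-measured positions) reach `min_rho` (default 0.7 —
the acceptance threshold for "high correlation"); otherwise the deepest
replicate is kept with a warning. Merging precedes normalization.

NAG statistics report r_N, r_A, r_G, the median over ±150 nt (the three
motif positions are *included* — 3 of ~300 values, negligible and simpler)
and the magnitude r_A − r_N (a ratio is available as an option; the
difference is the primary definition). Control-NAG normalization locates AG
dinucleotides ≥ 10 nt from any annotated acceptor, averages their
reactivity per motif offset, and divides the splice-site profile
position-wise by that control mean.

## Folding engine

A reduced nearest-neighbor model rather than full Turner tables: the
analyses here are comparative (group contrasts in pairing, stability and
ensemble diversity), so a compact model that can be validated *exactly*
against exhaustive enumeration was preferred over parameter fidelity.

- Pairs: Watson–Crick + GU; N never pairs; minimum hairpin loop 3 nt.
- Stacking energy of adjacent pairs: −(w₁ + w₂) with per-pair-type strengths
  w = {CG 1.7, GC 1.6, GU 0.5, UG 0.6, AU 1.1, UA 1.0} kcal/mol.
- Hairpin: 5.0 + 1.077·ln(size/3); bulge: 3.2 + 1.077·ln(size); interior:
  1.3 + 1.077·ln(size); interior/bulge size capped at 30.
- Multiloop: 3.4 + 0.4·branch + 0.1·unpaired (affine).
- No dangles, coaxial stacks or terminal-pair penalties.
- T = 310.15 K, kT = 0.6156 kcal/mol.
- SHAPE pseudo-energy per *paired nucleotide*: m·ln(r+1) + b with
  m = 1.8, b = −0.6 kcal/mol; masked positions contribute 0. With m = b = 0
  the guided fold equals the unguided fold exactly; uniform reactivity ≥ 2
  makes every pairing cost energy and reduces pairing.

MFE uses the Zuker recursions (O(n³), numba-compiled); traceback is
deterministic (pairing preferred, smallest 5' index first, stacks/interior
before multiloops). Pair probabilities use the McCaskill inside–outside
recursions over the same decomposition, with Vienna-style per-nucleotide
rescaling on windows > 60 nt so the partition function stays inside float64;
the scale cancels identically in p_ij. A `max_dist` constraint zeroes pairs
with span beyond the bound (max_dist < 4 forbids all pairs); accessibility is
the per-base unpaired probability averaged over max distances 27–34.
Correctness is asserted against enumeration of *all* nested structures up to
16 nt (MFE to 1e-9, p_ij to 1e-6), including SHAPE-restrained and
distance-constrained cases.

Scanning analysis: windows of 200 nt at step 20; per window the
SHAPE-guided MFE is compared against `n_shuffles` dinucleotide-shuffled
(Altschul–Erikson Euler-path) versions folded *without* restraints —
shuffling destroys the sequence–reactivity register, and the z-score is
meant to measure sequence-encoded stability. z = (MFE − mean)/sd with sample
sd; sd = 0 flags the window (NaN, excluded from per-base means). Ensemble
diversity is computed per window from the unconstrained partition function.
Per-base values are plain means over covering windows. The end-to-end demo
pipeline reports ED and paired-base counts over −120…+15 (the metrics that
carry the flexibility contrast) and leaves the windowed scan to the
`structure` subcommand, keeping the default run to ~half a minute.

The hairpin-content metric counts bases within −120…+15 whose partner may
lie anywhere, divided by two, so a pair straddling the region boundary
contributes 0.5. The analysis region's intron bound is a parameter
(default −120; the equivalent description "−121…+15" appears in the
literature — the one-base discrepancy is absorbed by the parameter).

## Group comparisons

The bootstrap comparison subsamples the larger pool to the smaller group's
size, 1000 times by default, *without* replacement (subsampling — the use
case is a small sensitive set against a much larger resistant pool);
with-replacement is an option. Two-sided empirical p with add-one smoothing.
Note the calibration caveat: when the pool is not much larger than the
subsample, the subsampling null is narrower than the sampling distribution
of an independent group by the finite-pool factor (1 − n/N); calibration
checks therefore use N ≫ n. Wilcoxon tests use the exact null up to n = 25
without ties, else the normal approximation with continuity correction;
families of pairwise tests are BH-adjusted (the adjustment choice is
reported in every ComparisonReport).

## Synthetic data generator

The generator emulates the study conditions so every stage is testable:

- **Regions**: 450 nt on each side of the canonical acceptor (900 nt), AG
  dinucleotides planted at the canonical site and (for MT/WT) at a cryptic
  site 25–60 nt upstream; a canonical polypyrimidine tract at −20…−4.
- **MT junctions**: an extended, purine-poor pyrimidine tract
  (A/C/G/U = 0.15/0.25/0.10/0.50) across −130…+20 of the cryptic site — this
  simultaneously plants the low-GC signature and leaves the region
  structurally flexible.
- **WT junctions**: pyrimidine tract upstream only (downstream unbiased),
  plus a structured scaffold — a 14-bp stem whose 5' arm ends exactly at the
  N of the cryptic NAG with the A and G in an A-rich loop (nestedness then
  guarantees they are unpaired in any structure containing the stem), and
  two further 14-bp hairpins upstream. This is the sequence-level
  realization of "resistant junctions are built over stable structure";
  planting can be disabled (`plant_wt_structure=False`), which the
  composition tests use.
- **Counts**: junction-spanning inclusion/skipping counts are beta-binomial
  (concentration 10000 — mild overdispersion; chosen so that at depth 10000
  a null event's |ΔPSI| stays below 0.02 in ≥ 95% of draws) around true PSI
  0.05 → 0.35 for sensitive and 0.30 (both conditions) for resistant
  junctions; p-values from a two-proportion z-test on pooled counts, FDR by
  BH within dataset. The interface (p, FDR, dPSI) is what downstream stages
  consume; the test statistic itself stands in for rMATS's likelihood model.
- **Probing**: the ±150 nt window around the focal acceptor is folded
  without restraints to define the true structure; latent reactivities are
  gamma(1, 0.05) for paired and gamma(2, 0.25) for unpaired bases (means
  0.05 / 0.5); modified-channel mutation probability is
  0.002 + 0.03·latent (clipped at 1), untreated 0.002, binomial at depth
  10000 per channel, two technical replicates.
- One global seed, per-stage substreams; identical config + seed is
  byte-identical.

**What passing does and does not show.** The generator plants clean,
well-separated effects: one cryptic site per junction, independent events,
no alignment artifacts, no PCR duplicates, no read-level noise, reactivity
noise that is purely binomial, and a literal two-state (paired/unpaired)
reactivity model. Recovery of the planted contrasts demonstrates that the
statistics measure what they claim and that effect directions propagate
through the pipeline — it does not certify power or calibration on real
sequencing data, where dispersion, mappability and structural heterogeneity
are all harsher.

## Numerical and degenerate-input choices

- Sequences shorter than 5 nt fold to the open chain at 0 kcal/mol.
- All-masked reactivity input raises; < 20 unmasked positions cannot be
  normalized; a non-positive normalizer raises.
- Events with missing FDR/dPSI are dropped with a warning; zero-count events
  carry NaN PSI and are excluded downstream.
- Homopolymer scan windows have sd = 0 across shuffles: z is flagged
  undefined and excluded from per-base means; ED is 0.
- Empirical p-values use add-one smoothing throughout.
- The overlap statistic is a discrete count, so its add-one p-values are
  conservative by construction (the atom mass scales as ~0.4/sd of the
  count and the sd grows only with the square root of the universe size).
  Calibration is therefore asserted on the randomized probability integral
  transform computed from the returned (observed, null distribution) pair,
  which is exactly uniform when the resampling null is exchangeable with
  the observation; the reported p-value keeps the conservative add-one
  form.

## Known limitations

- The energy model is reduced; absolute energies and structures differ from
  Turner-parameter engines. Group contrasts, not energies, are the output.
- The default 3'SS scorer is a first-order model, not MaxEntScan's maximum
  entropy distribution; scores are comparable within a run only.
- The pair-probability outside recursion is O(n²) per pair in the multiloop
  term; windows much beyond ~300 nt get slow. Scan windows (200 nt) and the
  −120…+15 analysis region are well inside the comfortable range.
- In vivo/in vitro comparisons of real probing data are out of scope; the
  package starts from per-nucleotide mutation counts.
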