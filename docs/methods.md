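# Methods

This note documents the models, parameter choices and numerical decisions
behind `ooribo`, and what the synthetic data do and do not establish.

## Synthetic experiment generator

The generator (`ooribo.simulate`) emulates a spike-in ribosome-profiling /
mRNA-seq study of stored *Drosophila* oocytes. Its defaults are the study
conditions the package is built around, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `timepoints` | d2, d8, d12 | oocyte storage ages (days at 25 °C); d2 is the reference |
| `bulk_factors` | 1.0, 0.595, 0.427 | true relative bulk translation per timepoint (footprint assay only) |
| `n_replicates` | 3 | independent libraries per (timepoint, assay) |
| `spike_fraction` | 0.02 | expected spike read fraction at the reference — the 1.6 µg / 80 µg RNA mass ratio |
| `read_length` | 30 nt | ribosome-footprint length; mRNA fragments use the same length (one assignment code path) |
| `reads_per_sample` | 2×10⁵ | library depth; chosen so the spike total (~4×10³ reads) estimates ratios to ~1.6% |
| `n_genes`, `length_range` | 300, 150–450 nt | transcriptome size; large enough for stable TPM composition, small enough to run in seconds |
| `divergence` | 0.12 | per-site substitution probability between orthologs |
| `abundance_shape` | 1.0 | σ of the log-normal per-gene abundance distribution (long-tailed, like real expression) |

**Ortholog model.** The spike transcriptome is the focal one with i.i.d.
per-site substitutions to a uniformly chosen different base — no indels, so
orthologs stay length-matched and positionally aligned and window
distinguishability has the closed form 1 − (1−p)^k. Real *Dmel*/*Dpse*
divergence is not i.i.d. (codon structure, indels, conservation gradients);
the simulation establishes correctness of the counting and normalization
machinery, not the empirical distinguishability of any real gene set.

**Read model.** A read picks its species with odds (bulk_factor × focal
mass) : (spike mass), the spike mass fixed so the spike probability equals
`spike_fraction` at bulk factor 1 — i.e. the spike-in is pipetted at
constant mass while focal translational output changes. Within a species,
genes are drawn proportionally to abundance (× per-gene relative
translation for the footprint assay), starts uniformly. Reads are
error-free sense-strand substrings: no sequencing error, adapters, UMIs,
rRNA or fragment-length variation. Consequently assignment can be exact
(below) and "unmapped" essentially never occurs; real libraries would add a
mismatch-tolerant mapping layer in front of the counting, which is out of
scope here.

**mRNA assay.** Bulk factors apply to footprints only; the mRNA assay is
generated at bulk factor 1.0 at every timepoint, encoding the studied
regime where stored-oocyte mRNA levels and composition hold steady while
translation declines.

**Uniform TE decline.** A uniform k-fold drop in per-gene translational
output is statistically identical, at the read level, to bulk factor 1/k
with unchanged mRNA: a constant multiplier cancels from the within-species
gene-choice probabilities and moves only the focal:spike mass ratio. The
TE-decline recovery therefore plants its 2.3-fold truth through the bulk
factor; heterogeneous (per-gene) declines can be planted through
`te_profile` instead.

**Determinism.** Every ReadSet gets its own stream seeded by (seed,
sample id) via crc32 tokens, so any sample regenerates independently and
identical configs give byte-identical outputs end to end.

**Hatch data.** Binomial draws around the logistic decay below, with the
number of scored eggs per day as the trial count.

## Exact assignment and the unique-mapping filter

`ooribo.assign` indexes every k-mer (k = read length) of every transcript
of both species and resolves each read by exact lookup: exactly one
occurrence → unique (species, gene); several → multimapped; none →
unmapped. With error-free full-length reads this reproduces an aligner's
NH:i:1 unique-mapping filter bit-exactly while admitting no
mis-assignment — a unique-status read's label is always its true source, so
the filter's only cost is discarded (indistinguishable) reads. A
brute-force all-vs-all substring scan ships alongside as the oracle the
index is tested against.

Uniqueness granularity: occurrences are collapsed to distinct
(species, gene) pairs by default — a read hitting one gene at two positions
is still unique, matching transcript-level unique-mapping semantics;
position-level strictness is a flag (`collapse_positions=False`), as is
reverse-complement lookup (off by default; simulated reads are
sense-strand). Coordinates are 0-based half-open everywhere.

Window distinguishability counts, per gene, the length-k windows covering
at least one substituted position (difference-array sweep, O(L + subs));
transcripts shorter than the window contribute zero windows and are
flagged rather than dropped.

## Normalization and TE

TPM is computed per sample over focal coding sequences:
tpm_g = 10⁶ (c_g/L_g) / Σ_j (c_j/L_j). Scale factors divide each sample's
focal:spike unique-read ratio by the **arithmetic mean** ratio of the
reference-timepoint replicates (how replicate pooling enters was an open
choice; the mean keeps the reference condition's factor exactly 1.0).
Factors are applied to footprint TPMs only; mRNA TPMs stay unadjusted for
TE, and the mRNA-stability check runs on the mRNA assay's raw focal:spike
ratios with pairwise Student t-tests across replicates.

TE per condition is (mean adjusted footprint TPM + c)/(mean mRNA TPM + c)
with pseudocount c = 1 TPM (the analysis this follows states none; 1 TPM
stabilizes low-expression genes without moving well-expressed ones).
Genes below an mRNA floor of 1 TPM in any condition are excluded from TE
summaries; both constants are configurable.

## Differential statistics

Two-sample Student t-test (equal variance by default, Welch by flag) on
log2(replicate value + pseudocount); log2 fold changes from pseudocounted
group means; BH q-values always computed. Genes with zero variance in both
groups get p = 1 at equal means and p = 0 otherwise. Pilot-light
classification uses the raw p < 0.01 threshold with the oocyte > embryo
direction filter, on spike-adjusted expression over the expressed universe
(mRNA ≥ floor); q-values are reported but deliberately do not gate the
call, since the classification this mirrors is thresholded on raw p.
Category summaries report per-gene and median log2 changes for translation
and mRNA separately; genes missing from the tables are listed, never
silently dropped. Curated functional categories require external
annotation, so only user-supplied or synthetic category maps are used.

## Viability decay

Three-parameter logistic h(t) = h0/(1 + exp(slope·(t − t50))): upper
plateau estimated (fresh hatch rates are 90–96%, not 100%), lower plateau
fixed at 0. The published description of the decay is only "sigmoidal";
the logistic form is this package's choice, and fitted t50 values should be
read as model-dependent summaries. Fitting uses scipy's bounded
trust-region least squares with σ_i = √(p̃(1−p̃)/n_i) from a shrunk
proportion p̃ = (x+0.5)/(n+1) (finite weight at 0/100% hatch days), bounds
h0 ∈ (0,1], slope > 0, t50 > 0, and deterministic initialization
(h0 = max observed hatch; t50 = day nearest half of it; slope = 0.5/day).
Flat series return an unconverged fit with NaN t50 rather than a fabricated
half-life; prediction from an unconverged fit raises.

## Problem sizes

Recovery checks run at the design scale above (18 samples × 2×10⁵ reads);
the distinguishability check uses 250 ortholog pairs of 500 nt; the null
calibration pools 25 simulated 2000-gene null experiments; the pilot-light
recovery plants 243 preferential genes among 4050 expressed; decay fits
score 200 eggs/day over twice the half-life. These sizes give standard
errors comfortably inside the stated tolerances (e.g. ±0.05 on scale
factors vs ~0.01 sampling noise) while keeping any full run to about a
minute.

## Known limitations

- No sequencing-error or alignment layer: conclusions about the unique-
  mapping filter transfer to real data only insofar as mismatch-tolerant
  alignment approximates exact matching on diverged species.
- The i.i.d. substitution model overstates how evenly polymorphisms spread
  across real orthologs; real distinguishable fractions vary by gene.
- The t-test on three replicates has the usual small-n fragility; no
  variance moderation (empirical Bayes) is applied, matching the analysis
  this package re-implements rather than improving on it.
- The logistic decay is one of several sigmoids consistent with the data
  shape; t50 is robust to this choice, slope less so.
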