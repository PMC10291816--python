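# Methods

## Scope and data flow

`otsp` covers the computational stages of a spike-in calibrated multiplex
TCRβ sequencing protocol: merged reads → (demux) → per-template spike-in
(ST) counts + clonotype read stream; ST count matrices → (nb) negative
binomial fits → (scaling) per-primer-pair factors → (normalize) corrected
clonotype counts → (metrics) repertoire summaries; plus (interaction) V×J
dependence diagnostics and (simulate) a generator for every input. Read
merging, quality control and clonotype calling are upstream concerns:
clonotype tables are consumed as TSV (a reader adapter accepts MiXCR-style
exports with `cloneCount`/`allVHitsWithScore`/`allJHitsWithScore`/
`nSeqCDR3`, taking the top hit and stripping scores).

## Demultiplexing

A read is an ST read iff the universal 9-bp barcode occurs anywhere in it
within one Levenshtein edit (substitution, insertion or deletion), searched
in forward and reverse-complement orientation. The matcher returns the
leftmost qualifying window; since edlib reports only optimal-distance hits,
start offsets left of the best hit are rescanned with prefix-anchored
alignment to honor that contract. The template identity is the unique
16-bp barcode within one edit, searched first in a ±4 nt window around the
position implied by the universal hit (the unique barcode sits immediately
downstream of it in the template layout), with a full-read fallback. Zero
hits, or ties at equal distance between different templates, make the read
*ambiguous*: it is dropped from both streams but counted, so
ST + clonotype + ambiguous always equals the input read count. A strictly
closer barcode beats a farther one. `N` bases mismatch everything. The
library invariant — 260 distinct barcodes, every V×J pair exactly once,
pairwise edit distance ≥ 3 — is enforced at load and generation time, and
guarantees that no single window can sit within one edit of two barcodes.

## Count model

Replicate ST counts are modeled as C ~ NB(m, d) with E(C) = m and
var(C) = m + d·m²; d is the reciprocal of the conventional "size", and
d = 0 is the Poisson boundary. The mean MLE is the arithmetic mean,
exactly; the dispersion MLE maximizes the profile log-likelihood in d on
[0, 50] by bounded scalar optimization, with the Poisson boundary checked
explicitly. For integer counts the Gamma-ratio term of the log-pmf is
accumulated as Σ_{j<k} log(1/d + j), which stays accurate for arbitrarily
small d where differencing two `lgamma` values loses precision; the
implementation is cross-checked in the tests against `scipy.stats.nbinom`.
The common dispersion of a batch is the median of per-template dispersion
MLEs; all-zero templates carry no information and are excluded with a
warning. Sample variances use the n−1 denominator. At the default study
conditions (n = 20 samples, d = 0.125) the profile MLE has a small
downward finite-sample bias (the recovered median is ≈ 0.11–0.12); this is
a property of the estimator, not a calibration error, and is visible in
the acceptance output.

## Scaling factors and pooling

Batch-mean factors SF_i = C_i•/C_•• and NB-mean factors m_i/m_• coincide
elementwise when computed from one matrix and average to 1 exactly; the
tests assert both identities. Zero-mean templates keep their zero factor
(preserving the mean-1 identity) but are flagged unusable; normalizing a
nonzero count with an unusable factor raises rather than dividing by zero
or imputing a pseudocount. Batches run at different spike-in
concentrations are pooled by reducing each batch's mean vector to relative
frequencies (removing the overall concentration/depth difference),
averaging with weights proportional to sample counts, and rescaling to the
weighted grand mean. This is the minimal rule that is exactly invariant to
rescaling any batch by a positive constant; richer precision-weighted
estimators would need per-template variances and were deliberately not
layered on. Cross-batch stability is summarized as the Pearson correlation
of natural-log factors (the log base cancels in r).

## Normalization

Clonotype counts are aggregated to primer-pair totals (genes map to primer
indices through a required, user-supplied primer map, which may be
many-to-one since one V primer can amplify several segments; unmapped
records are excluded and reported), totals are divided by the pair's
factor, and each clonotype receives its raw within-pair proportion of the
normalized total. Normalized counts stay real-valued: re-rounding would
break the exact identities (batch-mean self-normalization preserves the
grand ST total exactly; within-pair proportions are bit-for-bit
invariant). Metrics are computed on normalized counts converted to
frequencies — normalization happens first, frequency computation second.

## V×J dependence and the independence null

Counts pooled over samples form a 20×13 table; signed Pearson residuals
(O−E)/√E with E from the margins quantify departure from independence, and
their squared sum is the chi-squared statistic (asserted against scipy's
independent implementation). Cells in zero-margin rows or columns are
undefined and flagged. Display ordering uses average-linkage hierarchical
clustering on Euclidean distances of residual rows/columns; fully
degenerate (equidistant) inputs keep their original order, making the
ordering deterministic. Because the closed-form lower bound for bias
reduction under independence is derived elsewhere and not restated here,
the bound is provided as a Monte-Carlo null: iid NB(m, d) matrices,
self-normalized by their own batch factors, summarized per sample by the
log max/min ratio and the IQR of log counts (both reported, since spread
is quoted both as fold-change and as IQR); zero counts are excluded from
the log statistics, so m should be large enough that they are rare.

## Metrics

Shannon diversity H = −Σ p ln p; clonality 1 − H/ln S; maximum clonal
frequency; hyperexpanded fraction = total frequency of clones with
p > threshold (default 0.01, configurable). Clonality and the
hyperexpanded definition are field-standard stand-ins chosen here and
documented prominently — cross-platform comparisons of such metrics are
meaningful at the level of concordance, not equality. A single-clone
repertoire has clonality 1 by convention (with a warning). All metrics
depend only on relative frequencies and are therefore invariant under
uniform rescaling of counts.

## Simulator

The generator defines the study conditions rather than adapting to them:

* **Bias model** — pair log-efficiency = baseline + V effect + J effect +
  interaction; effects iid normal, main effects mean-centered, interaction
  double-centered so it cannot be absorbed into the main effects. Defaults
  v_sd = j_sd = 0.6, interaction_sd = 0.2, chosen once to produce the
  multi-fold template-to-template spread of equimolar counts that spike-in
  calibration is designed for; they are tunable, not fitted.
* **Counts** — NB(m_vj, d) independent across templates and samples given
  the model; default d = 0.125, 20 samples, expected depth 520,000 reads
  per sample (≈ 2,000 per template), a scale at which the d·m² term
  dominates the variance as in calibrated runs.
* **Repertoires** — log-normal clone abundances (σ default 1), uniform at
  σ = 0, monoclonal and 50:50 two-clone mixtures as special cases; random
  CDR3s screened against the universal barcode (within one edit, either
  orientation), mirroring the design requirement that the barcode be
  absent from the amplified locus.
* **Competition** — expected read depth splits between spike-ins and
  clonotypes proportionally to their input masses; clones drawn at zero
  are dropouts, so raising spike-in mass at fixed gDNA monotonically
  starves clonotype detection.
* **Clone bias** — each clone amplifies with its primer pair's spike-in
  efficiency (the method's working assumption); `bias_mismatch_sd` adds a
  per-clone log-normal perturbation to stress-test that assumption.
* **Reads** — one read per counted molecule: 200-nt ST templates
  (V filler, universal 9-mer at offset 80, unique 16-mer, J filler; fillers
  deterministic from the library content) and flank+CDR3+flank clonotype
  reads, with substitution errors at the configured rate (indels are not
  emitted by default; demux tolerates them by construction). At error rate
  0 the counts round-trip exactly through demux. All randomness flows from
  integer seeds via `SeedSequence` spawning; identical seeds give
  byte-identical FASTQ.

What the simulator does *not* emulate: PCR-cycle chemistry, chimeras,
quality-score structure, indel-dominated error profiles, or clonotype-
caller errors. Passing tests therefore demonstrate the statistical logic
of the calibration — not robustness to every artifact of real libraries.

## Validation study sizes

The acceptance checks run at desk scale, chosen as the package's own
validation design: dispersion recovery averages 20 replicate 260×20
batches; the two-clone mixture study runs 200 replicates, each with an
independent 20-sample ST-only calibration and 3 technical mixture samples
(expected 8,000 clonotype reads each), with the clones placed at the outer
deciles of the pair-efficiency distribution — the regime where bias is
visible, matching the intent of a transgenic-mixture validation. The
dominant clone is defined a priori as the one on the higher-efficiency
pair, so its normalized proportion is an unbiased ~½ rather than a
max-statistic.

## Known limitations

* The demux scan is O(reads × barcodes) per ST read in Python; it is meant
  for method validation and moderate read counts, not production-scale
  FASTQ throughput.
* The dispersion MLE's finite-sample bias (above) is not corrected;
  empirical-Bayes or REML-style shrinkage is out of scope.
* The pooling rule is the minimal concentration-invariant estimator, not a
  variance-optimal one.
* Gene→primer maps must be supplied by the user (the simulator emits a
  consistent one); no organism-specific panel is hard-coded.
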