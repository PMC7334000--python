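# Methods

This note documents the models, defaults and numerical choices behind
`fourcstab`, and what the synthetic-data tests do and do not establish
about real 4C-seq libraries.

## Fragment map

A chromosome is digested in silico by scanning for every (possibly
overlapping) occurrence of the primary motif; cut positions are motif
starts. DpnII actually cuts 5′ of GATC, but since every downstream
quantity is fragment-relative, any single consistent convention is
equivalent; coordinates are 0-based, half-open (BED) throughout. `N`
bases never match a motif. Each fragment side is flagged *blind* when no
secondary-motif occurrence starts between that boundary and the fragment
midpoint; blind-side fragments are retained (coverage is kept complete)
but carry the flag so callers can filter them if desired. The viewpoint
exclusion zone is ±2.5 kb around the viewpoint position (primer-side
self-ligation and undigested products dominate there); any fragment
overlapping the zone by ≥ 1 bp is excluded from counting.

## Counting and candidate filter

Reads are assigned by containment of their 5′ position, ignoring strand:
the fragment is the counting unit, and the simulator emits positions
uniform within the source fragment, so containment is the exact inverse
of the generative model. Dropped reads (exclusion zone, unknown
chromosome) are tallied so input totals are always reconstructible.

The statistical candidate set is fragments whose *condition-mean* count
reaches `min_count` (default 20, inclusive). The mean-across-replicates
rule was chosen over a per-replicate rule; profiles for visualization are
never filtered. Replicate QC reports Pearson and Spearman correlations of
log1p counts over fragments with ≥ `min_count` reads in *both* members of
a pair (per-pair qualification).

## Profiles

RPM uses the library total over counted (non-excluded) fragments, so each
profile sums to 10⁶ exactly. The running mean (default window 5, odd
required) shrinks at chromosome edges rather than padding or truncating,
keeping profiles full-length for bedGraph export; consequently exact mass
conservation holds only when a zero margin of (window − 1) fragments
flanks the data. Replicates are smoothed first, then averaged, matching
the stage order of the published pipeline description.

## Interaction calling

Counts are transformed with log1p — a deliberate simplification of a
fitted variance-stabilizing transform: it needs no estimated dispersion
trend and is adequate for z-scoring. The expected background is an
isotonic (pool-adjacent-violators) regression of log1p(count) on distance
order, constrained non-increasing, fitted separately upstream and
downstream of the viewpoint (≥ 10 candidates per side required). The
residual scale is 1.4826 × median absolute deviation in a sliding window
of 101 fragments (minimum 5 observations per window, global-MAD fallback,
floored at max(0.1 × global scale, 1e−3) to avoid zero division on
near-perfect fits). z = (obs − fit)/scale; p-values are upper-tail normal
(only enrichment is called); q-values are Benjamini–Hochberg over the
candidate set; a fragment is significant iff z ≥ 1.96 **and** q ≤ 0.1.

Known limitation: log1p NB residuals are right-skewed, so far-tail
normal p-values are anti-conservative. On spiked simulations the caller
recovers 8× spikes essentially completely, and on null simulations the
q ≤ 0.1 fraction stays far below 0.1, but once true spikes occupy the top
BH ranks, fragments with z ≈ 3.5 can pass the joint threshold — expect
an occasional false flag per library (a higher observed false-discovery
proportion than the nominal FDR would suggest). Users needing strict FDR
control should raise `z_thresh` or calibrate p-values empirically.

### Domain segmentation

Observations are window means of log1p signal over consecutive blocks of
`hmm_k` = 5 fragments (trailing partial window folded into the last full
one). A 3-state Gaussian HMM is fitted by Baum–Welch (100 iterations,
1e−6 tolerance) and decoded by Viterbi; states are relabeled in
increasing order of emission mean (non < low < high) for identifiability.
Initialization is explicit and deterministic — means at the 10/50/90%
observation quantiles, shared variance at var(obs)/4, sticky transitions
(0.85 diagonal), uniform start — because k-means seeding was observed to
collapse to a degenerate solution with all three states equal on clean
step signals. A flat profile (range < 1e−9) returns a single
non-interacting segment without fitting. Non-convergence returns the best
iterate with a warning.

## Differential analysis

The two-condition test preserves the contract of the NB-framework tools
it stands in for: NB family, per-fragment Wald test, nominal p < 0.05
with **no** multiple-testing correction (deliberately, matching the
cited default; expect ~5% of null fragments to be flagged). Size factors
are median-of-ratios over fragments positive in every library,
geometric-mean centred. Per-fragment dispersion is method-of-moments from
the pooled within-condition variance of normalized counts
(Var(K/s) = μ/s + αμ²); the mean–dispersion trend is a log-linear fit to
*binned means* of those estimates (10 expression-quantile bins, ≥ 10
fragments per bin) — binning before the log is essential, since roughly
half the per-fragment moment estimates are non-positive at 2–3 replicates
and fitting the log of the positive ones alone biases the trend low and
inflates the test. The working dispersion shrinks the (floored at 0)
per-fragment estimate toward the trend with weight
resid_df/(resid_df + 10), so with three replicates per condition the
trend carries ~70% of the weight. The Wald statistic is
log2(μ_B/μ_A) over a delta-method standard error; significance uses
normal quantiles, which on simulated data holds the null significant
fraction near 0.055 for 3 + 3 replicates. Condition means are floored at
0.5 normalized counts to keep fold changes finite; the reference
condition (fold-change denominator) is caller-fixed. Runs of adjacent
significant fragments merge into bp regions; a differential region counts
as overlapping a high-interacting domain when they share ≥ 1 bp.

## Allelic bias

Phasing retains a SNP when the proband is heterozygous and at least one
genotyped parent is homozygous: the allele matching a homozygous parent
is assigned to the chromosome inherited from that parent (directly for
the affected parent, by elimination for the unaffected one), and the
chromosome from the affected, expansion-transmitting parent is the
expanded one. Both-parents-heterozygous, homozygous-proband, and
Mendelian-inconsistent records are discarded (inconsistencies logged).
Informative SNPs lie within 1 Mb of the viewpoint (inclusive) and outside
its exclusion zone.

A *sample* is one (SNP, library) pair — the reading under which the
published per-region totals (41, 43, …) are plausible for a handful of
SNPs times several libraries; the unit is kept explicit in the record
structure so it can be re-aggregated. Samples need ≥ 10 total reads; ties
are excluded from both tallies (and from n) and logged. The two-sided
exact binomial P sums all point probabilities ≤ that of the observed
count (with a 1 + 1e−7 relative guard against float noise, the standard
implementation of the minimum-likelihood rule); at p₀ = 0.5 it reduces to
the symmetric doubled-tail form. n = 0 regions report a missing P.

## Synthetic data

The generator emulates the minimal structure the statistics assume:
i.i.d. uniform ACGT sequence (expected GATC spacing 4⁴ = 256 bp, giving
realistic fragment sizes); expected contact counts ∝ (1 + d)^−α from the
viewpoint (α = 1 by default), scaled to 10⁶ reads per library (a typical
usable single-viewpoint depth) and zeroed inside the exclusion zone;
replicate counts NB with dispersion 0.05 (mild overdispersion, three
replicates per condition); optional spike regions multiply expectations
by a fold factor and populate a truth table; trio genotypes with parental
heterozygosity 0.5 and uniform inheritance, exactly one parental
chromosome labeled expanded; allelic coverage NB around 30× with
expanded reads Binomial(total, bias). All draws come from named,
seed-derived `numpy` Generator substreams (`default_rng([seed,
adler32(stream)])`), so outputs are byte-identical across runs and
platforms and conditions have independent but reproducible noise.

What this does *not* model: PCR duplicates, ligation artifacts,
mappability variation, fragment-length capture biases, TAD-scale
structure beyond optional step spikes, or sequence-level allelic reads.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under its own assumptions, not performance on
real patient libraries.

## Test problem sizes

Statistical tests use a 600 kb chromosome (~2300 fragments, ~2.9 Mreads
per condition), 50 null seeds for caller calibration, 10 seeds for spike
recall, 3 seeds for differential calibration/power, and 10⁴ Monte Carlo
draws per bias level for the binomial power curve (keeping the Monte
Carlo standard error well under the 2-percentage-point oracle
comparison). These sizes make the whole suite run in well under a minute
while leaving every estimate's sampling error small relative to the
asserted tolerances.
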