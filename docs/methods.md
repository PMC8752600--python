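# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic data does and does not emulate, and the places
where the design was genuinely open.

## Synthetic contact maps

The generator builds a per-chromosome expectation matrix and draws each
replicate as an independent Poisson sample of its upper triangle:

    E[c(i,j)] = s · (|i−j| + 1)^(−α) · plaid(i,j) · boundary(i,j) · loop(i,j)

* **Distance decay** `(d+1)^−α` with `α = 1.0` by default — the canonical
  power-law scaling of cis contact frequency; the `+1` keeps the diagonal
  finite.
* **Compartment plaid**: bins alternate A/B in blocks of
  `compartment_block_size` (default 2 Mb at 100 kb resolution); same-label
  pairs are multiplied by `plaid_strength` (default 1.8), cross-label pairs
  divided by it.
* **Boundaries**: each boundary at bp position `b` multiplies every pair
  spanning `b` by its depletion factor in (0, 1]; pairs spanning several
  boundaries accumulate all their factors.
* **Loops**: a loop spec multiplies one pixel by
  `enrichment × condition_factor`, so condition-specific loops are planted
  by giving one condition a factor ≠ 1.
* The scale `s` is set so each replicate's expected cis total equals
  `depth` before loop factors are applied; with tens of loops the excess is
  well inside Poisson noise of the total (asserted in tests at 5 SD).

Poisson replicate noise is a modelling choice, not a claim about the assay:
real proximity-ligation replicates are likely over-dispersed
(library-preparation and biological variability), and real maps carry
fragment-level and mappability biases plus nested domain hierarchies that
this generator does not emulate. Passing the recovery suites therefore
shows the algorithms are correct under their own stated background model,
not that their error rates transfer to arbitrary real libraries.

Peak counts and expression counts are negative binomial (gamma–Poisson,
dispersion 0.05 by default) around condition means implied by the planted
dynamic label (`static`, `enhanced`, `reduced`; fold 4 by default). dSTORM
pairs are binary from the start — the analysis operates on binarized
reconstructions, so no localization-event simulation is attempted — with a
planted shared on-pixel fraction, equal channel densities, and a rigid
integer-pixel shift applied to the second channel and its beads.

Default study conditions (the `analysis/` drivers and the pipeline): an
8 Mb chromosome at 10 kb with ~15 loops of enrichment 6 (anchor
separations 150–600 kb, binding assignments cycling through the four
anchor classes, every sixth loop lost three-fold on knockout with a
planted −1 log2 expression effect), boundaries of depletion 0.3 and 0.5,
three replicates per condition at 3.2 M cis contacts each; a 20 Mb
compartment map at 100 kb with four replicates. The dedicated recovery
suites use larger instances (50 loops of enrichment 5 on 30 Mb for
recall/precision; 33 loops with 8 condition-specific on 20 Mb for
differential detection) so that rates are estimated on meaningful counts.

## Contact-matrix model

One chromosome per matrix; symmetric counts stored as the sparse upper
triangle and mirrored on access. `total_cis` counts every unordered pair
once and includes the diagonal once — a stated convention the tests
assert, since published work rarely defines it. Cis normalization rescales
to a target total; no KR/ICE balancing is performed (the upstream maps
this mirrors were produced by external tooling whose balancing state is
not restated here, a documented gap).

The expected profile is the plain per-offset mean; an optional 3-bin
running mean is off by default so small-matrix oracles stay exact. O/E
divides by the expectation and defines 0/0 as 0.

## Compartments

PC1 of the Pearson correlation matrix of the O/E map, computed on bins
with nonzero O/E variance; a constant correlation matrix (uniform map) is
flagged degenerate and yields all-ambiguous labels. The eigenvector sign
is arbitrary, so it is oriented to correlate positively with a user
activity track (planted truth in tests; any per-bin activity proxy such as
gene density in use), and A = positive. The replicate majority rule is
strict: A requires strictly more than 70% of replicates (3/4 passes, 4/7
does not). Shift percentages are reported over bins unambiguous in both
conditions by default (`denominator="all"` gives the all-bins version);
the printed-denominator convention of the source analyses is not stated,
so both are exposed.

## Insulation and CDBs

IS(i) is the mean count in the square pairing the `w` upstream with the
`w` downstream bins (defaults: window 1 Mb, delta span 200 kb, mean
aggregation, noise threshold 0.1); NI = log2(IS / chromosome mean IS) is
depth-invariant and undefined within `w` of chromosome ends. CDBs sit at
local NI minima (strict on the left, non-strict on the right, so plateau
ties break to the lower bin index); the relative insulation RI is the mean
of the flanking NI maxima within the delta span minus the minimum, and a
CDB is kept when RI exceeds the noise threshold. This RI is a declared
stand-in for the published boundary tool's score (only the tool name and
parameters are public); it is validated on planted truth — localization
within ±1 bin, RI monotone in planted depletion.

Differential CDBs: Welch t on per-replicate RI, BH correction, and an
effect gate at the 80% quantile of |mean difference| over all CDBs
(absolute and pooled; the signed variant is exposed, since the source
wording does not fix the convention). Binding classes follow the
exclusion-radius reading: `MyoD_only_le20kb` means MyoD-bound with no CTCF
peak within 20 kb, so the 40 kb class is the stricter subset.

## Loop calling

For every candidate pixel (anchor separation 2 bins to 2 Mb), four local
backgrounds are computed as the mean O/E over the geometry rescaled by the
expected count at the pixel's own distance: the donut (Chebyshev radius
`i` minus the `p`-box and the center cross), the lower-left quadrant
block, and 3-wide horizontal/vertical stripes. Defaults (p, i) = (2, 5)
at 10 kb and (4, 7) at 5 kb. The Poisson rate is the maximum of the four;
the p-value is the Poisson upper tail (asserted equal to a direct pmf
summation to 1e−12); BH runs within log2-spaced distance bands —
simpler and more conservative than lambda-chunking; a pixel must also be
≥1.5-fold over its strongest background, the enrichment gate this caller
family applies on top of significance. Significant pixels are clustered
with 8-connectivity and reported at the count-weighted centroid (rounded
down). Loops co-detected at 5 and 10 kb deduplicate by 10 kb anchor bins,
keeping the finer record.

**APA.** Windows of (2k+1)² pixels (k = 10 by default) centered on each
loop are summed elementwise and divided by the contributing loop count;
the score is the central pixel over the mean of the lower-left 6×6 corner
block (the common tool convention; the block size scales as 0.6k for other
k). Aggregation uses O/E windows by default: the lower-left corner lies
5–20 bins closer to the diagonal than the center, so raw-count aggregates
understate enrichment under distance decay — with O/E windows the score
for loops planted at enrichment 5 lands in [4, 6] and is exactly 1 for
structureless maps. `scale="raw"` restores raw-count aggregation with
cis-pair rescaling for cross-library comparison. Loop strength is the raw
center count over the raw donut mean at the same geometry (NaN when the
donut is empty).

## Loop dynamics

The domain score D of a loop is Σ counts with both ends inside the span
(left anchor start bin to right anchor end bin, unordered pairs once) over
Σ counts with at least one end inside, cis only — a depth-invariant
measure of internal connectivity in [0, 1]. Differential D uses Welch t +
BH with the 80%-quantile |log2 fold| gate, mirroring the boundary test.

Differential loops are detected replicate-wise: loops called on each
condition's summed map, merged by 10 kb anchors, then per replicate the
loop-pixel count and the donut-background sum are extracted and each loop
is tested with a negative-binomial regression of the pixel count on
condition with log background as offset — the "enrichment of the loop over
its background" formulated literally as an offset model (whether the
source framework used a ratio, interaction or offset is not stated; the
offset form is the cleanest GLM rendering). BH runs separately within the
≤150 kb and >150 kb distance regimes (the boundary value in the lower
regime) per resolution, significance at q < 0.1, and double detections
keep the 5 kb record. The construction is symmetric: swapping condition
labels flips every direction and preserves q-values (asserted).

**Dispersion and small-sample calibration.** With 2–3 replicates,
per-row moment dispersion estimates are far too noisy to support the
asymptotic Wald reference (measured 14% type-I at nominal 1% under the
null with per-gene estimates). Both NB stages therefore share dispersion
across rows — the median of row-wise moment estimates, floored at 1e−8
and capped at 10 — which is the information-sharing idea the standard
RNA-seq frameworks formalize with shrinkage-to-trend; no trend fitting or
per-row shrinkage is attempted (documented limitation: genes whose true
dispersion far exceeds the median are tested anti-conservatively).
Calibration and power are both verified: permutation nulls give pooled
false-discovery proportions ≤ 0.05 at q < 0.01, null simulations of the
differential-loop stage stay ≤ 0.2 at q < 0.1 over 20 rounds, and calls
agree with an independent reference NB-GLM implementation on planted data.

Each gene is assigned to its most dynamic containing loop (maximal
|log2 D fold|); ties break deterministically to the smaller span, then the
lower start, independent of input order.

## Annotation and expression

Peak dynamics: library-size-normalized counts, Welch t on log2(1+count),
enhanced/reduced at BH FDR < 0.05 and fold ≥ 1.5 (a +1 pseudocount
stabilizes folds at silent peaks). Pseudo-peaks represent a condition's
binding repertoire: growth = static ∪ reduced, differentiation = static ∪
enhanced — so every static peak is in both sets (asserted). Loop classes
scale each anchor to its containing 10 kb bin and use ≥1 bp overlap,
0-based half-open; the four classes (MyoD-MyoD without/with CTCF,
MyoD-CTCF, CTCF-CTCF) do not cover all occupancy patterns, so the
remainder is kept and reported as `other` rather than dropped. Gene
association requires the ±3 kb promoter window around the TSS to overlap
an anchor (half-open, so a TSS exactly at the anchor edge counts). E-box
enrichment scans both strands for the CANNTG consensus (its own reverse
complement — strand symmetry is asserted) and computes the cumulative
binomial tail against the background match fraction.

Differential expression applies the stated thresholds — BH FDR < 0.01 and
linear fold > 1.5 in either direction — on top of the shared-dispersion
NB Wald test with median-of-ratios size factors. "Does not affect
expression" is operationalized as the label `unchanged` (not passing both
thresholds). Lineage Z-scores are (target − panel mean)/panel SD (ddof 1),
optionally on log2(FPKM+1) — the transform of the original panel analysis
is not stated, so it is a flag. The one-sided Wilcoxon rank-sum test
enumerates all C(n+m, n) splits of the pooled values when n+m ≤ 12
(tie-safe and exact) and otherwise uses the tie-corrected normal
approximation; when every value is identical the test is uninformative and
returns 0.5 by convention.

## dSTORM colocalization

Channels are aligned by the mean displacement of matched fiducial beads,
rounded to integer pixels (a >2 px bead disagreement attaches a warning;
a gated nearest-neighbour matcher is provided for unpaired lists). The
pair cross-correlation is

    c(r) = Re( IFFT( FFT(Im_A) · conj(FFT(Im_B)) ) / (ρ_A ρ_B N(r)) )

with both channels masked to a shared ROI, zero-padded to twice the linear
size so the correlation is aperiodic, and N(r) the autocorrelation of the
ROI mask — the exact count of overlapping ROI pixels at displacement r
(N(0) = ROI area, asserted). Two identities pin the normalization:
identical channels give c(0) = 1/ρ exactly, and independent channels give
c → 1. The radial profile averages c in 1 px annuli. Colocalization ratios
are shared on-pixels over each channel's on-pixels, as percentages. ROI
size and the binarization threshold are free parameters here, as in the
source protocol.

## Pipeline and determinism

`run_pipeline` executes simulate → compartments → boundaries → loops →
annotation → dynamics → expression → colocalization, writing plain-text
outputs plus `summary.json` with the config hash and seed. All randomness
flows from one master seed through spawned substreams, so a rerun with the
same config reproduces every output bytewise (asserted). Unknown config
keys are rejected. The full default run takes on the order of a minute on
one CPU.

## Known limitations

* Poisson replicate noise and a single noise-free bias field: no
  fragment-length/GC/mappability biases, no overdispersion between Hi-C
  replicates, no nested domain hierarchy.
* One chromosome per matrix; trans contacts and inter-chromosomal loops
  out of scope.
* The boundary score is a stand-in for the published tool's relative
  insulation, validated on planted truth only.
* NB dispersion is shared (median), not trend-shrunk; very high-dispersion
  rows are tested liberally.
* No matrix balancing; all statistics operate on raw or cis-scaled counts.
* Statistical power at 2–3 replicates limits the effect sizes the
  differential stages can certify at FDR 0.01; the test suites document
  the regimes in which the planted effects are recoverable.
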