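# loopforge

A tested, synthetic-data-driven reimplementation of the 3D-genome analysis
stack used to study how a lineage-determining transcription factor (the
myogenic master regulator MyoD, alongside CTCF) organizes chromatin
architecture in muscle cells: A/B compartments, contact-domain boundaries
(CDBs), chromatin loops and their dynamics between wild-type and knockout
conditions, the link from loops to gene expression, and super-resolution
(dSTORM) colocalization of factor pairs.

The real analyses of this kind run on multi-billion-read proximity-ligation
(BL-Hi-C), ChIP-seq and RNA-seq libraries.  `loopforge` reproduces the
*computational machinery* at desk scale: every stage is exercised on a
synthetic-data generator that plants known architecture (compartment
checkerboards, boundaries with controllable depletion, focal loop
enrichments, TF peaks with binding dynamics, loop-linked gene expression,
binary image pairs with known overlap and shift), so every claim the code
makes is checked against recorded ground truth.

## What is implemented

| Stage | Model / statistic |
|---|---|
| `synthetic` | Distance-decay Poisson contact maps `E[c(i,j)] ∝ (|i−j|+1)^−α` with multiplicative plaid, boundary depletion and loop factors; NB peak/expression counts; binary dSTORM pairs |
| `hic` | COO text I/O, cis-pair normalization, distance-expected profile, observed/expected (O/E) transform |
| `compartments` | PC1 of the O/E correlation matrix, sign-oriented by an activity track; strict >70% replicate majority rule; A/B shift percentages; sample PCA |
| `insulation` | Sliding-square insulation (1 Mb window, 200 kb delta span, mean aggregation, 0.1 noise floor), log2-normalized; CDBs at local minima scored by relative insulation (flanking maxima − minimum); Welch-t + BH differential CDBs with the 80%-quantile effect gate; binding classes vs MyoD/CTCF peaks |
| `loops` | Donut-filter caller: Poisson upper tail against the max of four local backgrounds (donut, lower-left, horizontal, vertical) on O/E rescaled to raw, BH within log2 distance bands, 8-connected clustering; multi-resolution merge keeping the 5 kb record; loop strength = center/donut; APA with center over lower-left 6×6 score |
| `annotation` | Peak dynamics (static/enhanced/reduced), pseudo-peaks (GM = static∪reduced, DM = static∪enhanced), four-class loop taxonomy with Both/Xor/Neither, ±3 kb promoter gene association, CANNTG E-box cumulative-binomial enrichment |
| `dynamics` | Domain score D = intra-span contacts / contacts touching the span; differential D (Welch-t + BH + 80%-quantile fold gate); replicate-aware differential loops via NB regression with log donut-background offset, FDR within ≤150 kb / >150 kb regimes; most-dynamic-loop gene assignment |
| `expression` | NB Wald differential expression (median-of-ratios normalization, shared moment dispersion; FDR < 0.01 and fold > 1.5), promoter-occupancy summaries, lineage Z-scores, one-sided Wilcoxon rank-sum with exact enumeration at small n |
| `storm` | Fiducial-bead rigid alignment; pair cross-correlation `c(r) = Re(IFFT(FFT(Im_A)·conj(FFT(Im_B))) / (ρ_A ρ_B N(r)))` with aperiodic padding and radial profile; pixel-by-pixel colocalization ratios |

## Worked example

The numbered drivers under `analysis/` run each stage on the default
synthetic study (8 Mb chromosome at 10 kb with 15 planted loops, two of
them lost three-fold on knockout; 20 Mb compartment map at 100 kb; three
replicates per condition):

```
$ python analysis/04_loops.py 1
called [18, 16] loops per condition, 19 after merging; recall 1.00, precision 0.79 vs planted truth
loop strength (center/donut): median 5.44
APA score [WT]: 6.04 over 13 loops (2 without window support)
APA score [MKO]: 5.99 over 13 loops (2 without window support)

$ python analysis/06_dynamics.py 1
domain scores at 15 loops: median D = 0.340
differential loops: 2 significant of 15 tested; 2/2 planted condition-specific loops recovered

$ python analysis/08_storm.py 1
planted shift (3, -2), estimated (3, -2) (bead spread 0.00 px)
c(0) = 10.00 for the planted-overlap pair (identical channels would give 1/rho = 20.0; uncorrelated channels give 1)
colocalization: 49.5% of channel-A pixels share channel B, 50.0% vice versa (planted overlap 50%)
```

Reading the numbers: the caller recovers every planted loop (the extra
calls are replicate-noise pixels admitted at the nominal 10% FDR); the
median loop strength ≈ 5.4 and APA score ≈ 6 match the planted six-fold
enrichment; both knockout-lost loops are the only significant differential
loops and carry the right direction; and with a planted 50% pixel overlap
the cross-correlation at zero displacement sits halfway between the
uncorrelated baseline (1) and the identical-image value (1/ρ = 20).

The same stages are available as a single deterministic pipeline:

```
loopforge run --seed 1 --out results/pipeline   # or: loopforge simulate / loops / cdb / compartments / storm
```

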