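# Methods

## Pipeline model

`difreg` analyses a two-condition expression matrix (condition A = normal,
condition B = disease) in seven stages: probe collapse → DEG screening →
promoter mapping → differential coexpression → network construction → RIF
scoring → pathway enrichment. Each stage writes a plain-text intermediate
file; the manifest records configuration, input checksums and row counts,
and contains no timestamps, so identical runs are byte-identical.

Expression values are used on the scale supplied — the pipeline neither
applies nor assumes a log transformation. Missing values are rejected at
validation rather than imputed: the correlation and t statistics downstream
require complete vectors, and typical series matrices are complete.

## Differential expression

The DEG screen is the pooled-variance two-sample t statistic with a
two-sided p on n_A + n_B − 2 degrees of freedom and Benjamini–Hochberg
step-up adjustment; genes with q strictly below the threshold (default
0.05) are DEGs. This is a deliberately transparent surrogate for
moderated-variance (empirical-Bayes) pipelines: the downstream stages
consume only the DEG list and the per-condition means, so any external DE
caller can be plugged in through the `deg_list` option. Degenerate genes
(zero pooled variance) are resolved explicitly — equal means give t = 0,
p = 1 (no signal); unequal means give p = 0 and a "degenerate" flag.

With the default design (7 vs 9 samples, shift of two noise standard
deviations) the power of this test is moderate: an independent Monte-Carlo
puts per-gene recall near 70 % under BH at 0.05. Tests and the acceptance
script therefore treat DEG recall as a measured quantity, not as a
near-certain event.

## Promoter mapping

Coordinates are 0-based half-open (BED convention) throughout. The promoter
window runs from `upstream` (default 1000) bases 5′ of the TSS to
`downstream` (default 500) bases 3′ of it, oriented by the gene's strand and
clipped at position 0; `--ignore-strand` applies the +-strand window
everywhere. An overlap of at least one base between a binding site and the
window creates the (TF, gene) relation; containment is not required, and
duplicate relations collapse to one. Interval queries use an interval tree
per chromosome; the tests check the result against an exhaustive
double-loop overlap oracle.

## Differential coexpression

Per-condition Pearson correlations are computed by centring and
unit-normalising each gene's profile within a condition, after which a
block of correlations is a single matrix product. The all-vs-all mode walks
the G × G structure in blocks of `block_size` (default 512) genes per axis,
streaming results, so memory stays bounded for large G. Pairs are stored
once under the canonical key (lexicographically smaller id first). A pair
involving a zero-variance profile has undefined correlation: it is emitted
flagged and never selected. Selection keeps pairs with Diff = |r1 − r2|
strictly greater than the threshold (default 1), matching the
strictly-greater screening rule; ties at the threshold are excluded.

Sign classification is by reversal: positive-to-negative when r1 > 0 and
r2 < 0, the mirror case for negative-to-positive, everything else
(including exact zeros) same-sign. Relabelling the conditions leaves Diff
unchanged and swaps the two reversal classes.

The pipeline default computes correlations only for the TF–target relation
pairs (`pairs: tf-target`): the network keeps only relation pairs anyway,
so gene–gene pairs affect no downstream result, and the default run stays
linear in the relation count. `pairs: all` enables the full screen when the
pair table itself is the object of interest; both modes produce identical
networks (tested).

## Network construction

Edges are the intersection of the selected differential pairs with the
relation set, directed TF → target; a TF–TF pair with relations in both
orientations contributes both edges. "Top" truncation ranks by diff
descending — diff magnitude is the only per-edge score the screen
produces — with (tf_id, target_id) as the deterministic tie-break, and a
fractional cut keeps ceil(fraction · edges). Exports: SIF
(`tf<TAB>regulates<TAB>target`), edge TSV (lossless round-trip), GraphML,
plus a node-role table (TF / target / both).

## Regulatory Impact Factor

    RIF_i = (1 / n_de) · Σ_j [ (e1_j · r1_ij)² − (e2_j · r2_ij)² ]

e1_j / e2_j are the per-condition arithmetic means of DEG j — the scalar
per condition per DEG that the formula requires (the sum runs over DEGs
only, and the cognate impact-factor methodology uses condition-average
expression). Undefined TF–DEG correlations contribute 0 and are tallied per
TF rather than dropped, so n_de is identical across TFs and scores remain
comparable. By default the TFs scored are those present in the constructed
network; ranking is by raw RIF descending with TF id as tie-break
(`--rank-by abs` ranks by magnitude instead). Exact properties verified in
tests: swapping condition labels negates every score; duplicating condition
A as condition B forces all scores to 0; scaling all condition-A DEG values
by c scales the positive part of each term by c².

Small-sample caveat: with n samples per condition, a truly uncorrelated
TF–DEG pair still shows E[r²] ≈ 1/(n − 1). At n = 7 this noise floor
(≈ 0.17) times squared mean expression is large enough that a null TF can
outrank a genuinely rewired one; at n = 20 the floor drops to ≈ 0.05 and
ranking is stable. This is a property of the statistic, not of the
implementation, and drives the choice of scales below.

## Pathway enrichment

The upper-tail hypergeometric probability P(X ≥ k) for an overlap of k
query genes with a K-member pathway inside an N-gene universe, computed
with scipy's stable survival function and verified in tests against exact
integer enumeration (Pascal-triangle binomials, suffix sums) over every
parameter set with N ≤ 60. Query genes outside the universe are dropped
with a recorded count; pathways are intersected with the universe first.
The universe defaults to all genes in the (collapsed) expression matrix and
the query to the genes of the truncated network. BH q-values are computed
over the tested pathways; `significant` flags p < alpha (default 0.05).
The EASE variant (tail at k − 1) is optional and strictly more
conservative.

## Synthetic data generator

The generator emulates the study design the pipeline expects, not real
microarray physics. Defaults: 10 TFs, 300 genes, two groups of 7 and 9
samples, baseline 8.0 with Gaussian noise sd 1.0 (a log2-microarray-like
scale), 170 TF→target relations (the planted rewired pairs plus
15·n_tfs background relations drawn uniformly), 50 DE genes, 20 rewired
pairs. Coordinates live on one artificial chromosome (`chrS`, 20 kb gene
spacing, one 20 bp site per relation placed 200 bp upstream of the target's
TSS) so that promoter mapping at the default window reproduces exactly the
planted relation set — by construction, which is what makes the generator a
usable oracle for the mapping stage.

The planted scenario is loss of activation. One designated impact TF (the
first) carries all rewired pairs; its targets are drawn from the planted DE
set, are driven at r_A = +0.9 by regression on the TF profile
(x = r·z_TF + √(1−r²)·ε, exact in expectation), rewired to r_B = −0.9,
and down-shifted by two noise standard deviations in disease. The downward
direction is what makes the scenario coherent: a regulator whose targets
are both decoupled and diminished in disease has (e1·r1)² > (e2·r2)² and
earns a large positive RIF, whereas up-shifted targets would describe a
regulator *gaining* impact in disease (negative RIF). DE genes not targeted
by the impact TF carry the same shift without planted correlation. All
draws come from NumPy's seeded PCG64 generator; a fixed seed reproduces the
dataset bit-for-bit.

What the generator does not emulate: probe-level effects, normalisation
artefacts, batch structure, heavy-tailed noise, and correlated null genes.
Passing the planted-recovery tests therefore demonstrates correctness of
the statistics and plumbing under the stated model, not robustness to real
microarray artefacts.

## Verification scales

The end-to-end planted-structure checks run at two scales, chosen to match
what each property needs: rewired-relation recovery (true Diff ≈ 1.8
against a sampling sd of ≈ 0.5) is tested at the study-like 7 + 9 design,
where it is already near-certain per pair; the impact-TF rank-1 property is
tested at 20 + 20 samples, where the r² noise floor no longer dominates
(see the RIF caveat above). The null-FDR check uses 200 replicates of 500
null genes at 7 + 9. These sizes keep the full suite and the acceptance
script within a few seconds while leaving the generator's study-condition
defaults untouched.

## Numerical choices

Correlations are clipped to [−1, 1] after the matrix product to absorb
rounding; blockwise and per-pair results agree to ~1e−15. BH adjustment
delegates to statsmodels' `fdr_bh`. Selection thresholds are strict
inequalities (q < FDR, Diff > 1, p < alpha). All output sorts carry
explicit lexicographic tie-breaks so files are deterministic. Floats are
written with `%.10g`, which round-trips the quantities at well above the
precision any downstream decision uses.
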