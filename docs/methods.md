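# Methods

This note records the models, parameter choices and numerical conventions
behind `cernapipe`, and what the synthetic study does and does not show.

## Study design being emulated

Four developmental stages (labelled `120dPG`, `1mo`, `3mo`, `10mo`) with
three biological replicates each — twelve samples per matrix. Three count
matrices (lncRNA, mRNA, miRNA) share the sample axis; a GTF-style
annotation, coding-potential verdicts, miRNA-target prediction tables, qPCR
Ct tables and dual-luciferase readouts complete the inputs.

## Synthetic-data generator

**Counts.** Every count is NB(μ, Var = μ + φμ²), sampled per feature and
sample. Defaults: φ = 0.01 (so the generator's dispersion and the exact
test's fixed dispersion are the same quantity on the same scale); baseline
log-means uniform on [3.5, 6.0] (natural log; means ≈ 33–400, a mid-range
expression band that keeps exact-test enumeration cheap without starving
the correlation statistics of signal); multiplicative replicate-level
log-normal noise with σ = 0.05.

**Planted ceRNA structure.** Each planted lncRNA–mRNA pair shares
`mirnas_per_triplet` miRNAs (default 3; ground truth lists one
(lncRNA, miRNA, mRNA) triplet per shared miRNA). A single shared miRNA
would make the shared-miRNA hypergeometric test structurally powerless —
with k = K = n = 1 the p-value is 1/N, which for realistic filtered
universes is not below 0.05 — so several shared regulators per pair is the
minimal structure a screen of this design can recover. The first pair
carries two extra miRNAs so that a known connectivity hub exists. miRNA
stage means follow a strictly monotone geometric ramp spanning
`fold_span` (default 6×) across the four stages; the lncRNA and mRNA of the
same pair follow the reversed ramp. Monotone ramps are the simplest
trajectories for which the noise-free Spearman correlation is exactly ±1
and the noise-free lncRNA–mRNA Pearson correlation is exactly +1.

**Decoys.** Decoy pairs (default 40) are non-planted lncRNA/mRNA pairs
that *do* share a predicted, threshold-passing miRNA, but whose stage-mean
trajectories are independent random permutations of a milder ramp (3×).
They therefore pass the differential-expression gate and genuinely reach
the correlation filters; flat decoys would be removed before the screen and
test nothing. A further `decoy_fail_fraction` of target records fails
exactly one prediction threshold or appears in only one predictor's output,
exercising the score/energy cuts and the intersection rule.

**Annotation.** One coding gene (3 exons over an 11 kb span) per 100 kb
slot; each novel transcript is anchored to its own slot with geometry that
forces its assigned class: fully inside an intron (intronic), exons
overlapping a coding exon on the opposite strand (antisense), span
overlapping the gene on the same strand (sense-overlapping), divergent TSS
300 bp from the gene's TSS on the opposite strand (bidirectional), or
mid-slot ≥ 34 kb from any gene (intergenic). Class proportions default to
an intergenic-dominated mix (52.4 : 13.4 : 7.2 : 11.6 : 10.22, renormalized
to sum to 1) allocated by largest remainder. All novel transcripts have two
exons and ≥ 200 bp unless contamination is requested.

**Determinism.** Every `simulate_*` call derives a per-entity RNG
sub-stream from (seed, domain, index), so identical configs are
byte-identical and adding features does not reshuffle existing ones.
Ground truth is emitted as separate tables, never embedded in inputs.

**What passing tests do not show.** The generator has no sequence level:
no seed matching, no read simulation, no splice-graph realism, no
GC/length biases, no outlier samples or batch effects, and its planted
trajectories are cleaner than real developmental profiles. Recovery rates
measured here bound what the screen can do under its own model, not on
real tissue.

## Statistical components

**NB exact test.** Counts are divided by median-of-ratios size factors and
rounded to a common scale. With n replicates of NB(μ, φ) per group, the
group sum is NB(nμ, φ/n); conditioning on the two-group total T, the
group-A sum follows the normalized product of the two group-sum pmfs, with
μ estimated as T/(n_A+n_B). The two-sided p sums the probabilities of all
outcomes with mass ≤ the observed outcome's mass (relative tie tolerance
1e-12), floored at the observed mass; all-zero genes return p = 1. One
fixed-dispersion test serves all three matrices — re-implementing two
separate estimation frameworks (a GLM engine for lncRNA/mRNA, a tagwise
empirical-Bayes engine for miRNA) is out of scope, and a fixed φ makes the
test exactly enumerable and oracle-checkable. log₂ fold changes use
normalized group means with pseudocount 1 so zero groups stay finite.

**BH-FDR.** adjusted_i = min over the p-value tail of p_(j)·m/rank(j),
capped at 1; order-equivariant and monotone.

**Hypergeometric survivor function.** P(X ≥ k) computed in log-space
(log-gamma terms + logsumexp) over the support [max(k, n+K−N), min(K, n)];
k = 0 returns exactly 1. Used both by the pair screen and by ORA (ORA goes
through `scipy.stats.hypergeom`, the screen through the log-space path;
the two agree to 1e-10 up to N = 500 by test).

**Screen conventions.** Spearman ρ is Pearson on mid-ranks (average ranks
for ties); constant vectors have undefined ρ and are skipped with a
warning. Correlations are computed on size-factor-normalized counts.
For the pair test, K and n are the *post-Spearman* target-set sizes and
the default universe N is the number of distinct miRNAs with ≥ 1 retained
edge (`filtered`); `all_expressed` and `all_predicted` are exposed because
the field does not agree on the universe. Raw p < 0.05 is the default
(matching common practice in these screens); `pair_fdr` adds BH. By
default only features significant in ≥ 1 comparison enter the screen
(`de_gate`), pairs are lncRNA–mRNA (other combinations behind
`pair_types`), and a pair needs ≥ 1 shared retained miRNA (`all_shared`
requires every predicted shared miRNA to survive the edge filter).

**Classifier.** Precedence containment-first (intronic → antisense →
sense-overlapping → bidirectional → lincRNA) makes the five classes a
partition; antisense uses exon-level overlap (the biologically meaningful
case), sense-overlapping uses span-level overlap. `bidirectional_window`
defaults to 1 kb and `min_overlap` to 1 bp; both configurable since no
standard exists. Classification is against coding *transcripts*, not
merged gene spans. Note that the divergent-orientation test is not
invariant under flipping every strand (a divergent pair becomes
convergent), so only antisense/lincRNA/intronic membership is
flip-stable — the tested invariant.

**Wet-lab statistics.** Technical replicates are averaged at the Ct level
before ΔCt; ΔΔCt subtracts the calibrator group's mean ΔCt, so the
calibrator's geometric mean fold is exactly 1. The luciferase helper names
reporter and normalizer channels explicitly rather than assuming which
luciferase carries the cloned site, because common vector designs place the
reporter on either channel. ANOVA is the classical F test; groups that are
all identical return F = 0, p = 1; perfectly separated groups (zero
within-group variance) return p = 0 by convention.

## Numerical and interface choices

* Internal coordinates are 0-based half-open; GTF is the only 1-based
  surface. Tables are TSV (ids like `MSTRG.5182.1` contain dots); counts
  must be integers, real-valued FPKM is a distinct file type; readers
  reject rather than coerce.
* PCA and sample correlation default to log₂(x+1); raw scale is exposed.
  Size factors exclude features with any zero from the geometric-mean
  reference; a pseudo-reference fallback exists for sparse matrices.
* Connectivity ties are broken lexicographically by id, making rankings
  deterministic.

## Problem sizes

The default study (300/500/150 features × 12 samples, 20 planted pairs,
40 decoys) runs the full screen in a few seconds; the acceptance script
adds a 1000-transcript classifier round trip and a 2000-gene null
calibration of the exact test and completes in under a minute. These sizes
give the planted/decoy rates enough resolution (5-percentage-point
granularity on decoys, 5 on planted pairs) while keeping exact-test
enumeration totals in the low tens of thousands.

## Known limitations

* The exact test diverges from estimation-based DE frameworks when the
  fixed φ is far from the data's true dispersion; it is calibrated here
  because the generator uses the same φ.
* The hypergeometric pair test treats target sets as exchangeable draws —
  miRNA families with correlated target sets violate that.
* Enrichment is plain ORA: no term-graph propagation or pathway topology.
* The generator's decoys are structured-but-independent; adversarial
  decoys (e.g. co-regulated but non-interacting modules) are not modelled.
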