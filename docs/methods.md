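# Methods

`flycerna` implements an age-related competing-endogenous-RNA (ceRNA)
analysis for a two-condition design (day-7 vs day-42 adult *Drosophila*):
negative-binomial differential expression (DE), miRNA binding-site
prediction on sponge transcripts (circRNAs, lncRNAs) and mRNA 3'UTRs,
shared-miRNA triple construction with a sign-consistency filter, GO
enrichment of network targets, and qPCR 2^-ddCt concordance. A synthetic
generator reproduces the study design so the whole chain is testable
without the original sequencing data. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Differential expression

**Model.** Counts for feature *f* in sample *s* are modelled
NB(mu_fs, alpha) with variance mu + alpha·mu² (alpha = 0 recovers
Poisson). Effect sizes are carried as log2(day42/day7) throughout;
published fold changes in the bundled DE-circRNA table are interpreted on
this scale, since values like 0.74476 marked "up" and -0.48662 marked
"down" are inconsistent with linear folds.

**Normalization.** Median-of-ratios size factors against the per-feature
geometric mean; features containing any zero are excluded from the
median. If no feature has all-positive counts the function fails loudly —
no silent pseudo-reference fallback.

**Dispersion.** Per-feature method of moments on normalized counts,
alpha_raw = max(0, (s² − m)/m²) with the variance pooled within
conditions, then shrunk toward a centered running mean of alpha over the
50 features of most similar normalized mean (the trend). The weight on
the per-feature value is df/(df + prior_df) with prior_df = 10, where df
is the pooled residual degrees of freedom. The weighting is deliberate:
with 2 replicates per condition the raw moment estimate has 2 df and is
so noisy that plugging it into the exact test inflates the null rejection
rate well above nominal (underestimated alpha widens the rejection region
asymmetrically); deferring to the trend at low df restores calibration,
verified on null simulations of 2,000 features (empirical type-I error
0.047–0.059 at nominal 0.05). With ~10 residual df the blend approaches
50/50 and the per-feature signal dominates as replication grows.

**Exact test.** The test conditions on the total of the two group sums.
If each group sum is a sum of independent NB(mu, alpha) samples, the
group-A sum given the total is BetaBinomial(total, n_A/alpha, n_B/alpha);
at alpha = 0 this degenerates to Binomial(total, n_A/(n_A+n_B)). The
two-sided p is the total null probability of all partitions whose
probability does not exceed the observed one (ties included, with a 1e-9
relative tolerance for floating-point ties). Replicates are collapsed to
rounded size-factor-normalized group sums before testing; this
quantile-style collapse is an approximation — normalized counts are not
exactly NB — but is exact at equal size factors and accurate for factors
in the simulated [0.7, 1.4] range. Features with zero counts everywhere
are dropped; a zero total yields p = 1 with a warning.

**Screening profiles.** circRNA: raw p < 0.05, no fold-change floor
(matching the published circRNA screen, which lists raw p up to 0.048 as
DE — BH-adjusted p is reported alongside for the stricter option); miRNA:
|fold change| >= 1.5 and raw p < 0.05. The mRNA/lncRNA lists in the study
came from earlier work whose thresholds are not restated; the miRNA
profile is reused for them as the package default.

## Binding-site prediction

**Seed anchors.** The seed is miRNA positions 2–8 (5'->3'). Watson–Crick
pairing of positions 2–7 is required; classes follow the canonical
hierarchy (8mer = positions 2–8 paired plus target A opposite position 1;
7mer-m8; 7mer-A1; 6mer). G:U is not accepted inside the seed. Site
coordinates are the 8-nt target window opposite miRNA positions 1–8,
1-based inclusive on the target's 5'->3' strand — defining coordinates by
the seed window (rather than the variable alignment extent) makes
position comparisons against ground truth exact.

**Alignment.** Each anchor is extended by a local antiparallel hybrid
alignment (Gotoh affine gaps) of the full miRNA against the anchor window
±30 nt: match +5, G:U wobble +2, mismatch −3, gap open −9, gap extend −4;
substitution scores are doubled at seed positions (5' dominance). A
perfectly complementary 22-mer scores 5·22 + 5·7 = 145; a seed-only
pairing of 7 matches scores 70.

**Duplex energy.** Nearest-neighbor free energy of the aligned duplex:
+4.09 kcal/mol initiation, stacking terms for adjacent base pairs from a
bundled Turner-style table (Xia-style Watson–Crick values; approximate
single-wobble values; generic fallbacks of −1.0 for unlisted
single-wobble stacks and +0.5 for tandem wobbles), and a length-linear
penalty of 2.0 + 0.4·n kcal/mol per interior loop/bulge of n unpaired
nucleotides. Terminal AU penalties and dangling ends are omitted. A site
with no helix of >= 2 consecutive pairs has undefined energy and is
rejected. These parameters are a documented, configurable default: the
upstream tool's exact score/energy parameters are not published, so
absolute energies here are comparable within runs, not to the published
−15 to −23 kcal/mol values.

**Thresholds and reporting.** Defaults: score >= 140 and dG <= −10
kcal/mol. Overlapping sites of one (miRNA, target) pair are resolved by
keeping the best-scoring site and greedily adding non-overlapping ones;
equal scores break toward the lower start coordinate. circRNAs are
scanned with the first L−1 nucleotides appended (L = miRNA length) so
back-splice-junction sites are findable; their coordinates are reported
modulo the sequence length (a wrapped site has start > end). DNA input
(T) is converted to U with a logged warning rather than rejected.

## ceRNA triples and the mechanism filter

A candidate triple is a (sponge, miRNA, mRNA) with >= 1 predicted site on
both the sponge and the mRNA for the shared miRNA and all three members
DE. Under the ceRNA model the sponge sequesters the miRNA, so sponge and
mRNA should move together and the miRNA opposite: of the 8 direction
triplets exactly (up, down, up) and (down, up, down) conform. Triples
with any non-significant member are rejected (the study works with hard
DE lists; no down-weighting). The unfiltered triple table is also
emitted, so both the full and the mechanism-conforming networks are
reproducible. No statistical test is applied to shared-site counts — the
upstream analysis applies none either.

## GO enrichment

Upper-tail hypergeometric test per term: p = P(X >= k) for
X ~ Hypergeom(N, K, n) with N the background size (unannotated background
genes count toward N), K the term size, n the query size, k the overlap.
BH correction across all reported terms; terms with zero overlap are not
reported. Terms are tested exactly as mapped — no GO-DAG ancestor
propagation, since the annotation source's propagation behaviour is
unknown. The default background is the annotation universe united with
the query. Reporting follows the top-30-by-lowest-p convention, ties
broken by GO id.

## qPCR quantification and concordance

dCt = Ct_target − Ct_ref per sample (reference rp49), ddCt = dCt −
mean(dCt over day-7 replicates) per gene, RQ = 2^−ddCt (amplification
efficiency fixed at 2.0; no standard-curve correction). RQ is invariant
to per-sample plate shifts by construction. Groups are compared by a
two-sided Welch t-test on ddCt rather than on RQ — ddCt is the
log-scale, approximately normal quantity; the source protocol says only
"independent-samples t-tests", so pooled-variance is a documented
alternative reading. Stars: "**" for p < 0.01, "*" for 0.01 <= p < 0.05.
A gene is concordant "(+)" with the sequencing screen iff the qPCR t-test
is significant at 0.05, the DE call is significant (direction != ns), and
the sign of the mean log2 RQ at day 42 matches the DE direction.

## Synthetic-data generator

**What it emulates.** Two conditions (day 7, day 42); RNA-seq with 2
biological replicates per condition for mRNA/lncRNA/circRNA and miRNA-seq
with 5, matching the study design; NB counts with planted log2 fold
changes; planted sponge/miRNA/mRNA triples with sign-consistent
directions, half (up, down, up) and half (down, up, down) so both
admissible patterns are exercised.

**Sequences.** Background composition is i.i.d. uniform A/C/G/U (chance
seed-hit rates are then analytic: 4^-6 per window for a 6mer core). For
each planted (miRNA, target) pair the generator writes the full-length
reverse complement of the miRNA with the canonical A opposite position 1
into the target at a random non-overlapping position (one site per pair
by default; configurable, e.g. five per pair to mirror multi-site
sponges). The recorded ground-truth coordinates are the site's 8-nt seed
window, an exact 8mer. Full-length complementarity is deliberate: a
seed-only site scores ~70 under the alignment scheme and could never pass
the default score threshold of 140, whereas a full-complement site scores
>= 140 with certainty, making 100% planted-site recall a property of the
generator/scanner pair rather than a tuning accident. Real sites pair
less extensively; consequently passing recall here validates coordinate
bookkeeping and thresholds, not sensitivity to imperfect duplexes.

**Counts.** Defaults: baseline mean 500 (per-feature baselines
log2-uniform in [250, 1000], geometric mean 500, so the dispersion trend
is estimated over a non-degenerate mean range), planted |log2fc| = 2,
dispersion alpha = 0.05, per-sample size factors log-uniform in
[0.7, 1.4] so normalization is non-trivial. Sequencing depth and
dispersion are not stated in the source study; these are choices of
plausible bulk-RNA-seq magnitudes, not estimates from data, and they are
the fixed conditions under which the recovery and calibration properties
are tested.

**Ct tables.** Reference Ct 20, target offset +5, day-42 shift −log2fc,
Gaussian noise (sd 0.2 by default, 3 replicates per condition as in the
validation experiments); at zero noise the closed form RQ = 2^log2fc is
exact.

**Determinism.** All three generators (and the synthetic GO map) draw
from children of a single seed sequence, so identical (config, seed)
reproduces byte-identical outputs; the pipeline manifest plus seed fully
determines every file, which the tests verify by hashing.

## Problem sizes

Default analyses run 60 mRNAs, 15 lncRNAs, 15 circRNAs, 20 miRNAs and 10
planted triples; recovery properties are pooled over 5 seeds (50 planted
triples) and null calibration uses 2,000 features. These sizes give
stable Monte-Carlo estimates (binomial SE < 0.01 on the type-I rate)
while keeping a full pipeline run under a second of compute per seed.

## Known limitations

- The exact test's group collapse (rounded normalized sums) is an
  approximation for unequal size factors.
- Duplex energies are comparable within runs only; no terminal penalties,
  dangling ends, or target-accessibility modelling.
- The generator does not simulate raw reads, back-splice junction
  discovery, adapters, quality scores, GC/length biases, or correlated
  replicates; passing tests demonstrate the pipeline's internal
  correctness under the stated model, not performance on real libraries.
- GO enrichment is flat (no DAG propagation) and the synthetic GO map has
  no term-size bias or hierarchy.
- qPCR modelling assumes perfect efficiency and a single reference gene.
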