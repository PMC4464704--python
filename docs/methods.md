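# Methods

This note documents the models, parameter choices and numerical decisions
behind epimark, and what the synthetic benchmarks do and do not establish.

## Study design being modelled

A wild-type line and a histone-methyltransferase deletion mutant are
profiled by ChIP-seq for a gene-body histone mark, with and without a
transient joint carbon + light treatment, in two biological ChIP replicates
per genotype/condition plus an input (non-immunoprecipitated) library; the
enzyme's own binding is profiled with a tagged line.  The transcriptome is
measured on a full 2×2×2 factorial (genotype × ±carbon × ±light) with three
replicates per cell.  The analysis asks: which genes lose the mark in the
mutant, where within the gene the loss occurs, which genes the enzyme
binds, and how methylation loss couples to expression and to carbon/light
responsiveness.

## Island calling

Fragment libraries are deduplicated to at most `redundancy_threshold`
(default 1) copies per identical (chrom, start, end, strand) — the standard
guard against PCR clones.  Coverage adds one to every base of [start, end);
RPM scaling multiplies by 1e6/library size.

The caller is a window-cluster method for broad marks.  Windows of 200 bp
are scored by fragment *midpoints*: midpoint assignment is unambiguous and
mass-preserving across windows, unlike counting a fragment into every
window it touches.  The background rate is
λ_w = N·w/(φ·G) with effective genome factor φ = 0.9; windows beat the
background at upper-tail Poisson p < 0.05 (`window_p`), and eligible
windows cluster across ineligible gaps up to 200 bp.  Island significance
is an upper-tail Poisson test of the island's ChIP count against
max(input count × library-size ratio, λ_w × window span) — the max guards
against input dropouts producing spuriously small expectations.  BH runs
across all candidate islands; retention needs FDR < 0.01 and ChIP/input RPM
enrichment > 2.  Island bounds are window-aligned by construction.  A
pseudocount of 0.5 enters enrichment and fold-change ratios only, never the
count tests.

With no input library the background expectation λ_w × span serves as the
reference and enrichment is observed/expected.

## Differential islands

Candidate regions are the union of the two samples' islands *segmented at
every island boundary*.  Segmentation, rather than merging, is what makes a
partial loss detectable: when the mutant retains the 5′ ~40% of a gene's
mark, the merged whole-gene ratio is capped near 1/(retained fraction) ≈
1.9 and can never clear a 2-fold cutoff, while the segmented 3′ region
carries the full contrast.  Boundaries are taken from the candidate
(pre-retention) islands of both samples — retention thresholds classify
marked genes; for the partition only the edges matter, and a weakly
supported island in one sample still marks a real edge.

Counts are compared with the exact conditional binomial test: given
n = k_a + k_b, k_a ~ Binom(n, N_a/(N_a+N_b)) under equal per-million
rates.  This is the canonical exact comparison of two Poisson counts and is
symmetric in the two samples, so swapping them flips directions while
preserving p-values exactly.  BH across regions; significance at
FDR < 0.05 and pseudocounted RPM fold change > 2 for the genotype
contrast, or > 1.3 for the milder treatment contrast.  The treatment
contrast runs on the same union-of-islands machinery (the union is built
from the two libraries being compared, not re-called per condition).

Genes receive a status by ≥ 1 bp of overlap (configurable) with significant
regions; a gene overlapped by both directions in one contrast is flagged
`ambiguous` and excluded from downstream sets — the conservative choice.

## Metagene profiles

Per gene: 10 upstream flank bins (500 bp at 50 bp/bin), 40 body bins, 10
downstream flank bins, all oriented 5′→3′ (minus-strand genes are read
reversed).  The body split distributes the L mod 40 remainder bases one per
bin from the 5′ end — deterministic and exactly mass-conserving
(Σ bin mean × bin width = Σ body coverage).  Genes shorter than 40 bp
cannot be split and are skipped and reported.  Flanks are fixed at 500 bp
even when they overlap a neighbouring gene; flank bases beyond a chromosome
end contribute zero.  Aggregation is the per-bin median over the chosen
gene set.

Cross-sample normalization divides each profile by its sample's mean RPM
coverage over its own marked-gene bodies (so each sample's gene-body signal
is ~1 in expectation); a `genome` mode dividing by genome-wide mean
coverage is available.  The phrase this interprets — correcting for the
genotypes' different genome coverage — is ambiguous in the field; the
marked-body convention is the default and the switch records the
alternative.

The 3′ fraction (second half of the body bins over the whole body) is
scale-invariant, hence independent of the normalization choice.  For
detecting the mutant's positional shift it is computed over the *affected*
(hypomethylated) gene set: over an all-marked aggregate the per-bin median
moves only marginally when fewer than half the genes are affected (a
median of a mixture shifts to a quantile of the unaffected component), so
the all-marked aggregate supports the strict inequality (mutant < WT) but
not an effect-size bound.  At 3′ attenuation 0.2 the hypo-set shift is
≈ 0.17–0.19 across seeds.

## Replicate QC and qPCR

Three concordance criteria: (1) each replicate's top 40% of islands (ranked
by ascending FDR, ties by p then coordinate, top ⌈0.4n⌉) shared ≥ 80% with
the other's top set, both directions; (2) Spearman ρ of per-base coverage
over three seeded, non-overlapping 300 kb regions, mean > 0.9; (3) > 80% of
all retained islands shared, both directions.  "Shared" means ≥ 1 bp of
overlap; requiring both directions makes the directionless criterion
well-defined.  The top-40% cut counts islands, not bases.  Results are then
reported only where true in both replicates: the consensus is the
intersection of (gene, status) pairs — commutative and idempotent.

The per-base Spearman threshold is calibrated for real, structured
coverage.  On synthetic libraries the background is exchangeable Poisson
noise with no shared fine structure, so replicate ρ sits well below 0.9
even when Pearson correlation exceeds 0.99; the criterion is implemented as
stated but a pass on flat-background synthetic replicates should not be
expected (see Limitations).

qPCR: percent input = 2^(Ct_input − Ct_ChIP) × input dilution factor,
normalized by the geometric mean of the reference genes' percent inputs
(the standard multi-reference convention; with no references the raw value
is returned).  Fold enrichment over the no-antibody control =
2^(Ct_noAb − Ct_ChIP), passing only when strictly > 3.

## Factorial expression analysis

The low-expression filter removes a gene only when *every* sample sits
below the linear-scale cutoff 40 (boundary inclusive).  The ANOVA is fitted
on log2(x + 1) — the standard variance-stabilizing transform for
MAS5-style intensities; a raw-scale flag exists.  With a balanced 2×2×2
design the ±1 contrasts are orthogonal, so each term's sum of squares is
T²/n for contrast total T, the error is the within-cell residual with
8(r−1) degrees of freedom, and the whole matrix is fitted in one vectorized
pass; agreement with an independent OLS decomposition (statsmodels
`anova_lm`) is at the 1e-10 relative level, and balance makes the
sums-of-squares type moot.  Unbalanced designs are rejected with a message
rather than silently re-weighted.  BH runs per term across genes.  Response
sets: genotype at FDR < 0.05 split by the sign of the mutant−WT contrast;
carbon and light at FDR < 0.05; genotype × light at FDR < 0.15.

## Integration

Hypergeometric overlap p-values are exact upper tails; the background
universe defaults to all annotated genes shared by the compared sets and is
always reported with the p-value, since the p depends on it strongly.
Percentages round half-up (728/2,267 → 32%).  Binned trends rank genes by
one measure into equal-count bins (remainder to the lowest bins) and
summarize the other per bin (median methylation per expression decile; mean
expression change per hypomethylation-magnitude bin), with a Spearman trend
statistic over bin summaries.  Chromosomal clustering slides a 20-gene
window (step 1) per chromosome, scores it by the hypergeometric upper tail
of its member count given the genome-wide set frequency, keeps raw
p < 0.05 as the field's clustering tools do (a BH mode exists but is off by
default), and merges overlapping significant windows into clusters
reporting member genes and the best window p.

## The synthetic generator

The generator emulates the study at desk scale with every label known.
Defaults: 500 genes of 1–3 kb on two 1.15 Mb chromosomes (genic fraction
~43%, close to the organism's gene density); 60% of genes marked (marked
bodies ~26% of the genome); 40% of marked genes hypomethylated and half of
those bound by the enzyme, mirroring the study's set-size ratios; gene-body
enrichment 10× background with a piecewise-linear 5′-weighted shape (1.5 at
the TSS to 0.75 at the TTS, mean-normalized — the real WT shape is not
parameterized anywhere, so any monotone 5′-biased stand-in is equally
defensible); fragment length fixed at 200 bp (a single median length;
length variation is not modelled); libraries of 5e5 fragments with Poisson
size noise.  In the mutant, the enrichment *excess above background* over
the 3′ 60% of hypo-gene bodies is multiplied by `three_prime_attenuation`
(0 = the mark is completely lost there, leaving background — attenuating
total density instead would leave a non-physical coverage hole).  The
binding library puts a flat 10× excess on bound-gene bodies only.

Expression: log2 baseline N(8, 2) (chosen so ~4–5% of genes fall below the
cutoff 40 in all samples, exercising the filter), Gaussian noise
sd 0.25, effects of −2 (genotype, applied to truth-down genes; up genes get
+2), +1 (carbon, light, and the genotype × light interaction, the last
applied only in mutant/+light cells), emitted on the linear scale.
Down-regulation is coupled to hypomethylation: truth-down = truth-hypo,
plus an independent 10% of unmarked genes up-regulated.

Everything is deterministic per seed; fixture files are byte-identical for
a fixed seed.

### What the generator does not emulate

- **Mappability, GC bias, chromatin accessibility**: the background is
  uniform.  Consequently per-base replicate coverage has no shared fine
  structure and the Spearman QC threshold behaves as noted above.
- **Duplication saturation**: at 5e5 fragments over ~0.6 Mb of enriched
  bodies, deduplication removes a substantial fraction of enriched-region
  fragments (unique start positions saturate), compressing observed
  enrichment from 10× to ~7× and flattening the 5′ gradient at small
  genome/library ratios.  This is a realistic phenomenon, but it means
  effect sizes measured on the synthetic data understate the configured
  densities; benchmark scales were chosen where the compression is mild.
- **Treatment-induced methylation gain** is not modelled (no truth label
  exists for it); the mild-treatment fold-change pathway is exercised on
  the genotype fixtures instead.
- **Reads**: fragments are intervals; sequencing errors, trimming and
  mapping are upstream of this pipeline's scope.

Passing recovery benchmarks therefore demonstrates correctness of the
statistics and bookkeeping under the stated generative model — not
robustness to the biases of real libraries.

## Problem sizes used by the test and benchmark suites

Unit tests run a 60-gene, 2 × 150 kb study with 6e4-fragment libraries.
Benchmarks run: island error control on a 10 Mb chromosome with 2e5
fragments over 20 null simulations plus one implant recovery; differential
and expression recovery on the 500-gene default study (libraries 5e5,
attenuation 0, two and ten seeds respectively); the positional shift at
attenuation 0.2 over ten seeds; ANOVA type-I error on 2,000-gene null
matrices over ten seeds; and one end-to-end run applying the
both-replicates consensus rule.  These sizes keep the full suite and the
acceptance script each under a few minutes on one CPU while leaving the
binomial/Poisson error bars far tighter than the asserted bounds.

## Known limitations

- The island caller's uniform-background window test is a simplification;
  local-λ backgrounds (as in peak callers built for punctate marks) are out
  of scope.
- Exon-aware metagene coordinates and TSS-anchored (unscaled) profiles are
  not implemented.
- The hypergeometric background universe is a choice the user must own;
  published overlap p-values are not comparable without knowing it.
- Replicate handling is by consensus of independently analysed replicates,
  not joint modelling.
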