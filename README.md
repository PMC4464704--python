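# epimark

Island-based differential histone-mark ChIP-seq analysis with transcriptome
integration, for studies that ask what happens genome-wide when a histone
methyltransferase is removed.

The motivating setting is a plant mutant carrying a complete deletion of an
H3K36 methyltransferase: gene-body H3K36me3 is lost preferentially towards
the 3′ end of gene models on a specific subset of genes, and that loss is
coupled to reduced expression of carbon- and light-responsive genes.  The
package implements the full analysis chain for this kind of experiment —
island calling, differential methylation, positional metagene profiling,
replicate QC, per-gene factorial ANOVA, and target-set integration — plus a
synthetic-data generator with per-gene ground truth so every stage can be
validated end to end without any external download.

## The statistics at the core

**Island calling.** Each chromosome is tiled into windows of *w* = 200 bp
and ChIP fragment midpoints are counted per window.  Under a uniform
background the window count is Poisson with rate
λ_w = *N·w* / (φ·*G*), where *N* is the library size, *G* the genome length
and φ = 0.9 the effective genome factor.  Windows with upper-tail
P(X ≥ k; λ_w) < 0.05 are clustered across gaps up to 200 bp into islands;
each island's ChIP count is tested against
max(input count × library ratio, λ_w × windows) by an upper-tail Poisson
test, Benjamini–Hochberg corrected, and retained at FDR < 0.01 with
ChIP/input enrichment > 2.

**Differential islands.** Candidate regions are the union of both samples'
islands, segmented at island boundaries so a loss confined to part of a
gene is tested on its own.  Counts are compared with the exact conditional
binomial test — given *n* = k_a + k_b, k_a ~ Binom(*n*, N_a/(N_a+N_b))
under equal per-million rates — BH-corrected, and called at FDR < 0.05 with
fold change > 2 (genotype contrast) or > 1.3 (mild treatment contrast).

**Metagene profiles.** Each gene yields a 60-bin vector (10 × 50 bp
upstream, 40 body bins, 10 × 50 bp downstream), oriented 5′→3′; the
aggregate is the per-bin median over a gene set.  The 3′ fraction
Σ(body bins 21–40)/Σ(body bins 1–40) quantifies positional shifts
(0.5 = flat, smaller = 5′-biased).

**Expression.** After a linear-scale low-expression cutoff of 40, each gene
gets a balanced 2×2×2 fixed-effects ANOVA (genotype G × carbon C × light L,
log2(x+1) scale) decomposed by orthogonal ±1 contrasts into G, C, L, G×C,
G×L, C×L, G×C×L; per-term BH across genes.  Response sets: G at FDR < 0.05
split by sign into down/up in the mutant, C and L at FDR < 0.05, G×L at
FDR < 0.15.

**Integration.** Set overlaps use the exact hypergeometric upper tail
P(X ≥ k) with X ~ Hypergeom(N, n₁, n₂); direct targets = hypomethylated ∩
bound, functional targets = hypomethylated ∩ down-regulated; chromosomal
clustering slides a 20-gene window (hypergeometric p < 0.05, overlapping
windows merged).  ChIP-qPCR: percent input = 2^(Ct_input − Ct_ChIP) ×
dilution, normalized to reference genes; fold enrichment over the
no-antibody control = 2^(Ct_noAb − Ct_ChIP), required > 3.

## Worked example

```python
import epimark as em
from epimark import anova as an, metagene as mg

cfg = em.SyntheticConfig(seed=1, three_prime_attenuation=0.2)
annotation, truth = em.build_annotation(cfg)
dd = em.deduplicate_fragments
chip_wt  = dd(em.simulate_chip_fragments(annotation, truth, "WT",  "chip_mark", cfg, 11))
chip_mut = dd(em.simulate_chip_fragments(annotation, truth, "mut", "chip_mark", cfg, 12))
input_wt  = dd(em.simulate_chip_fragments(annotation, truth, "WT",  "input", cfg, 13))
input_mut = dd(em.simulate_chip_fragments(annotation, truth, "mut", "input", cfg, 14))

islands_wt = em.call_islands(chip_wt, input_wt, annotation.chrom_lengths)
diff = em.call_differential_islands(chip_wt, chip_mut, annotation.chrom_lengths,
                                    input_a=input_wt, input_b=input_mut)
gm = em.annotate_islands_to_genes(diff, annotation)
hypo = set(gm.index[gm["status"] == "hypomethylated"])

cov_wt  = em.compute_coverage(chip_wt,  annotation.chrom_lengths, rpm=True)
cov_mut = em.compute_coverage(chip_mut, annotation.chrom_lengths, rpm=True)
pw, _ = mg.profile_gene_set(annotation, cov_wt,  hypo)
pm, _ = mg.profile_gene_set(annotation, cov_mut, hypo)

matrix, design = em.simulate_expression(truth, cfg, 15)
filtered, removed = an.filter_low_expression(matrix)
sets = an.classify_response_sets(an.fit_three_way_anova(filtered, design))
res = em.hypergeometric_overlap(hypo, sets.down_in_mut, set(annotation.gene_ids))
```

Output for this run:

```
WT islands: 297  marked genes: 297/500
differential regions: 455  significant: 122  hypomethylated genes: 120
3' signal fraction over hypomethylated genes: WT 0.436  mutant 0.259
expressed genes: 486 (cutoff removed 14)  down in mutant: 118  up: 43
hypo ∩ down overlap: k=115 (expected 28.3), fold 4.1, P = 9.12e-103
```

Reading it: the caller marks 297 of 500 genes in WT (the generator marked
300); the WT-vs-mutant contrast recovers 120 hypomethylated genes (truth:
120); the mark over those genes shifts from a gently 5′-biased profile
(3′ fraction 0.436) to a strongly 5′-shifted one (0.259) when 80% of the 3′
signal is lost; and the hypomethylated set overlaps the down-regulated set
~4-fold above chance, mirroring the coupling built into the generator.

The same stages are scriptable from a shell via the `epimark` entry point
(`epimark simulate`, `epimark islands call|diff|annotate`,
`epimark metagene`, `epimark anova`, `epimark qc replicates|pcr`,
`epimark report`).

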