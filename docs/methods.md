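# Methods

This note records the models behind each stage of the pipeline, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test-bed does and does not establish
about real data.

## The synthetic allotetraploid

The generator (`synthetic_genome`) encodes the assumed history directly:

1. A random uniform-ACGT ancestor of `n_pairs` chromosomes (default 10) of
   `chrom_len` bp (default 2 Mb — desk scale, ~40 Mb total, so the full
   pipeline runs in minutes) carrying `n_genes_per_chrom` gene templates
   (default 100 per chromosome, 1-kb genes on a regular grid).
2. Two progenitor lineages evolve independently for `divergence_time` years
   (default 5.8 × 10⁶) at `substitution_rate` r (default 1.3 × 10⁻⁸
   /site/year). Substitutions are drawn from the exact Jukes–Cantor kernel:
   a site differs from its start state with probability 3/4·(1 − e^(−4d/3))
   for branch length d = rT and, conditional on differing, is uniform over
   the three alternatives. Because the simulated kernel *is* the JC model,
   applying the JC distance to simulated alignments is unbiased — the
   cross-module recovery tests depend on this exactness, and the expected
   *p*-distance between the two parents is 3/4·(1 − e^(−8rT/3)) ≈ 0.086,
   not the naive 2rT ≈ 0.091 (which is instead the expectation of the
   JC-corrected distance).
3. Each lineage receives LTR retrotransposon bursts: `burst_families_A` = 8
   subfamilies in A and `burst_families_B` = 1 in B (the asymmetry the
   enrichment stage must recover). Each element is 5′LTR–internal–3′LTR
   (300 + 1000 + 300 bp) copied from a per-family consensus; insertion ages
   are Normal(`burst_age` = 3.5 Myr, sd 0.5 Myr) truncated to
   (0, divergence_time), and each copy's two terminal repeats then evolve
   independently for `age` years — the exact signal terminal-repeat dating
   assumes. Internal regions stay at consensus: the age signal lives only in
   the LTRs, which is what the k/2r clock reads.
4. Copy numbers are 12 per A-family per A-scaffold and 100 for the single
   B-family per B-scaffold. These are free knobs (no empirical counts exist
   for the progenitors); they were chosen so that (a) consensus k-mers clear
   the genome-wide abundance floor of 100 (≈ 120 intact internal copies per
   family), (b) both subgenomes have ≈ 2 diagnostic-k-mer-bearing elements
   per 50-kb window, so window symbols are rarely missing, and (c) ≥ 200
   elements are available for age recovery.
5. The allopolyploid merge concatenates both parents under neutral shuffled
   scaffold names, deletes each ancestral gene from subgenome A with
   probability 1 − 0.85 and from B with 1 − 0.79 (independently), and plants
   the configured homoeologous exchange by overwriting the destination
   scaffold with the source's homologous sequence (default: one 200-kb A→B
   translocation). Gene deletion replaces the sequence with fresh background,
   not just the annotation — k-mer stages cannot cheat by reading ghosts.

Two deliberate simplifications keep the test-bed exact. Elements and gene
losses *overwrite* background rather than inserting/deleting, so ancestor
and parents stay colinear at identical coordinates and every coordinate
comparison in the tests is exact; and there are no indels, gene structure,
or non-LTR repeat classes. Consequently, passing tests establish the
*statistical machinery* — phasing separability, HMM decoding, clustering,
dating, the exact tests — under the assumed history; they do not establish
robustness to assembly artifacts, nested/fragmented elements, indel-rich
alignment, or rate variation among families, all of which real genomes
have.

Determinism: all randomness flows from one integer seed through numpy
Generator streams; equal seeds give byte-identical genomes.

## Phasing

Counting is canonical (each 13-mer merged with its reverse complement under
lexicographic minimum) because assemblies have arbitrary strand per
scaffold; non-canonical mode exists for reproduction attempts. The
abundance floor (`min_total_count` = 100) is genome-wide. A k-mer is
diagnostic for a pair only if the raw fold and the per-Mb-standardized fold
both reach `min_fold` = 3 in the same direction; a zero denominator counts
as infinite fold (a k-mer entirely absent from one homoeolog is the
strongest possible signal, and rejecting it would discard exactly the relic
repeats the method looks for). Scaffolds are clustered on per-Mb
standardized diagnostic counts with complete linkage (the common default of
the heatmap-clustering tools this analysis family uses; exposed as an
option) and the cut is validated: any homoeologous pair landing in one
cluster is a hard error, not a warning. Each k-mer is then oriented by
majority vote over the pairs in which it is diagnostic; conflicted k-mers
are dropped, and the side with more preferred k-mers is labeled A — a
deterministic convention that also matches the expectation that the
dominant subgenome carries more relic repeats.

## Exchange HMM

Window symbols are the majority diagnostic side per window (`a`/`b`), with
ties — including empty windows — recorded as `missing`. Missing windows are
skipped as evidence (emission factor 1) while the transition chain is kept:
a third emission symbol would let sparse regions *pull* the state, whereas
regions with few diagnostic k-mers are exactly where assignment is least
trustworthy. Start probabilities are 0.5/0.5 and the switch probability is
fixed at 0.01; only emissions are trained (iterated Viterbi decoding with
Laplace +1 smoothing, parameters frozen otherwise, stop at max change
< 10⁻⁴). Training material should be scaffolds believed exchange-free;
`pick_training_scaffolds` automates the choice by minority-symbol count and
takes one scaffold per subgenome so both states are visited. Viterbi ties
break toward staying in the previous state, which favors fewer segments —
the right prior when exchange is rare. Calls are window-resolution; with
emissions trained to ≈ 0.98, a minority run must span ≥ 2–3 informative
windows to outweigh two switches, which sets the method's resolution floor
and its false-positive behavior (quantified in the acceptance run by
decoding exchange-free symbol sequences drawn from the trained model
itself: the generative false-positive rate).

The library default window is 1 Mb (appropriate for ~40-Mb chromosomes);
the desk-scale runs use 50 kb so that a 200-kb planted exchange spans four
windows. The window should scale with scaffold length so that a scaffold
has tens of windows.

## LTR subfamilies and dating

Edges of the similarity graph connect elements whose 5′-LTR global
alignment reaches identity ≥ 0.70 with mutual coverage ≥ 0.90. The identity
threshold replaces a BLAST e-value cutoff (e-values need database-size
statistics that a pairwise setting does not have); the 90% mutual-coverage
filter is kept as is. Default alignment is unit-cost (edlib), with an exact
early-abandon: identity = matches/(matches + d) ≤ min(|x|,|y|)/(min(|x|,|y|)
+ d), so pairs whose edit distance exceeds min·(1 − θ)/θ cannot reach
identity θ and are skipped after the distance-only pass.

Markov clustering: self-loops set to each node's maximum incident weight,
columns normalized, then expansion (matrix square) and inflation
(elementwise power 3) alternate; after renormalization, entries below 10⁻⁵
are pruned *except each column's maximum* — pruning before renormalizing
would zero out wide uniform columns (a 400-member family's 1/400 entries
inflate below any absolute threshold) and silently merge large families.
Clusters are read off by attractor row (column argmax); nodes are processed
in lexicographic id order so results are reproducible bit-for-bit.

Dating converts the proportion of differing sites p over gap-free columns
to k = −(3/4)·ln(1 − 4p/3) and t = k/2r. Two modes: `within_family_pairs`
(all pairwise 5′-LTR distances inside a subfamily; dates divergence from
the common burst) and `five_vs_three_prime` (each element's own two
terminal repeats; the classical per-element insertion clock — this is the
mode the recovery checks use, since the simulator plants per-element ages).
The dating alignment is *not* the unit-cost one: a minimum-edit-distance
path trades clusters of substitutions for spurious indel pairs and biases p
— hence every age — downward by ~10% at these divergences. Dating therefore
uses a gap-penalized Needleman–Wunsch (match 0, mismatch −1, gap −4), under
which the simulated (indel-free) comparisons reduce to site-wise
comparison and age recovery is unbiased (3.54 vs 3.50 Myr planted, n ≈
2000). Saturated comparisons (p ≥ 0.75) are dropped and counted.

## Fractionation statistics

The ancestral universe is genes with ≥ 1 surviving copy — genes lost from
both subgenomes are unobservable. The retention-bias 2×2 is
retained-vs-lost per subgenome where "lost from A" means retained only in
B; this is the construction under which the published-count checks
reproduce exactly. Percentages are exact fractions; rounding happens only
at display. The Fisher test computes hypergeometric point probabilities in
log space over the full support and sums those not exceeding the observed
one (relative tolerance 10⁻⁷), the standard two-sided convention.

Because the two rows of the retention table are built from the same genes,
the test is slightly anticonservative under the matched null: simulated
type-I error is ≈ 5–6% at retention 0.85 and drifts toward 7.5% at 0.60.
At the study's retention levels it sits within 5% ± 2% (verified on 1,000
replicates of 2,000 genes in the acceptance run).

GO enrichment is plain per-term one-sided Fisher over-representation with
`expected = annotated × |foreground| / |universe|` and raw p-values by
default (an optional Benjamini–Hochberg column exists). The term map is a
flat gene → terms table; DAG-aware elimination/weighting algorithms are out
of scope, so p-values for deeply nested terms can differ from tools that
use them. `exclude_genes_in_regions` re-runs the accounting without genes
in ambiguously assigned regions.

## TE density

Density is the union of TE intervals intersected with the window, divided
by window length — the only definition bounded by 1 and invariant to
annotation fragmentation (property-tested). Up/downstream follow gene
strand by default (toggle provided). Windows truncated by a scaffold end
are renormalized to the truncated length and flagged; a `drop` mode reports
NaN instead. The Mann–Whitney test enumerates rank assignments exactly for
tie-free pooled samples ≤ 12, otherwise uses the tie-corrected normal
approximation with continuity correction (type-I ≈ 4.7–5.4% at n = 50+50).

## Numerical and degenerate-input conventions

* Coordinates: 0-based half-open everywhere internally; GFF3's 1-based
  closed convention converted only at I/O. IUPAC ambiguity letters fold to
  N (counted, logged); k-mer windows containing N contribute nothing.
* pg→Mbp conversion: 978 Mbp/pg (configurable).
* Degenerate Fisher margins give p = 1; identical pooled Mann–Whitney
  samples give p = 1; an all-missing HMM scaffold decodes to the prior
  argmax with a warning; an empty diagnostic k-mer set, an unseparated
  homoeologous pair, an empty ortholog table, and a foreground outside its
  universe are hard errors.
* Greedy disjoint homoeolog pairing by descending minimum coverage with
  lexicographic tie-break; anchor chaining extracts chains longest-first,
  each anchor in at most one block.

## Problem sizes

The desk-scale configuration (20 × 2 Mb, ~2,000 LTR elements, 1,000
ancestral genes) was chosen so the complete pipeline — simulation, k-mer
phasing, exchange scan, subfamily clustering, dating, and both 1,000-
replicate calibrations — completes in about two minutes on one CPU; the
test suite uses a 4-pair × 500-kb version of the same conditions for
per-module checks and runs the desk scale once in the acceptance tests.
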