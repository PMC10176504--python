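# subkit

Subgenome phasing and post-polyploidy analysis for allotetraploid genome
assemblies.

Many plant genomes are recent allopolyploids: two diploid progenitor genomes
merged into one nucleus by hybridization. Long after the event, each
chromosome still descends from one progenitor or the other, and questions
about the merge — which chromosomes form each subgenome, whether the
subgenomes have exchanged material, when the progenitors' transposable
elements were active, and which subgenome lost more genes — can be answered
from the assembly alone. `subkit` implements that analysis chain for
genomicists working on polyploid assemblies, together with a ground-truthed
synthetic allotetraploid generator that makes every stage testable without
any external data.

## What it computes

* **Diagnostic k-mer phasing.** Count 13-mers per scaffold (canonical,
  in-memory); keep those abundant genome-wide (≥ 100 occurrences) and ≥ 3-fold
  enriched on one member of a homoeologous scaffold pair, both before and
  after standardizing counts per Mb and only when both folds agree in
  direction. Scaffolds are clustered on the diagnostic count matrix
  (Euclidean distance, complete linkage, cut at two clusters) to define
  subgenomes A and B; the side with more preferred k-mers is named A.
* **Homoeolog pairing and synteny.** Pairs are scaffolds whose mutual
  self-alignment coverage (union of aligned intervals, PAF input) exceeds 50%
  on *both* scaffolds; collinear blocks against a reference diploid are
  chained from one-to-one gene anchors (longest monotone chains in rank
  space) and summarized into an ortholog table.
* **Homoeologous exchange.** Each scaffold is reduced to 1-window symbols
  (majority diagnostic-k-mer side); a two-state HMM with equal start
  probabilities and switch probability 0.01 is decoded by Viterbi, with
  emissions re-estimated by Viterbi training on exchange-free scaffolds.
  Runs decoded against the scaffold's assigned subgenome are exchange calls.
* **LTR retrotransposon dynamics.** Elements are clustered into subfamilies
  by Markov clustering (inflation 3) of a pairwise-alignment graph (identity
  ≥ 0.70, mutual coverage ≥ 0.90); subfamilies ≥ 3-fold more common in one
  subgenome by both occurrence and bp are flagged; insertion ages come from
  the Jukes–Cantor distance k = −(3/4)·ln(1 − 4p/3) between terminal repeats
  as t = k/2r with r = 1.3 × 10⁻⁸ substitutions/site/year.
* **Biased fractionation.** Ancestral-gene accounting per subgenome
  (retained on A / B / both as fractions of genes with ≥ 1 surviving copy), a
  two-sided Fisher's exact test of retained-vs-lost counts, and per-term
  one-sided Fisher GO over-representation of single-copy or duplicated gene
  sets.
* **TE density near genes.** TE-occupied fraction of 5-kb windows
  up/downstream of each gene (union of TE intervals), compared between
  groups by a Mann–Whitney U test (exact for small tie-free samples,
  tie-corrected normal approximation otherwise).
* **Flow-cytometry genome size.** 2C picograms → haploid Mbp at
  978 Mbp/pg (2.56 pg → 1.25 Gb).

## Worked example

Simulate a small allotetraploid (4 homoeologous pairs of 500-kb scaffolds,
progenitors diverged 5.8 Myr ago, LTR bursts at 3.5 Myr, retention
probabilities 0.85/0.79, one planted 200-kb exchange), then phase it and
scan for exchange:

```python
from subkit import (SimConfig, simulate, pair_homoeologs, count_kmers, KmerConfig,
                    select_diagnostic_kmers, density_track, detect_exchanges,
                    tally_retention, retention_bias_test)
from subkit.synthetic_genome import truth_paf
from subkit.exchange_hmm import pick_training_scaffolds

cfg = SimConfig(n_pairs=4, chrom_len=500_000, seed=1)
cfg.exchange_spec = [("A", 1, 250_000, 450_000)]
tetra, features, orthologs, truth = simulate(cfg)

pairs = pair_homoeologs(truth_paf(tetra, truth))
kcfg = KmerConfig(min_total_count=20)   # abundance floor scaled to the small genome
kmers = select_diagnostic_kmers(count_kmers(tetra, kcfg), pairs, kcfg)

tracks = {s: density_track(tetra, s, kmers, 50_000) for s in tetra.names()}
train = pick_training_scaffolds(tracks, kmers.assignment)
calls, model = detect_exchanges(tracks, kmers.assignment, train_scaffolds=train)

rt = tally_retention(orthologs)
```

Output:

```
homoeologous pairs: 4
diagnostic 13-mers: 10391 A-preferred, 1307 B-preferred
subgenome assignment: 8/8 scaffolds correct
exchange call: scf01:250000-500000 (truth 250000-450000)
retention: A 88.9%, B 83.2%, both 72.0% (bias p = 2.90e-02)
```

All 8 scaffolds phase to their true subgenome; the planted exchange is
recovered with its right boundary off by one 50-kb window (calls are
window-resolution); the A subgenome retains more genes than B, as simulated.
The retention percentages exceed the input probabilities because the
accounting universe is genes with at least one surviving copy.

The same pipeline is available from the shell: `subkit simulate`,
`subkit pair`, `subkit phase`, `subkit exchange`, `subkit fractionation`,
`subkit fcm`.

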