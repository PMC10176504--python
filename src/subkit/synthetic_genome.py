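"""Synthetic allotetraploid genome with full ground truth.

The generative model mirrors the history the downstream analyses assume:

* a random diploid ancestor carrying gene templates;
* two progenitor lineages that each accumulate Jukes–Cantor substitutions for
  ``divergence_time`` years at ``substitution_rate`` per site per year;
* lineage-specific LTR retrotransposon bursts: each burst subfamily has a
  consensus element (5' LTR — internal — 3' LTR, the two terminal repeats
  identical at insertion time); copies are planted with insertion ages drawn
  from a normal distribution around ``burst_age`` truncated to
  ``(0, divergence_time)``, and each copy's two terminal repeats then evolve
  independently for ``age`` years — exactly the signal that terminal-repeat
  divergence dating assumes;
* an allopolyploid merge hiding the parental scaffolds behind neutral ids,
  followed by biased gene loss (independent retention per subgenome) and an
  optional planted homoeologous exchange (sequence copied from one subgenome
  onto its partner).

Elements and gene losses are placed by *overwriting* intergenic background
rather than inserting/deleting, so the ancestor and both parents stay
colinear at identical coordinates; this keeps every coordinate comparison in
the test-bed exact while leaving the k-mer and divergence signals untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Feature, GenomeSet, PafRecord

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the simulated allopolyploidy history.

    Defaults are desk scale: 10 homoeologous pairs of 2-Mb scaffolds
    (~40 Mb total), progenitors diverged 5.8 Myr at 1.3e-8 substitutions
    per site per year, 8 A-specific and 1 B-specific LTR burst subfamilies
    peaking 3.5 Myr ago, and per-subgenome gene retention probabilities
    0.85 (A) and 0.79 (B).
    """

    n_pairs: int = 10
    chrom_len: int = 2_000_000
    n_genes_per_chrom: int = 100
    gene_len: int = 1_000
    divergence_time: float = 5.8e6
    substitution_rate: float = 1.3e-8
    burst_families_A: int = 8
    burst_families_B: int = 1
    burst_age: float = 3.5e6
    burst_age_sd: float = 0.5e6
    ltr_len: int = 300
    internal_len: int = 1_000
    copies_per_scaffold_A: int = 12
    copies_per_scaffold_B: int = 100
    retention_prob_A: float = 0.85
    retention_prob_B: float = 0.79
    # (source scaffold index 0-based, source subgenome 'A'/'B', pair index, start, end):
    # sequence of the source parent is copied onto its homoeologous partner.
    exchange_spec: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.retention_prob_A <= 1.0 and 0.0 <= self.retention_prob_B <= 1.0):
            raise ValueError("retention probabilities must lie in [0, 1]")
        if self.burst_age > self.divergence_time:
            raise ValueError("burst_age must not exceed divergence_time")
        if min(self.n_pairs, self.chrom_len, self.gene_len, self.ltr_len, self.internal_len) <= 0:
            raise ValueError("counts and lengths must be positive")

    @property
    def element_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len


def default_exchange_spec(cfg: SimConfig) -> list:
    """One planted 200-kb homoeologous translocation: A material of pair 2
    overwrites the tail of its B partner."""
    end = min(1_600_000, cfg.chrom_len)
    return [("A", 2, end - 200_000, end)]


@dataclass
class TruthSet:
    """Simulator ground truth used to score every downstream stage."""

    subgenome_of: dict = field(default_factory=dict)          # scaffold -> 'A'/'B'
    gene_fate: dict = field(default_factory=dict)             # ancestral gene id -> fate
    ltr_age: dict = field(default_factory=dict)               # element id -> years
    ltr_family_truth: dict = field(default_factory=dict)      # element id -> family id
    exchange_segments: list = field(default_factory=list)     # Feature(kind=exchange_segment)
    homoeolog_pairs: list = field(default_factory=list)       # (scaffoldA, scaffoldB)


# ---------------------------------------------------------------------------
# Jukes–Cantor machinery on 2-bit arrays
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def jc_substitution_prob(branch_length: float) -> float:
    """P(site differs from its start state) after a JC branch of expected
    ``branch_length`` substitutions per site."""
    return 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))


def jc_mutate(seq: np.ndarray, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a 2-bit-coded sequence along one JC branch.

    Sites differ from the start state with probability
    ``3/4 (1 - exp(-4d/3))`` and, conditional on differing, are uniform over
    the three alternative bases — the exact JC transition kernel, so applying
    the JC distance formula to simulated alignments is unbiased.
    """
    p = jc_substitution_prob(branch_length)
    hit = rng.random(seq.size) < p
    out = seq.copy()
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def _from_str(s: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.uint8)
    for i, ch in enumerate(b"ACGT"):
        lut[ch] = i
    return lut[np.frombuffer(s.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Progenitors
# ---------------------------------------------------------------------------

class _Occupancy:
    """Sorted intergenic occupancy map for non-overlapping element placement."""

    def __init__(self, length: int):
        self.length = length
        self.intervals: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> bool:
        for s, e in self.intervals:
            if start < e and s < end:
                return False
        self.intervals.append((start, end))
        return True


def _place_elements(
    rng: np.random.Generator,
    occ: _Occupancy,
    n: int,
    elem_len: int,
    max_retries: int = 2000,
) -> list[int]:
    starts = []
    for _ in range(n):
        for _try in range(max_retries):
            pos = int(rng.integers(0, occ.length - elem_len))
            if occ.reserve(pos, pos + elem_len):
                starts.append(pos)
                break
        else:
            raise RuntimeError(
                "could not place an element without overlapping genes or other "
                "elements; reduce copies_per_scaffold_* or increase chrom_len"
            )
    return starts


def simulate_progenitors(cfg: SimConfig):
    """Simulate the ancestor and the two diverged progenitor genomes.

    Returns ``(ancestor, parent_a, parent_b, gene_features, truth)`` where
    the gene features are the ancestral templates (valid at the same
    coordinates on all three genomes) and ``truth`` is partially filled
    (LTR ages and families; subgenome labels come with the merge).
    """
    rng = np.random.default_rng(cfg.seed)
    d_branch = cfg.substitution_rate * cfg.divergence_time

    ancestor_arrays = {}
    genes: list[Feature] = []
    spacing = cfg.chrom_len // cfg.n_genes_per_chrom
    if spacing < 2 * cfg.gene_len:
        raise ValueError("chromosome too short for requested gene count")
    for i in range(cfg.n_pairs):
        name = f"anc{i:02d}"
        ancestor_arrays[name] = _random_seq(rng, cfg.chrom_len)
        for g in range(cfg.n_genes_per_chrom):
            start = g * spacing + spacing // 4
            genes.append(Feature(name, start, start + cfg.gene_len, "+", "gene", f"g{i:02d}_{g:03d}"))

    # Diverge the two lineages.
    parent_arrays = {"A": {}, "B": {}}
    for name, arr in ancestor_arrays.items():
        parent_arrays["A"][name] = jc_mutate(arr, d_branch, rng)
        parent_arrays["B"][name] = jc_mutate(arr, d_branch, rng)

    # Lineage-specific LTR bursts.
    truth = TruthSet()
    te_features: list[Feature] = []
    gene_spans = {}
    for f in genes:
        gene_spans.setdefault(f.scaffold, []).append((f.start, f.end))

    fam_specs = [("A", f"famA{j}") for j in range(cfg.burst_families_A)] + [
        ("B", f"famB{j}") for j in range(cfg.burst_families_B)
    ]
    consensi = {
        fam: (_random_seq(rng, cfg.ltr_len), _random_seq(rng, cfg.internal_len))
        for _side, fam in fam_specs
    }
    elem_len = cfg.element_len
    counter = 0
    for name in ancestor_arrays:
        for side in ("A", "B"):
            occ = _Occupancy(cfg.chrom_len)
            for s, e in gene_spans.get(name, []):
                occ.reserve(s, e)
            side_fams = [fam for sd, fam in fam_specs if sd == side]
            n_copies = cfg.copies_per_scaffold_A if side == "A" else cfg.copies_per_scaffold_B
            for fam in side_fams:
                ltr_cons, int_cons = consensi[fam]
                starts = _place_elements(rng, occ, n_copies, elem_len)
                for pos in starts:
                    age = -1.0
                    while not (0.0 < age < cfg.divergence_time):
                        age = float(rng.normal(cfg.burst_age, cfg.burst_age_sd))
                    d_age = cfg.substitution_rate * age
                    ltr5 = jc_mutate(ltr_cons, d_age, rng)
                    ltr3 = jc_mutate(ltr_cons, d_age, rng)
                    arr = parent_arrays[side][name]
                    arr[pos : pos + cfg.ltr_len] = ltr5
                    arr[pos + cfg.ltr_len : pos + cfg.ltr_len + cfg.internal_len] = int_cons
                    arr[pos + cfg.ltr_len + cfg.internal_len : pos + elem_len] = ltr3
                    eid = f"ltr{counter:05d}"
                    counter += 1
                    te_features.append(
                        Feature(
                            name, pos, pos + elem_len, "+", "LTR_element", eid,
                            {
                                "parent_side": side,
                                "family": fam,
                                "five_prime": (pos, pos + cfg.ltr_len),
                                "three_prime": (pos + cfg.ltr_len + cfg.internal_len, pos + elem_len),
                            },
                        )
                    )
                    truth.ltr_age[eid] = age
                    truth.ltr_family_truth[eid] = fam

    ancestor = GenomeSet({n: _to_str(a) for n, a in ancestor_arrays.items()})
    parent_a = GenomeSet({n: _to_str(a) for n, a in parent_arrays["A"].items()})
    parent_b = GenomeSet({n: _to_str(a) for n, a in parent_arrays["B"].items()})
    return ancestor, parent_a, parent_b, genes, te_features, truth


# ---------------------------------------------------------------------------
# Allopolyploid merge
# ---------------------------------------------------------------------------

def simulate_allopolyploid(
    parent_a: GenomeSet,
    parent_b: GenomeSet,
    genes: list[Feature],
    te_features: list[Feature],
    truth: TruthSet,
    cfg: SimConfig,
):
    """Merge the progenitors into one tetraploid genome with biased gene loss
    and optional planted homoeologous exchange.

    Returns ``(tetraploid, features, ortholog_table, truth)``.  Scaffolds of
    both parents are renamed to neutral ids (``scf00`` ...) in an interleaved
    shuffled order; each ancestral gene is deleted from subgenome A with
    probability ``1 - retention_prob_A`` (independently from B), deletion
    meaning both the annotation is dropped and the sequence is overwritten
    with fresh random background.  ``ortholog_table`` maps each ancestral
    gene to its surviving A/B copies.
    """
    rng = np.random.default_rng(cfg.seed + 1)

    anc_names = parent_a.names()
    origins = [("A", n) for n in anc_names] + [("B", n) for n in anc_names]
    order = rng.permutation(len(origins))
    neutral: dict[tuple, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for new_idx, old_idx in enumerate(order):
        side, anc = origins[old_idx]
        name = f"scf{new_idx:02d}"
        neutral[(side, anc)] = name
        src = parent_a if side == "A" else parent_b
        arrays[name] = _from_str(src[anc])
        truth.subgenome_of[name] = side
    for anc in anc_names:
        truth.homoeolog_pairs.append((neutral[("A", anc)], neutral[("B", anc)]))

    # Biased gene loss.
    features: list[Feature] = []
    for g in sorted(genes, key=lambda f: f.id):
        keep_a = rng.random() < cfg.retention_prob_A
        keep_b = rng.random() < cfg.retention_prob_B
        for side, keep in (("A", keep_a), ("B", keep_b)):
            scaf = neutral[(side, g.scaffold)]
            if keep:
                gid = f"{g.id}_{side}"
                features.append(
                    Feature(scaf, g.start, g.end, g.strand, "gene", gid,
                            {"ancestral_id": g.id, "subgenome": side})
                )
            else:
                arrays[scaf][g.start : g.end] = _random_seq(rng, g.end - g.start)

    # Carry TE annotations over to neutral coordinates (same positions).
    for te in te_features:
        side = te.attrs["parent_side"]
        scaf = neutral[(side, te.scaffold)]
        features.append(
            Feature(scaf, te.start, te.end, te.strand, "LTR_element", te.id, dict(te.attrs))
        )

    # Planted homoeologous exchange: overwrite the partner with source sequence.
    spec = cfg.exchange_spec
    for source_side, pair_idx, start, end in spec:
        anc = anc_names[pair_idx]
        dest_side = "B" if source_side == "A" else "A"
        src_name = neutral[(source_side, anc)]
        dst_name = neutral[(dest_side, anc)]
        if not (0 <= start < end <= len(arrays[dst_name])):
            raise ValueError(f"exchange segment [{start}, {end}) out of bounds on {dst_name}")
        arrays[dst_name][start:end] = arrays[src_name][start:end]
        truth.exchange_segments.append(
            Feature(dst_name, start, end, ".", "exchange_segment",
                    f"hx_{src_name}_{dst_name}_{start}",
                    {"source": src_name})
        )
        # Annotations under the overwritten window are gone; copies of the
        # source annotations now exist on the destination.
        features = [
            f for f in features
            if not (f.scaffold == dst_name and f.start < end and f.end > start)
        ]
        dups = []
        for f in list(features):
            if f.scaffold == src_name and start <= f.start and f.end <= end:
                dups.append(
                    Feature(dst_name, f.start, f.end, f.strand, f.kind, f.id + "_hx",
                            dict(f.attrs, exchanged="1"))
                )
        features.extend(dups)

    # Final fate accounting from the surviving annotations: a gene is retained
    # on a subgenome if a copy physically sits on one of its scaffolds (an
    # exchanged copy counts for the scaffold it now lives on, which is how a
    # synteny scan of the merged genome would see it).
    copies: dict[str, dict] = {}
    for f in features:
        if f.kind != "gene":
            continue
        aid = f.attrs["ancestral_id"]
        side = truth.subgenome_of[f.scaffold]
        copies.setdefault(aid, {}).setdefault(side, f.id)
    rows = []
    for g in sorted(genes, key=lambda f: f.id):
        d = copies.get(g.id, {})
        truth.gene_fate[g.id] = {
            (True, True): "both",
            (True, False): "A_only",
            (False, True): "B_only",
            (False, False): "lost_both",
        }[("A" in d, "B" in d)]
        rows.append({"ref_gene": g.id, "A_gene": d.get("A", "-"), "B_gene": d.get("B", "-")})
    ortholog_table = pd.DataFrame(rows)

    tetraploid = GenomeSet({n: _to_str(a) for n, a in arrays.items()})
    return tetraploid, features, ortholog_table, truth


def simulate(cfg: SimConfig):
    """Run the full simulation; returns ``(tetraploid, features, ortholog_table, truth)``."""
    _anc, pa, pb, genes, tes, truth = simulate_progenitors(cfg)
    return simulate_allopolyploid(pa, pb, genes, tes, truth, cfg)


# ---------------------------------------------------------------------------
# Truth-based PAF emission (trivial self-alignment of known homoeologs)
# ---------------------------------------------------------------------------

def truth_paf(tetraploid: GenomeSet, truth: TruthSet, block: int = 500_000,
              identity: float = 0.92) -> list[PafRecord]:
    """Emit PAF records pairing each homoeologous scaffold pair.

    The progenitors are colinear by construction, so each pair aligns
    end-to-end; records are emitted in ``block``-sized pieces (both
    orientations of each pair) the way a self-alignment would report them.
    """
    recs = []
    for sa, sb in truth.homoeolog_pairs:
        la, lb = len(tetraploid[sa]), len(tetraploid[sb])
        L = min(la, lb)
        for s in range(0, L, block):
            e = min(s + block, L)
            nmatch = int((e - s) * identity)
            recs.append(PafRecord(sa, la, s, e, "+", sb, lb, s, e, nmatch, e - s))
            recs.append(PafRecord(sb, lb, s, e, "+", sa, la, s, e, nmatch, e - s))
    return recs


# ---------------------------------------------------------------------------
# Truth TSV round trip
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, prefix: str) -> None:
    pd.DataFrame(
        [(s, g) for s, g in truth.subgenome_of.items()], columns=["scaffold", "subgenome"]
    ).to_csv(f"{prefix}.subgenomes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, f) for g, f in truth.gene_fate.items()], columns=["gene", "fate"]
    ).to_csv(f"{prefix}.gene_fate.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(e, truth.ltr_family_truth[e], a) for e, a in truth.ltr_age.items()],
        columns=["element", "family", "age_years"],
    ).to_csv(f"{prefix}.ltr.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(f.scaffold, f.start, f.end, f.attrs.get("source", "")) for f in truth.exchange_segments],
        columns=["scaffold", "start", "end", "source"],
    ).to_csv(f"{prefix}.exchange.tsv", sep="\t", index=False)
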