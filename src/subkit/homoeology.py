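"""Homoeologous scaffold pairing and collinear anchor chaining.

Homoeologous pairs are read off a whole-genome self-alignment (PAF): two
scaffolds are candidates when the union of their mutual alignments covers
more than half of *each* scaffold, and candidates are greedily resolved into
disjoint pairs.  Collinear blocks against a reference diploid (or the
simulator's ancestor) are found by chaining one-to-one gene anchors into
longest monotone runs in rank space — a deliberately small stand-in for a
full synteny scanner — and summarized into an ortholog table recording which
subgenome retains a copy of each reference gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core_io import Feature, PafRecord

log = logging.getLogger("subkit")


@dataclass
class HomoeologPair:
    scaffold_x: str
    scaffold_y: str
    cov_x: float
    cov_y: float


@dataclass
class CollinearBlock:
    anchors: list                      # ordered (gene_x, gene_y) pairs
    orientation: str                   # '+' or '-'
    scaffolds: tuple = ("", "")

    def __len__(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------
# Pairing from PAF coverage
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        if s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def pair_homoeologs(paf: list[PafRecord], min_cov: float = 0.5) -> list[HomoeologPair]:
    """Disjoint homoeologous scaffold pairs from self-alignment coverage.

    Per unordered scaffold pair, the coverage of each scaffold is the union
    of aligned intervals on it (from records in either direction) divided by
    its length.  Pairs where both coverages exceed ``min_cov`` are selected
    greedily by descending minimum coverage, each scaffold used at most once.
    """
    if not paf:
        log.warning("pair_homoeologs: empty PAF input")
        return []
    intervals: dict[tuple, dict[str, list]] = {}
    lengths: dict[str, int] = {}
    for r in paf:
        if r.query == r.target:
            continue  # self-hit
        key = tuple(sorted((r.query, r.target)))
        d = intervals.setdefault(key, {key[0]: [], key[1]: []})
        d[r.query].append((r.qstart, r.qend))
        d[r.target].append((r.tstart, r.tend))
        lengths[r.query] = r.qlen
        lengths[r.target] = r.tlen

    candidates = []
    for (sx, sy), d in intervals.items():
        cov_x = _union_length(d[sx]) / lengths[sx]
        cov_y = _union_length(d[sy]) / lengths[sy]
        if cov_x > min_cov and cov_y > min_cov:
            candidates.append(HomoeologPair(sx, sy, cov_x, cov_y))

    candidates.sort(key=lambda p: (-min(p.cov_x, p.cov_y), p.scaffold_x, p.scaffold_y))
    used: set[str] = set()
    pairs = []
    for p in candidates:
        if p.scaffold_x in used or p.scaffold_y in used:
            continue
        used.update((p.scaffold_x, p.scaffold_y))
        pairs.append(p)
    return pairs


# ---------------------------------------------------------------------------
# Anchor chaining
# ---------------------------------------------------------------------------

def best_reciprocal_hits(hits: list[tuple]) -> list[tuple]:
    """Keep hits that are the top-scoring hit of both their genes
    (ties broken by lexicographic partner gene id)."""

    def _best(group_key, partner_key):
        best = {}
        for h in hits:
            k = h[group_key]
            cur = best.get(k)
            if cur is None or h[4] > cur[4] or (h[4] == cur[4] and h[partner_key] < cur[partner_key]):
                best[k] = h
        return best

    bx = _best(0, 2)
    by = _best(2, 0)
    return [h for h in hits if bx.get(h[0]) == h and by.get(h[2]) == h]


def chain_anchors(
    hits: list[tuple],
    max_gap: int = 25,
    min_block: int = 5,
) -> list[CollinearBlock]:
    """Chain one-to-one anchors into collinear blocks.

    ``hits`` are ``(gene_x, rank_x, gene_y, rank_y, score)`` tuples for one
    scaffold pair.  After best-reciprocal filtering, longest monotone chains
    (strictly increasing ranks for '+', x-increasing / y-decreasing for '-')
    with rank gaps <= ``max_gap`` on both axes are extracted by dynamic
    programming; chains shorter than ``min_block`` are discarded and each
    anchor belongs to at most one block.
    """
    anchors = best_reciprocal_hits(hits)
    anchors = sorted(anchors, key=lambda h: (h[1], h[3]))
    blocks: list[CollinearBlock] = []
    remaining = list(anchors)

    def _longest_chain(items: list[tuple], sign: int) -> list[int]:
        n = len(items)
        best_len = [1] * n
        prev = [-1] * n
        for j in range(n):
            for i in range(j):
                dx = items[j][1] - items[i][1]
                dy = sign * (items[j][3] - items[i][3])
                if 0 < dx <= max_gap and 0 < dy <= max_gap and best_len[i] + 1 > best_len[j]:
                    best_len[j] = best_len[i] + 1
                    prev[j] = i
        if n == 0:
            return []
        end = max(range(n), key=lambda j: best_len[j])
        chain = []
        while end != -1:
            chain.append(end)
            end = prev[end]
        chain.reverse()
        return chain

    while remaining:
        fwd = _longest_chain(remaining, +1)
        rev = _longest_chain(remaining, -1)
        chain, orient = (fwd, "+") if len(fwd) >= len(rev) else (rev, "-")
        if len(chain) < min_block:
            break
        picked = [remaining[i] for i in chain]
        blocks.append(
            CollinearBlock([(h[0], h[2]) for h in picked], orient)
        )
        chain_set = set(chain)
        remaining = [h for i, h in enumerate(remaining) if i not in chain_set]
    return blocks


# ---------------------------------------------------------------------------
# Ortholog table
# ---------------------------------------------------------------------------

def ortholog_table(
    blocks: list[CollinearBlock],
    gene_scaffold: dict,
    assignment,
) -> pd.DataFrame:
    """Reference gene -> retained A/B copies from collinear blocks.

    ``gene_scaffold`` maps each non-reference anchor gene to its scaffold;
    ``assignment`` maps scaffolds to subgenomes.  A reference gene hit in
    more than one block of the same subgenome keeps the anchor from the
    longest block (ties: first encountered), with a log entry when a gene
    appears in more than two such blocks.
    """
    per_gene: dict[str, dict] = {}
    seen_blocks: dict[tuple, int] = {}
    for b in sorted(blocks, key=len, reverse=True):
        for ref_gene, copy_gene in b.anchors:
            scaf = gene_scaffold[copy_gene]
            side = assignment[scaf]
            entry = per_gene.setdefault(ref_gene, {})
            nb = seen_blocks.setdefault((ref_gene, side), 0)
            seen_blocks[(ref_gene, side)] = nb + 1
            if nb + 1 > 2:
                log.info("ortholog_table: %s in >2 %s-side blocks; longest kept", ref_gene, side)
            if side not in entry:   # blocks visited longest-first
                entry[side] = copy_gene
    rows = [
        {"ref_gene": g, "A_gene": d.get("A", "-"), "B_gene": d.get("B", "-")}
        for g, d in sorted(per_gene.items())
    ]
    return pd.DataFrame(rows, columns=["ref_gene", "A_gene", "B_gene"])


# ---------------------------------------------------------------------------
# Anchor hits from annotations (simulator / precomputed homology plumbing)
# ---------------------------------------------------------------------------

def anchor_hits_from_features(
    ref_genes: list[Feature],
    genes: list[Feature],
    link_attr: str = "ancestral_id",
) -> dict:
    """Build per-scaffold-pair anchor hits from gene features sharing a
    homology attribute (the simulator records the ancestral gene id on each
    surviving copy).  Ranks are gene orders along each scaffold.  Returns
    ``{(ref_scaffold, scaffold): [(gene_x, rank_x, gene_y, rank_y, score)]}``.
    """

    def _ranks(feats):
        ranks = {}
        by_scaf: dict[str, list] = {}
        for f in feats:
            by_scaf.setdefault(f.scaffold, []).append(f)
        for scaf, fs in by_scaf.items():
            for i, f in enumerate(sorted(fs, key=lambda f: f.start)):
                ranks[f.id] = (scaf, i)
        return ranks

    ref_ranks = _ranks(ref_genes)
    tet_ranks = _ranks(genes)
    ref_ids = {f.id for f in ref_genes}
    hits: dict[tuple, list] = {}
    for f in genes:
        aid = f.attrs.get(link_attr)
        if aid is None or aid not in ref_ids:
            continue
        rscaf, rrank = ref_ranks[aid]
        tscaf, trank = tet_ranks[f.id]
        hits.setdefault((rscaf, tscaf), []).append((aid, rrank, f.id, trank, 1.0))
    return hits


def build_ortholog_table(
    ref_genes: list[Feature],
    genes: list[Feature],
    assignment,
    max_gap: int = 25,
    min_block: int = 5,
) -> tuple[pd.DataFrame, list[CollinearBlock]]:
    """Anchor hits -> chained blocks per scaffold pair -> ortholog table."""
    hits = anchor_hits_from_features(ref_genes, genes)
    blocks: list[CollinearBlock] = []
    for (rscaf, tscaf), hh in sorted(hits.items()):
        for b in chain_anchors(hh, max_gap=max_gap, min_block=min_block):
            b.scaffolds = (rscaf, tscaf)
            blocks.append(b)
    gene_scaffold = {f.id: f.scaffold for f in genes}
    return ortholog_table(blocks, gene_scaffold, assignment), blocks
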