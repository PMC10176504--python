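"""LTR retrotransposon subfamilies, subgenome enrichment and insertion dating.

An LTR retrotransposon is flanked by two terminal repeats that are identical
at insertion time; their subsequent divergence clocks the insertion age.
This module clusters annotated elements into subfamilies by Markov
clustering (MCL) of a pairwise-alignment similarity graph, flags subfamilies
that are fold-enriched in one subgenome by both occurrence and base-pair
count, and dates insertions with the Jukes–Cantor corrected distance
``k = -(3/4) ln(1 - 4p/3)`` converted to years as ``t = k / (2r)``.

Two dating modes are provided: ``within_family_pairs`` (all pairwise 5'-LTR
distances inside a subfamily — divergence of family members from their
common burst) and ``five_vs_three_prime`` (each element's own two terminal
repeats — the classical element-wise insertion clock).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .core_io import Feature, GenomeSet

log = logging.getLogger("subkit")

DEFAULT_RATE = 1.3e-8          # substitutions per site per year


@dataclass
class LtrElement:
    id: str
    scaffold: str
    start: int
    end: int
    five_prime: tuple           # (start, end) of the 5' terminal repeat
    three_prime: tuple          # (start, end) of the 3' terminal repeat
    seq5: str = ""
    seq3: str = ""

    def __post_init__(self):
        f, t = self.five_prime, self.three_prime
        if not (self.start <= f[0] < f[1] <= t[0] < t[1] <= self.end):
            raise ValueError(f"terminal repeats of {self.id} malformed or overlapping")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LtrAlignConfig:
    min_identity: float = 0.70
    min_mutual_coverage: float = 0.90
    scores: tuple | None = None      # (match, mismatch, gap); None = unit-cost distance

    def __post_init__(self):
        for v in (self.min_identity, self.min_mutual_coverage):
            if not (0.0 < v <= 1.0):
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class LtrSubfamily:
    family_id: str
    members: list
    occurrences: dict = field(default_factory=dict)   # subgenome -> element count
    bp: dict = field(default_factory=dict)            # subgenome -> total element bp
    enriched: bool = False
    direction: str = ""

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DivergenceEstimate:
    p: float
    k: float
    r: float
    t: float


def elements_from_features(features: list[Feature], genome: GenomeSet) -> list[LtrElement]:
    """Materialize LTR elements (with terminal-repeat sequences) from
    annotation features carrying ``five_prime``/``three_prime`` spans."""
    out = []
    for f in features:
        if f.kind != "LTR_element":
            continue
        fp = tuple(f.attrs["five_prime"])
        tp = tuple(f.attrs["three_prime"])
        seq = genome[f.scaffold]
        out.append(
            LtrElement(f.id, f.scaffold, f.start, f.end, fp, tp,
                       seq[fp[0]:fp[1]], seq[tp[0]:tp[1]])
        )
    return out


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_ops(cigar: str) -> list[tuple[str, int]]:
    return [(m.group(2), int(m.group(1))) for m in _CIG_RE.finditer(cigar)]


def _stats_from_ops(ops, len_x, len_y):
    columns = sum(n for _, n in ops)
    matches = sum(n for op, n in ops if op == "=")
    # trim terminal indel runs for coverage
    lo, hi = 0, len(ops)
    while lo < hi and ops[lo][0] in "ID":
        lo += 1
    while hi > lo and ops[hi - 1][0] in "ID":
        hi -= 1
    core = ops[lo:hi]
    x_core = sum(n for op, n in core if op in "=XI")
    y_core = sum(n for op, n in core if op in "=XD")
    identity = matches / columns if columns else 0.0
    return identity, x_core / len_x, y_core / len_y


def _nw_ops(x: str, y: str, match: float, mismatch: float, gap: float) -> list[tuple[str, int]]:
    """Needleman–Wunsch with linear gap scoring (score-maximizing), with
    traceback; quadratic time/memory, used for custom scoring schemes."""
    n, m = len(x), len(y)
    xa = np.frombuffer(x.encode(), dtype=np.uint8)
    ya = np.frombuffer(y.encode(), dtype=np.uint8)
    S = np.empty((n + 1, m + 1), dtype=np.float64)
    jg = np.arange(m + 1) * gap
    S[0, :] = jg
    S[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        sub = np.where(ya == xa[i - 1], match, mismatch)
        diag = S[i - 1, :-1] + sub
        up = S[i - 1, 1:] + gap
        best = np.maximum(diag, up)
        # left-dependency row[j] = max(best[j-1], row[j-1]+gap) resolved by a
        # running max of (value - j*gap)
        u = np.maximum.accumulate(np.concatenate(([i * gap], best - jg[1:])))
        S[i, :] = u + jg
    # traceback
    ops = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + (match if x[i - 1] == y[j - 1] else mismatch):
            ops.append("=" if x[i - 1] == y[j - 1] else "X")
            i, j = i - 1, j - 1
        elif i > 0 and S[i, j] == S[i - 1, j] + gap:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    out = []
    for op, grp in itertools.groupby(ops):
        out.append((op, sum(1 for _ in grp)))
    return out


def align_ltr_pair(seq_x: str, seq_y: str, scores: tuple | None = None):
    """Global alignment of two LTR sequences.

    Returns ``(identity, coverage_x, coverage_y)`` where identity is
    matches over aligned columns and coverage is each sequence's share of
    the alignment after trimming terminal gaps.  The default is unit-cost
    edit-distance alignment (edlib); a ``(match, mismatch, gap)`` triple
    switches to an explicit linear-gap Needleman–Wunsch.
    """
    if not seq_x or not seq_y:
        raise ValueError("empty sequence")
    if scores is None:
        res = edlib.align(seq_x, seq_y, mode="NW", task="path")
        ops = _cigar_ops(res["cigar"])
    else:
        ops = _nw_ops(seq_x, seq_y, *scores)
    return _stats_from_ops(ops, len(seq_x), len(seq_y))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl(W: np.ndarray, inflation: float = 3.0, prune: float = 1e-5,
        tol: float = 1e-6, max_iter: int = 200) -> list[list[int]]:
    """Markov clustering of a symmetric non-negative similarity matrix.

    Self-loops are set to each node's maximum incident edge weight (1 for
    isolated nodes); columns are normalized to stochastic, then expansion
    (matrix square) and inflation (elementwise power, renormalize) alternate
    with sub-``prune`` entries zeroed, until the matrix changes by less than
    ``tol`` or ``max_iter`` is hit (warning on non-convergence).  Clusters
    are read off by grouping columns on their attractor row (argmax).
    """
    n = W.shape[0]
    M = W.astype(np.float64).copy()
    np.fill_diagonal(M, 0.0)
    loops = M.max(axis=0)
    loops[loops <= 0] = 1.0
    M[np.diag_indices(n)] = loops

    def _normalize(A):
        s = A.sum(axis=0)
        s[s == 0] = 1.0
        return A / s

    M = _normalize(M)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M = _normalize(M)
        # prune relative to the renormalized column, never dropping its max
        # (a wide uniform column must survive inflation intact)
        keep_max = M.argmax(axis=0)
        small = M < prune
        small[keep_max, np.arange(n)] = False
        M[small] = 0.0
        M = _normalize(M)
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        log.warning("mcl: not converged after %d iterations; using current matrix", max_iter)
    attractor = M.argmax(axis=0)
    clusters: dict[int, list[int]] = {}
    for j in range(n):
        clusters.setdefault(int(attractor[j]), []).append(j)
    return sorted(clusters.values(), key=lambda c: (-len(c), c[0]))


def build_subfamilies(
    elements: list[LtrElement],
    cfg: LtrAlignConfig | None = None,
    inflation: float = 3.0,
) -> list[LtrSubfamily]:
    """Cluster elements into subfamilies by MCL over the alignment graph.

    Edges connect element pairs whose 5'-LTR alignment reaches
    ``min_identity`` with mutual coverage >= ``min_mutual_coverage``; edge
    weight is the identity.  Elements are processed in lexicographic id
    order so the clustering is reproducible bit-for-bit.
    """
    if not elements:
        raise ValueError("no elements to cluster")
    cfg = cfg or LtrAlignConfig()
    elems = sorted(elements, key=lambda e: e.id)
    n = len(elems)
    W = np.zeros((n, n), dtype=np.float64)
    # distance above this bound cannot reach min_identity (dist/columns >= dist/(lx+ly))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = elems[i].seq5, elems[j].seq5
            if cfg.scores is None:
                # identity = matches/(matches + d) <= min(|x|,|y|)/(min(|x|,|y|) + d),
                # so distances beyond this bound cannot reach min_identity
                mn = min(len(x), len(y))
                kmax = int(mn * (1.0 - cfg.min_identity) / cfg.min_identity)
                res = edlib.align(x, y, mode="NW", task="distance", k=kmax)
                if res["editDistance"] < 0:
                    continue
                res = edlib.align(x, y, mode="NW", task="path")
                ident, cov_x, cov_y = _stats_from_ops(_cigar_ops(res["cigar"]), len(x), len(y))
            else:
                ident, cov_x, cov_y = align_ltr_pair(x, y, cfg.scores)
            if ident >= cfg.min_identity and min(cov_x, cov_y) >= cfg.min_mutual_coverage:
                W[i, j] = W[j, i] = ident
    families = []
    for fi, idxs in enumerate(mcl(W, inflation=inflation)):
        families.append(LtrSubfamily(f"fam{fi:03d}", [elems[i].id for i in idxs]))
    return families


def subfamily_enrichment(
    families: list[LtrSubfamily],
    elements: list[LtrElement],
    assignment,
    min_fold: float = 3.0,
) -> list[LtrSubfamily]:
    """Flag subfamilies fold-enriched in one subgenome by BOTH occurrence and
    bp count (zero denominators count as infinite fold)."""
    by_id = {e.id: e for e in elements}
    for fam in families:
        occ = {"A": 0, "B": 0}
        bp = {"A": 0, "B": 0}
        for mid in fam.members:
            e = by_id[mid]
            side = assignment[e.scaffold]
            occ[side] += 1
            bp[side] += e.length

        def _fold(x, y):
            return np.inf if y == 0 else x / y

        fam.occurrences, fam.bp = occ, bp
        for side, other in (("A", "B"), ("B", "A")):
            if (_fold(occ[side], occ[other]) >= min_fold
                    and _fold(bp[side], bp[other]) >= min_fold
                    and occ[side] > 0):
                fam.enriched, fam.direction = True, side
                break
        else:
            fam.enriched, fam.direction = False, ""
    return families


# ---------------------------------------------------------------------------
# Jukes–Cantor dating
# ---------------------------------------------------------------------------

def jc_distance(p: float) -> float:
    """JC-corrected substitutions per site from a proportion of differing sites."""
    if not (0.0 <= p < 0.75):
        raise ValueError(f"p-distance {p} outside [0, 0.75): Jukes–Cantor saturated")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


DATING_SCORES = (0.0, -1.0, -4.0)   # match, mismatch, gap


def aligned_p_distance(seq_x: str, seq_y: str, scores: tuple = DATING_SCORES) -> float:
    """Proportion of differing sites over gap-free alignment columns.

    Dating uses a gap-penalized global alignment (gap cost well above
    mismatch cost): a minimum-edit-distance path would trade clusters of
    substitutions for spurious indel pairs and bias p — hence every age —
    downward.
    """
    ops = _nw_ops(seq_x, seq_y, *scores)
    matches = sum(n for op, n in ops if op == "=")
    mismatches = sum(n for op, n in ops if op == "X")
    sites = matches + mismatches
    if sites == 0:
        raise ValueError("no gap-free columns")
    return mismatches / sites


def date_family(
    family: LtrSubfamily,
    elements: list[LtrElement],
    mode: str = "within_family_pairs",
    r: float = DEFAULT_RATE,
) -> list[DivergenceEstimate]:
    """Insertion-age distribution of a subfamily, ``t = k / (2r)`` years.

    ``within_family_pairs`` dates every pairwise 5'-LTR comparison inside the
    family; ``five_vs_three_prime`` dates each element by its own two
    terminal repeats.  Saturated comparisons (p >= 0.75) are dropped with a
    reported count.
    """
    by_id = {e.id: e for e in elements}
    members = [by_id[m] for m in family.members]
    estimates = []
    dropped = 0

    def _estimate(p):
        nonlocal dropped
        if p >= 0.75:
            dropped += 1
            return
        k = jc_distance(p)
        estimates.append(DivergenceEstimate(p, k, r, k / (2.0 * r)))

    if mode == "within_family_pairs":
        for ex, ey in itertools.combinations(members, 2):
            _estimate(aligned_p_distance(ex.seq5, ey.seq5))
    elif mode == "five_vs_three_prime":
        for e in members:
            _estimate(aligned_p_distance(e.seq5, e.seq3))
    else:
        raise ValueError(f"unknown dating mode {mode!r}")
    if dropped:
        log.info("date_family %s: %d saturated comparisons dropped", family.family_id, dropped)
    return estimates
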