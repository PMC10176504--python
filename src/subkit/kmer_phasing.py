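"""Diagnostic k-mer discovery and subgenome assignment.

An allopolyploid's two subgenomes carry the relics of repeat families that
were active in only one of the diploid progenitors.  Short k-mers (13-mers by
default) drawn from those repeats are therefore systematically more abundant
on one member of each homoeologous scaffold pair.  This module counts k-mers
(in-memory, canonical by default), selects the ones that are both abundant
genome-wide and fold-enriched within homoeologous pairs — before *and* after
standardizing counts by scaffold length, in the same direction — clusters
scaffolds on the diagnostic count matrix (Euclidean distance, complete
linkage, cut at two clusters) and produces windowed A/B density tracks for
downstream exchange detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import GenomeSet

log = logging.getLogger("subkit")

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _LUT[_c] = _i


@dataclass
class KmerConfig:
    k: int = 13
    min_total_count: int = 100
    min_fold: float = 3.0
    canonical: bool = True

    def __post_init__(self):
        if self.k < 5 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 5")
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")


def encode_kmers(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """Integer codes of all k-mers of ``seq`` (N-containing windows dropped).

    Codes pack bases 2 bits each, first base most significant.  In canonical
    mode each code is the minimum of the k-mer and its reverse complement.
    """
    arr = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    bad = (arr == 4)
    safe = np.where(bad, 0, arr).astype(np.uint64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + m]
        rev |= (np.uint64(3) - safe[j : j + m]) << np.uint64(2 * j)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    codes = np.minimum(fwd, rev) if canonical else fwd
    return codes[valid]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


@dataclass
class KmerCounts:
    """Per-scaffold counts of the k-mers abundant genome-wide."""

    codes: np.ndarray                 # sorted kmer codes, shape (n_kmers,)
    matrix: np.ndarray                # counts, shape (n_kmers, n_scaffolds)
    scaffolds: list[str]
    lengths: dict[str, int]
    cfg: KmerConfig

    def column(self, scaffold: str) -> np.ndarray:
        return self.matrix[:, self.scaffolds.index(scaffold)]


def count_kmers(genome: GenomeSet, cfg: KmerConfig | None = None) -> KmerCounts:
    """Count k-mers per scaffold, keeping those with genome-wide total
    ``>= cfg.min_total_count``.

    Windows containing N contribute nothing; scaffolds shorter than k are
    skipped with a warning.
    """
    cfg = cfg or KmerConfig()
    names = []
    per_scaf = []
    for name, seq in genome.scaffolds.items():
        if len(seq) < cfg.k:
            log.warning("count_kmers: scaffold %s shorter than k=%d, skipped", name, cfg.k)
            continue
        codes = encode_kmers(seq, cfg.k, cfg.canonical)
        uniq, cnt = np.unique(codes, return_counts=True)
        names.append(name)
        per_scaf.append((uniq, cnt))
    if not names:
        raise ValueError("no scaffold long enough to count k-mers")

    all_codes = np.concatenate([u for u, _ in per_scaf])
    all_counts = np.concatenate([c for _, c in per_scaf])
    uniq, inv = np.unique(all_codes, return_inverse=True)
    totals = np.bincount(inv, weights=all_counts.astype(np.float64))
    keep = totals >= cfg.min_total_count
    kept = uniq[keep]

    matrix = np.zeros((kept.size, len(names)), dtype=np.int64)
    for col, (u, c) in enumerate(per_scaf):
        pos = np.searchsorted(kept, u)
        ok = (pos < kept.size)
        ok[ok] &= kept[pos[ok]] == u[ok]
        matrix[pos[ok], col] = c[ok]
    return KmerCounts(kept, matrix, names, {n: genome.lengths[n] for n in names}, cfg)


# ---------------------------------------------------------------------------
# Diagnostic k-mer selection and scaffold clustering
# ---------------------------------------------------------------------------

@dataclass
class SubgenomeAssignment:
    assignment: dict                       # scaffold -> 'A'/'B'
    linkage: np.ndarray | None = None      # scipy linkage matrix
    scaffolds: list[str] = field(default_factory=list)

    def __getitem__(self, scaffold: str) -> str:
        return self.assignment[scaffold]


@dataclass
class DiagnosticKmerSet:
    """Diagnostic k-mers oriented to the two subgenome sides.

    ``a_preferred``/``b_preferred`` are disjoint sets of k-mer strings; the
    A side is by convention the one with more preferred k-mers.
    """

    a_preferred: set
    b_preferred: set
    a_codes: np.ndarray
    b_codes: np.ndarray
    matrix: np.ndarray                  # diagnostic kmers x scaffolds count matrix
    kmer_codes: np.ndarray
    scaffolds: list[str]
    k: int
    assignment: SubgenomeAssignment | None = None


def _fold_pass(cx: np.ndarray, cy: np.ndarray, min_fold: float) -> np.ndarray:
    """True where cx >= min_fold * cy, with a zero denominator counting as
    infinite fold (provided the numerator is positive)."""
    return (cx >= min_fold * cy) & (cx > 0)


def pair_direction(counts: KmerCounts, sx: str, sy: str, min_fold: float) -> np.ndarray:
    """Per-k-mer diagnostic direction for one homoeologous pair:
    +1 enriched toward ``sx``, -1 toward ``sy``, 0 not diagnostic.

    A k-mer is diagnostic only if the raw-count fold and the per-Mb
    length-standardized fold both reach ``min_fold`` in the same direction.
    """
    cx = counts.column(sx).astype(np.float64)
    cy = counts.column(sy).astype(np.float64)
    mx = cx / (counts.lengths[sx] / 1e6)
    my = cy / (counts.lengths[sy] / 1e6)
    up = _fold_pass(cx, cy, min_fold) & _fold_pass(mx, my, min_fold)
    dn = _fold_pass(cy, cx, min_fold) & _fold_pass(my, mx, min_fold)
    return up.astype(np.int8) - dn.astype(np.int8)


def cluster_subgenomes(
    matrix: np.ndarray,
    scaffolds: list[str],
    lengths: dict[str, int],
    pairs: list,
    method: str = "complete",
) -> SubgenomeAssignment:
    """Agglomerative clustering of scaffolds on length-standardized diagnostic
    k-mer counts (Euclidean, complete linkage by default), cut at 2 clusters.

    Labels are provisional ('A' = first cluster by sorted scaffold name);
    callers with k-mer orientation information relabel by preferred-k-mer
    mass.  Raises if any homoeologous pair lands inside one cluster.
    """
    if matrix.shape[0] == 0:
        raise ValueError("diagnostic k-mer matrix is empty; clustering impossible")
    if len(pairs) < 2:
        raise ValueError("need at least 2 homoeologous pairs to define subgenomes")
    order = np.argsort(scaffolds)
    names = [scaffolds[i] for i in order]
    X = matrix[:, order].T.astype(np.float64)
    X /= np.array([lengths[n] / 1e6 for n in names])[:, None]
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("diagnostic count matrix carries no signal (all columns constant)")
    Z = linkage(X, method=method, metric="euclidean")
    labels = fcluster(Z, t=2, criterion="maxclust")
    lab = {n: int(l) for n, l in zip(names, labels)}

    def _pair_names(p):
        return (p.scaffold_x, p.scaffold_y) if hasattr(p, "scaffold_x") else tuple(p)

    offenders = [p for p in pairs
                 if lab[_pair_names(p)[0]] == lab[_pair_names(p)[1]]]
    if offenders:
        raise ValueError(
            "clustering does not separate homoeologous pairs: "
            + ", ".join(str(_pair_names(p)) for p in offenders)
        )
    first = lab[names[0]]
    assignment = {n: ("A" if l == first else "B") for n, l in lab.items()}
    return SubgenomeAssignment(assignment, Z, names)


def select_diagnostic_kmers(
    counts: KmerCounts,
    pairs: list,
    cfg: KmerConfig | None = None,
) -> DiagnosticKmerSet:
    """Select pair-diagnostic k-mers, cluster scaffolds and orient the sides.

    A k-mer enters the diagnostic set if it is diagnostic (raw and
    standardized fold >= ``min_fold``, same direction) in at least one pair.
    Scaffolds are clustered on the diagnostic matrix; each k-mer is then
    assigned to the side holding the majority of the scaffolds it points to,
    k-mers with no majority are dropped, and the side with more preferred
    k-mers is named A.
    """
    cfg = cfg or counts.cfg

    def _pair_names(p):
        return (p.scaffold_x, p.scaffold_y) if hasattr(p, "scaffold_x") else tuple(p)

    dirs = {}
    for p in pairs:
        sx, sy = _pair_names(p)
        dirs[(sx, sy)] = pair_direction(counts, sx, sy, cfg.min_fold)
    any_diag = np.zeros(counts.codes.size, dtype=bool)
    for d in dirs.values():
        any_diag |= d != 0
    if not any_diag.any():
        raise ValueError("zero diagnostic k-mers; check min_fold / min_total_count")

    sub_codes = counts.codes[any_diag]
    sub_matrix = counts.matrix[any_diag, :]
    assignment = cluster_subgenomes(
        sub_matrix, counts.scaffolds, counts.lengths, [_pair_names(p) for p in pairs]
    )

    # Majority vote of the provisional cluster labels each k-mer points to.
    votes_first = np.zeros(sub_codes.size, dtype=np.int32)
    votes_second = np.zeros(sub_codes.size, dtype=np.int32)
    for (sx, sy), d in dirs.items():
        dd = d[any_diag]
        toward_x = dd == 1
        toward_y = dd == -1
        if assignment[sx] == "A":
            votes_first += toward_x
            votes_second += toward_y
        else:
            votes_first += toward_y
            votes_second += toward_x
    side_first = votes_first > votes_second
    side_second = votes_second > votes_first
    dropped = int(np.sum(~side_first & ~side_second))
    if dropped:
        log.info("select_diagnostic_kmers: %d k-mers dropped (conflicting directions)", dropped)

    n_first, n_second = int(side_first.sum()), int(side_second.sum())
    if n_first == 0 and n_second == 0:
        raise ValueError("all diagnostic k-mers conflicted across pairs")
    # The side with more preferred k-mers is A.
    if n_first >= n_second:
        a_mask, b_mask = side_first, side_second
        final = dict(assignment.assignment)
    else:
        a_mask, b_mask = side_second, side_first
        final = {s: ("A" if g == "B" else "B") for s, g in assignment.assignment.items()}
    assignment = SubgenomeAssignment(final, assignment.linkage, assignment.scaffolds)

    keep = a_mask | b_mask
    a_codes = sub_codes[a_mask]
    b_codes = sub_codes[b_mask]
    return DiagnosticKmerSet(
        a_preferred={decode_kmer(int(c), cfg.k) for c in a_codes},
        b_preferred={decode_kmer(int(c), cfg.k) for c in b_codes},
        a_codes=a_codes,
        b_codes=b_codes,
        matrix=sub_matrix[keep, :],
        kmer_codes=sub_codes[keep],
        scaffolds=list(counts.scaffolds),
        k=cfg.k,
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# Density tracks
# ---------------------------------------------------------------------------

@dataclass
class DensityTrack:
    scaffold: str
    window: int
    starts: np.ndarray
    ends: np.ndarray            # last window may be partial; true end recorded
    a_counts: np.ndarray
    b_counts: np.ndarray

    def __len__(self) -> int:
        return self.starts.size


def density_track(
    genome: GenomeSet,
    scaffold: str,
    kmers: DiagnosticKmerSet,
    window: int = 1_000_000,
    canonical: bool = True,
) -> DensityTrack:
    """Exact per-window occurrence counts of the A- and B-preferred k-mers.

    The final partial window is kept with its true length.  A k-mer hit is
    attributed to the window containing its leftmost base.
    """
    seq = genome[scaffold]
    L = len(seq)
    n_win = max(1, -(-L // window))
    codes = encode_kmers(seq, kmers.k, canonical)
    # positions of valid windows (encode_kmers drops N windows, so recompute)
    arr = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    bad = (arr == 4)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    m = L - kmers.k + 1
    pos = np.nonzero((cbad[kmers.k:] - cbad[:-kmers.k]) == 0)[0] if m > 0 else np.empty(0, int)

    a_counts = np.zeros(n_win, dtype=np.int64)
    b_counts = np.zeros(n_win, dtype=np.int64)
    if codes.size:
        win_idx = pos // window
        in_a = np.isin(codes, kmers.a_codes)
        in_b = np.isin(codes, kmers.b_codes)
        np.add.at(a_counts, win_idx[in_a], 1)
        np.add.at(b_counts, win_idx[in_b], 1)
    starts = np.arange(n_win, dtype=np.int64) * window
    ends = np.minimum(starts + window, L)
    return DensityTrack(scaffold, window, starts, ends, a_counts, b_counts)
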