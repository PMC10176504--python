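"""TE density in fixed windows flanking genes, and rank-based group comparison.

TE density of a window is the number of TE-occupied base pairs (union of TE
intervals — the only definition bounded by 1) divided by the window size.
Windows flank each gene upstream/downstream of its strand (5 kb by default);
windows truncated by a scaffold end are renormalized to the truncated length
and flagged (or dropped, by option).  Group differences (subgenome A vs B,
single-copy vs duplicated genes) are tested with a Mann–Whitney U test:
exact enumeration for small tie-free samples, tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core_io import Feature

log = logging.getLogger("subkit")


@dataclass
class TeDensityRecord:
    gene_id: str
    upstream_density: float
    downstream_density: float
    window: int
    truncated_up: bool = False
    truncated_down: bool = False


# ---------------------------------------------------------------------------
# Flank density
# ---------------------------------------------------------------------------

def _merge_intervals(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def _occupied(merged, start, end) -> int:
    total = 0
    for s, e in merged:
        if s >= end:
            break
        if e > start:
            total += min(e, end) - max(s, start)
    return total


def flank_density(
    genes: list[Feature],
    tes: list[Feature],
    window: int = 5_000,
    lengths: dict | None = None,
    orientation_aware: bool = True,
    truncation: str = "renormalize",
) -> list[TeDensityRecord]:
    """TE density upstream/downstream of each gene.

    Upstream/downstream follow gene strand when ``orientation_aware`` (a '-'
    gene's upstream window sits to its right).  Windows are clipped at
    position 0 and, when ``lengths`` is given, at the scaffold end;
    ``truncation='renormalize'`` divides by the clipped length (flagged),
    ``'drop'`` reports NaN for that side.  Genes on scaffolds absent from
    ``lengths`` are skipped with a warning.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if truncation not in ("renormalize", "drop"):
        raise ValueError(f"unknown truncation mode {truncation!r}")
    te_by_scaf: dict[str, list] = {}
    for t in tes:
        te_by_scaf.setdefault(t.scaffold, []).append((t.start, t.end))
    merged = {s: _merge_intervals(iv) for s, iv in te_by_scaf.items()}

    records = []
    for g in genes:
        if lengths is not None and g.scaffold not in lengths:
            log.warning("flank_density: gene %s on unknown scaffold %s, skipped", g.id, g.scaffold)
            continue
        L = lengths[g.scaffold] if lengths is not None else None
        left = (g.start - window, g.start)
        right = (g.end, g.end + window)
        if orientation_aware and g.strand == "-":
            up, down = right, left
        else:
            up, down = left, right
        m = merged.get(g.scaffold, [])
        out = {}
        flags = {}
        for side, (s, e) in (("up", up), ("down", down)):
            cs = max(s, 0)
            ce = min(e, L) if L is not None else e
            truncated = (cs, ce) != (s, e)
            if ce <= cs or (truncated and truncation == "drop"):
                out[side], flags[side] = float("nan"), truncated
                continue
            out[side] = _occupied(m, cs, ce) / (ce - cs)
            flags[side] = truncated
        records.append(
            TeDensityRecord(g.id, out["up"], out["down"], window, flags["up"], flags["down"])
        )
    return records


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns ``(U, p)`` with U counted for x.

    ``exact``: full enumeration of rank assignments (requires
    ``len(x)+len(y) <= 12`` and no ties).  ``normal``: tie-corrected normal
    approximation with continuity correction.  ``auto`` picks exact when
    admissible.  Identical pooled samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return nx * ny / 2.0, 1.0

    ranks = rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    if mode == "auto":
        mode = "exact" if (nx + ny <= 12 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties or nx + ny > 12:
            raise ValueError("exact mode requires tie-free samples with nx+ny <= 12")
        n = nx + ny
        all_ranks = np.arange(1, n + 1)
        lo_u = min(u_x, nx * ny - u_x)
        hi_u = max(u_x, nx * ny - u_x)
        count = 0
        total = 0
        base = nx * (nx + 1) / 2.0
        for combo in itertools.combinations(range(n), nx):
            u = all_ranks[list(combo)].sum() - base
            total += 1
            if u <= lo_u or u >= hi_u:
                count += 1
        return u_x, count / total
    if mode == "normal":
        n = nx + ny
        mu = nx * ny / 2.0
        _, t = np.unique(pooled, return_counts=True)
        tie_term = np.sum(t**3 - t) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return u_x, 1.0
        z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
        return u_x, min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Group comparison report
# ---------------------------------------------------------------------------

def compare_groups(
    records: list[TeDensityRecord],
    labels: dict,
    side: str = "upstream",
) -> pd.DataFrame:
    """Mean ± SE of TE density per group plus a Mann–Whitney comparison.

    ``labels`` maps gene id -> group name; exactly two groups must be
    present among the labeled records.  Returns a table with one row per
    group (mean, se, n) carrying the shared U and two-sided p.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"unknown side {side!r}")
    attr = f"{side}_density"
    groups: dict[str, list] = {}
    for r in records:
        g = labels.get(r.gene_id)
        v = getattr(r, attr)
        if g is not None and not math.isnan(v):
            groups.setdefault(g, []).append(v)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(groups)}")
    (ga, va), (gb, vb) = sorted(groups.items())
    u, p = mann_whitney_u(va, vb, mode="normal")
    rows = []
    for name, vals in ((ga, va), (gb, vb)):
        arr = np.asarray(vals)
        rows.append(
            {
                "group": name,
                "n": arr.size,
                "mean": float(arr.mean()),
                "se": float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan"),
                "side": side,
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
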