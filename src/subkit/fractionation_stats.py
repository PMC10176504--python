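"""Ancestral-gene retention accounting, retention-bias exact test, and GO
term over-representation.

After allopolyploidy, duplicated genes are progressively lost
(fractionation); loss is *biased* when one subgenome loses more.  The
accounting unit is the ancestral (preduplication) gene: a reference-diploid
gene with at least one surviving copy across the two subgenomes.  The bias
test is a two-sided Fisher's exact test on retained-versus-lost counts per
subgenome, where "lost from A" means the gene survives only in B (genes
lost from both subgenomes are unobservable and excluded by construction).
GO enrichment is a per-term one-sided Fisher test of a foreground gene set
against the remaining universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger("subkit")


@dataclass
class RetentionTable:
    """Ancestral-gene accounting per subgenome."""

    n_ancestral: int
    retained_A: int
    retained_B: int
    retained_both: int

    @property
    def pct_A(self) -> float:
        return 100.0 * self.retained_A / self.n_ancestral

    @property
    def pct_B(self) -> float:
        return 100.0 * self.retained_B / self.n_ancestral

    @property
    def pct_both(self) -> float:
        return 100.0 * self.retained_both / self.n_ancestral

    @classmethod
    def from_counts(cls, n_ancestral, retained_A, retained_B, retained_both):
        """Build from externally tabulated counts (e.g., a published table).

        Counts violating inclusion–exclusion (A + B - both != n_ancestral)
        are accepted with a warning — published ancestral-gene columns are
        often filtered by extra criteria — but basic consistency is enforced.
        """
        if min(n_ancestral, retained_A, retained_B, retained_both) < 0:
            raise ValueError("counts must be non-negative")
        if retained_both > min(retained_A, retained_B):
            raise ValueError("retained_both exceeds a single-subgenome count")
        if retained_A + retained_B - retained_both != n_ancestral:
            log.warning(
                "RetentionTable: union of retained sets (%d) != stated ancestral count (%d)",
                retained_A + retained_B - retained_both, n_ancestral,
            )
        return cls(n_ancestral, retained_A, retained_B, retained_both)


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def tally_retention(table: pd.DataFrame) -> RetentionTable:
    """Retention accounting from an ortholog table.

    ``table`` has columns ``ref_gene``, ``A_gene``, ``B_gene`` with '-'
    marking an absent copy.  The ancestral universe is the rows with at
    least one surviving copy.  Percentages are exact; rounding happens only
    at display.
    """
    if table.empty:
        raise ValueError("empty ortholog table")
    if table["ref_gene"].duplicated().any():
        raise ValueError("duplicated reference gene ids in ortholog table")
    has_a = table["A_gene"] != "-"
    has_b = table["B_gene"] != "-"
    present = has_a | has_b
    n = int(present.sum())
    if n == 0:
        raise ValueError("no ancestral genes with surviving copies")
    return RetentionTable(n, int(has_a.sum()), int(has_b.sum()), int((has_a & has_b).sum()))


def retention_contingency(rt: RetentionTable) -> ContingencyTable2x2:
    """Retained-vs-lost 2x2 per subgenome.

    A gene is lost from A iff it survives only in B (and vice versa), so the
    margins are built from the union of observed genes — the only ancestral
    set that is actually observable.
    """
    lost_a = rt.retained_B - rt.retained_both
    lost_b = rt.retained_A - rt.retained_both
    return ContingencyTable2x2(rt.retained_A, lost_a, rt.retained_B, lost_b)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(t: ContingencyTable2x2, sided: str = "two") -> float:
    """Fisher's exact p-value for a 2x2 table, computed in log space.

    Point probabilities come from the hypergeometric distribution over all
    tables with the observed margins; the two-sided p is the sum of point
    probabilities no larger than the observed one (within relative tolerance
    1e-7), the convention of standard statistical environments.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    N = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - N)
    hi = min(row1, col1)
    if lo == hi:
        return 1.0
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, N, col1, row1)
    obs = logpmf[a - lo]
    if sided == "two":
        keep = logpmf <= obs + np.log1p(1e-7)
    elif sided == "greater":
        keep = support >= a
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    if keep.all():
        return 1.0
    # log-sum-exp over the kept tables
    m = logpmf[keep].max()
    p = float(np.exp(m) * np.sum(np.exp(logpmf[keep] - m)))
    return min(p, 1.0)


def retention_bias_test(rt: RetentionTable) -> float:
    """Two-sided Fisher's exact test of random gene loss between subgenomes."""
    return fisher_exact_2x2(retention_contingency(rt), sided="two")


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def go_enrichment(
    foreground: set,
    universe: set,
    term_map: dict,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-term one-sided Fisher over-representation of ``foreground`` genes.

    ``term_map`` maps gene id -> set of term ids (with any ancestor-term
    closure already applied by the caller).  For each term:
    ``annotated`` = universe genes carrying it, ``significant`` = foreground
    genes carrying it, ``expected = annotated * |foreground| / |universe|``.
    Raw Fisher p-values by default (no multiple-testing correction); set
    ``bh=True`` for an extra Benjamini–Hochberg column.
    """
    foreground = set(foreground)
    universe = set(universe)
    if not foreground <= universe:
        raise ValueError("foreground must be a subset of the universe")
    n_fg, n_uni = len(foreground), len(universe)
    ann: dict[str, int] = {}
    sig: dict[str, int] = {}
    for gene in universe:
        for term in term_map.get(gene, ()):
            ann[term] = ann.get(term, 0) + 1
            if gene in foreground:
                sig[term] = sig.get(term, 0) + 1
    rows = []
    for term, annotated in ann.items():
        significant = sig.get(term, 0)
        expected = annotated * n_fg / n_uni
        p = float(hypergeom.sf(significant - 1, n_uni, annotated, n_fg))
        rows.append((term, annotated, significant, expected, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "annotated", "significant", "expected", "p"])
    df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    if bh:
        m = len(df)
        ranked = df["p"].to_numpy() * m / (np.arange(m) + 1)
        df["p_bh"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    return df


def retention_gene_sets(table: pd.DataFrame) -> dict:
    """Foreground/background splits for enrichment: single-copy genes
    (retained in exactly one subgenome) and duplicated genes (both), each
    against the remaining ancestral genes as background."""
    has_a = table["A_gene"] != "-"
    has_b = table["B_gene"] != "-"
    present = has_a | has_b
    universe = set(table.loc[present, "ref_gene"])
    single = set(table.loc[has_a ^ has_b, "ref_gene"])
    dup = set(table.loc[has_a & has_b, "ref_gene"])
    return {"universe": universe, "single_copy": single, "duplicated": dup}


def exclude_genes_in_regions(
    table: pd.DataFrame,
    gene_features: list,
    regions: list,
) -> pd.DataFrame:
    """Drop ortholog-table rows whose surviving copies overlap any of the
    given regions (ambiguously assigned scaffold stretches)."""
    drop: set[str] = set()
    feats = {f.id: f for f in gene_features}
    for _, row in table.iterrows():
        for col in ("A_gene", "B_gene"):
            gid = row[col]
            f = feats.get(gid)
            if f is None:
                continue
            for r in regions:
                if f.scaffold == r.scaffold and f.start < r.end and r.start < f.end:
                    drop.add(row["ref_gene"])
    return table[~table["ref_gene"].isin(drop)].reset_index(drop=True)
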