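"""Pairwise alignment (vs a textbook DP oracle), Markov clustering,
subgenome enrichment and Jukes–Cantor insertion dating."""

import numpy as np
import pytest

from subkit import (
    LtrAlignConfig,
    LtrElement,
    LtrSubfamily,
    align_ltr_pair,
    build_subfamilies,
    date_family,
    elements_from_features,
    jc_distance,
    mcl,
    subfamily_enrichment,
)
from subkit.ltr_dynamics import _nw_ops, aligned_p_distance


def textbook_nw_score(x, y, match, mismatch, gap):
    """Plain quadratic-time Needleman–Wunsch, no vectorization (oracle)."""
    n, m = len(x), len(y)
    S = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = i * gap
    for j in range(1, m + 1):
        S[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if x[i - 1] == y[j - 1] else mismatch
            S[i][j] = max(S[i - 1][j - 1] + sub, S[i - 1][j] + gap, S[i][j - 1] + gap)
    return S[n][m]


def _ops_score(ops, match, mismatch, gap):
    return sum(
        n * {"=": match, "X": mismatch, "I": gap, "D": gap}[op] for op, n in ops
    )


class TestAlignment:
    def test_identical_sequences(self):
        ident, cx, cy = align_ltr_pair("A" * 300, "A" * 300)
        assert (ident, cx, cy) == (1.0, 1.0, 1.0)

    def test_single_substitution(self):
        x = "ACGT" * 75
        y = x[:100] + ("A" if x[100] != "A" else "C") + x[101:]
        ident, _, _ = align_ltr_pair(x, y)
        assert ident == pytest.approx(299 / 300)

    @pytest.mark.parametrize("seed", range(10))
    def test_scores_match_textbook_dp(self, seed):
        rng = np.random.default_rng(seed)
        scores = (2.0, -1.0, -2.0)
        for _ in range(5):
            lx, ly = rng.integers(20, 200, size=2)
            x = "".join(rng.choice(list("ACGT"), size=lx))
            y = "".join(rng.choice(list("ACGT"), size=ly))
            ops = _nw_ops(x, y, *scores)
            assert _ops_score(ops, *scores) == pytest.approx(
                textbook_nw_score(x, y, *scores)
            )

    def test_unit_cost_path_matches_textbook_distance(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            x = "".join(rng.choice(list("ACGT"), size=120))
            y = "".join(rng.choice(list("ACGT"), size=110))
            ops = _nw_ops(x, y, 0.0, -1.0, -1.0)
            dist = sum(n for op, n in ops if op in "XID")
            assert dist == -textbook_nw_score(x, y, 0.0, -1.0, -1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_ltr_pair("", "ACGT")


class TestMcl:
    def _clique_graph(self, sizes, bridge=None):
        n = sum(sizes)
        W = np.zeros((n, n))
        off = 0
        groups = []
        for s in sizes:
            idx = list(range(off, off + s))
            groups.append(idx)
            for i in idx:
                for j in idx:
                    if i != j:
                        W[i, j] = 1.0
            off += s
        if bridge:
            i, j, w = bridge
            W[i, j] = W[j, i] = w
        return W, groups

    def test_disconnected_components_are_separate_clusters(self):
        W, groups = self._clique_graph([4, 3])
        clusters = mcl(W)
        assert sorted(map(sorted, clusters)) == sorted(map(sorted, groups))

    def test_singleton(self):
        assert mcl(np.zeros((1, 1))) == [[0]]

    def test_barbell_splits_at_weak_bridge(self):
        W, groups = self._clique_graph([4, 4], bridge=(3, 4, 0.1))
        clusters = mcl(W)
        assert sorted(map(sorted, clusters)) == sorted(map(sorted, groups))

    def test_barbell_matches_direct_iteration(self):
        """Independent replication of the expansion/inflation recurrence."""
        W, _ = self._clique_graph([4, 4], bridge=(3, 4, 0.1))
        n = 8
        M = W.copy()
        np.fill_diagonal(M, M.max(axis=0))
        M = M / M.sum(axis=0)
        for _ in range(50):
            M = M @ M
            M = M**3.0
            M = M / M.sum(axis=0)
            keep = M.argmax(axis=0)
            small = M < 1e-5
            small[keep, np.arange(n)] = False
            M[small] = 0.0
            M = M / M.sum(axis=0)
        attract = M.argmax(axis=0)
        direct = {}
        for j in range(n):
            direct.setdefault(int(attract[j]), []).append(j)
        assert sorted(map(sorted, mcl(W))) == sorted(map(sorted, direct.values()))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_output_partitions_nodes_within_components(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        W = np.triu((rng.random((n, n)) < 0.15) * rng.random((n, n)), 1)
        W = W + W.T
        clusters = mcl(W)
        flat = sorted(i for c in clusters for i in c)
        assert flat == list(range(n))
        # clusters refine connected components
        import networkx as nx
        g = nx.from_numpy_array(W)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        for c in clusters:
            assert len({comp_of[i] for i in c}) == 1


def _element(eid, scaffold, length=1000, ltr=100):
    return LtrElement(eid, scaffold, 0, length, (0, ltr), (length - ltr, length))


class TestEnrichment:
    def test_both_metrics_pass(self):
        elems = [_element(f"a{i}", "sA", length=1000) for i in range(9)] + [
            _element("b0", "sB", length=1450), _element("b1", "sB", length=1450)
        ]
        fam = LtrSubfamily("f0", [e.id for e in elems])
        asg = {"sA": "A", "sB": "B"}
        (out,) = subfamily_enrichment([fam], elems, asg)
        # occurrence fold 4.5, bp fold 9000/2900 = 3.1 -> enriched toward A
        assert out.enriched and out.direction == "A"

    def test_bp_fold_vetoes(self):
        elems = [_element(f"a{i}", "sA", length=1000) for i in range(9)] + [
            _element("b0", "sB", length=2000), _element("b1", "sB", length=2000)
        ]
        fam = LtrSubfamily("f0", [e.id for e in elems])
        (out,) = subfamily_enrichment([fam], elems, {"sA": "A", "sB": "B"})
        assert not out.enriched  # bp fold 9000/4000 = 2.25

    def test_zero_denominator_counts_as_infinite(self):
        elems = [_element(f"a{i}", "sA") for i in range(3)]
        fam = LtrSubfamily("f0", [e.id for e in elems])
        (out,) = subfamily_enrichment([fam], elems, {"sA": "A"})
        assert out.enriched and out.direction == "A"


class TestJukesCantor:
    def test_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_distance(0.05) == pytest.approx(0.0517442, abs=1e-6)

    def test_saturation_boundary(self):
        with pytest.raises(ValueError):
            jc_distance(0.75)

    def test_monotone_and_above_identity(self):
        ps = np.linspace(0.01, 0.70, 30)
        ks = np.array([jc_distance(p) for p in ps])
        assert (np.diff(ks) > 0).all()
        assert (ks >= ps).all()


class TestDating:
    def test_worked_example_six_million_years(self):
        # k = 0.156 at r = 1.3e-8 -> 6.0 Myr
        k = 0.156
        assert k / (2 * 1.3e-8) == pytest.approx(6.0e6, rel=1e-3)

    def test_identical_ltr_pair_age_zero(self):
        e = LtrElement("e0", "s", 0, 1000, (0, 100), (900, 1000),
                       seq5="ACGT" * 25, seq3="ACGT" * 25)
        fam = LtrSubfamily("f0", ["e0"])
        (est,) = date_family(fam, [e], mode="five_vs_three_prime")
        assert est.t == 0.0

    def test_doubling_rate_halves_ages(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        mut = list(seq)
        for i in rng.choice(300, size=20, replace=False):
            mut[i] = "ACGT"[("ACGT".index(mut[i]) + 1) % 4]
        e = LtrElement("e0", "s", 0, 1600, (0, 300), (1300, 1600),
                       seq5=seq, seq3="".join(mut))
        fam = LtrSubfamily("f0", ["e0"])
        (t1,) = date_family(fam, [e], mode="five_vs_three_prime", r=1.3e-8)
        (t2,) = date_family(fam, [e], mode="five_vs_three_prime", r=2.6e-8)
        assert t1.t == pytest.approx(2 * t2.t)

    def test_within_family_pairs_counts(self):
        seqs = ["ACGT" * 25, "ACGT" * 25, "ACGT" * 25]
        elems = [
            LtrElement(f"e{i}", "s", 0, 1000, (0, 100), (900, 1000), seq5=s, seq3=s)
            for i, s in enumerate(seqs)
        ]
        fam = LtrSubfamily("f0", [e.id for e in elems])
        ests = date_family(fam, elems, mode="within_family_pairs")
        assert len(ests) == 3  # C(3,2) pairwise comparisons

    def test_gap_columns_excluded_from_p(self):
        x = "ACGTACGTAC"
        y = "ACGTCGTAC"   # one deletion, no substitutions
        assert aligned_p_distance(x, y) == 0.0


@pytest.fixture(scope="module")
def clustered(small_sim):
    tetra, feats, _o, truth = small_sim
    elems = elements_from_features(feats, tetra)
    fams = build_subfamilies(elems)
    return elems, fams, truth


class TestSimulatedRecovery:
    def test_families_match_truth_partition(self, clustered):
        elems, fams, truth = clustered
        for fam in fams:
            true_ids = {truth.ltr_family_truth.get(m.replace("_hx", "")) for m in fam.members}
            assert len(true_ids) == 1

    def test_enrichment_split_recovered(self, clustered, small_sim):
        elems, fams, truth = clustered
        _t, _f, _o, tr = small_sim
        fams = subfamily_enrichment(fams, elems, tr.subgenome_of)
        directions = sorted(f.direction for f in fams if f.enriched)
        assert directions == ["A"] * 8 + ["B"]

    def test_burst_age_recovered_within_15_percent(self, clustered):
        elems, fams, truth = clustered
        ests = [
            e for f in fams for e in date_family(f, elems, mode="five_vs_three_prime")
        ]
        assert len(ests) >= 200
        ages = np.array([e.t for e in ests])
        assert abs(ages.mean() - 3.5e6) / 3.5e6 < 0.15
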