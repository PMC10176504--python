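"""Shared fixtures: small ground-truthed simulations and derived pipeline state.

The small-scale simulation (4 homoeologous pairs of 500-kb scaffolds) keeps
the full pipeline under a few seconds while preserving every signal the
desk-scale configuration has; the k-mer abundance floor is scaled down with
it (fewer scaffolds carry proportionally fewer repeat copies).
"""

from __future__ import annotations

import numpy as np
import pytest

from subkit import (
    KmerConfig,
    SimConfig,
    count_kmers,
    density_track,
    pair_homoeologs,
    select_diagnostic_kmers,
    simulate,
)
from subkit.synthetic_genome import truth_paf

SMALL_WINDOW = 50_000
SMALL_KMER_CFG = dict(min_total_count=20)


def small_config(seed: int = 1, exchange: bool = True) -> SimConfig:
    cfg = SimConfig(n_pairs=4, chrom_len=500_000, seed=seed)
    if exchange:
        cfg.exchange_spec = [("A", 1, 250_000, 450_000)]
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    """(tetraploid, features, ortholog_table, truth) with one planted exchange."""
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_sim_no_exchange():
    return simulate(small_config(exchange=False))


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Phased small simulation: pairs, k-mer counts, diagnostic set, tracks."""
    tetra, feats, orth, truth = small_sim
    pairs = pair_homoeologs(truth_paf(tetra, truth))
    kcfg = KmerConfig(**SMALL_KMER_CFG)
    counts = count_kmers(tetra, kcfg)
    kset = select_diagnostic_kmers(counts, pairs, kcfg)
    tracks = {
        s: density_track(tetra, s, kset, SMALL_WINDOW) for s in tetra.names()
    }
    return {
        "pairs": pairs,
        "counts": counts,
        "kset": kset,
        "assignment": kset.assignment,
        "tracks": tracks,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
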