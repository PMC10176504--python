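"""Two-state HMM over windowed majority k-mer symbols: homoeologous exchange.

Each scaffold is reduced to a sequence of window symbols — ``a`` where
A-preferred diagnostic k-mers outnumber B-preferred ones, ``b`` for the
reverse, ``missing`` on ties or empty windows.  A two-state HMM (hidden
states = true subgenome origin of the window) with equal start probabilities
and a small switch probability (0.01) is decoded by Viterbi; maximal runs
decoded against the scaffold's assigned subgenome are called as exchange
segments.  Emission probabilities can be re-estimated by Viterbi training on
scaffolds believed exchange-free; start and transition probabilities stay
fixed.

Missing windows are skipped as evidence (emission factor 1) rather than
modeled as a third symbol: the transition chain is kept, so short gaps in
k-mer coverage neither break nor create segments.  Viterbi ties are broken
toward staying in the previous state, favoring fewer segments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import Feature
from .kmer_phasing import DensityTrack, SubgenomeAssignment

log = logging.getLogger("subkit")

STATES = ("A", "B")
SYMBOLS = ("a", "b")
MISSING = "missing"


@dataclass
class HmmModel:
    start: dict = field(default_factory=lambda: {"A": 0.5, "B": 0.5})
    switch: float = 0.01
    emission: dict = field(
        default_factory=lambda: {"A": {"a": 0.9, "b": 0.1}, "B": {"a": 0.1, "b": 0.9}}
    )

    def __post_init__(self):
        if abs(sum(self.start.values()) - 1.0) > 1e-9:
            raise ValueError("start probabilities must sum to 1")
        if not (0.0 <= self.switch <= 1.0):
            raise ValueError("switch probability must lie in [0, 1]")
        for s in STATES:
            if abs(sum(self.emission[s].values()) - 1.0) > 1e-9:
                raise ValueError(f"emission row for state {s} must sum to 1")

    def trans(self, s_from: str, s_to: str) -> float:
        return 1.0 - self.switch if s_from == s_to else self.switch


@dataclass
class SymbolSequence:
    scaffold: str
    symbols: list
    window: int

    def __post_init__(self):
        bad = set(self.symbols) - {"a", "b", MISSING}
        if bad:
            raise ValueError(f"unknown symbols: {bad}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class ExchangeCall:
    scaffold: str
    segments: list                 # Feature(kind=exchange_segment)
    path: list                     # decoded state per window
    assigned: str


def majority_symbols(track: DensityTrack) -> SymbolSequence:
    """``a`` if A-hits exceed B-hits in the window, ``b`` for the reverse,
    ``missing`` on ties (including the all-zero window)."""
    syms = []
    for a, b in zip(track.a_counts, track.b_counts):
        if a > b:
            syms.append("a")
        elif b > a:
            syms.append("b")
        else:
            syms.append(MISSING)
    return SymbolSequence(track.scaffold, syms, track.window)


# ---------------------------------------------------------------------------
# Viterbi decode
# ---------------------------------------------------------------------------

def _log(p: float) -> float:
    return math.log(p) if p > 0 else -math.inf


def viterbi(model: HmmModel, obs: SymbolSequence) -> tuple[list, float]:
    """Maximum-probability state path in log space.

    Missing symbols contribute emission factor 1 (evidence skipped, the
    transition chain retained).  Ties prefer staying in the previous state;
    an all-missing sequence decodes to the first state under the uniform
    prior, with a warning.
    """
    n = len(obs)
    if n == 0:
        raise ValueError("empty symbol sequence")
    if all(s == MISSING for s in obs.symbols):
        log.warning("viterbi: all windows missing on %s; path is the prior argmax", obs.scaffold)

    def emit(state: str, sym: str) -> float:
        return 0.0 if sym == MISSING else _log(model.emission[state][sym])

    delta = {s: _log(model.start[s]) + emit(s, obs.symbols[0]) for s in STATES}
    back: list[dict] = []
    for t in range(1, n):
        sym = obs.symbols[t]
        new = {}
        ptr = {}
        for s in STATES:
            # evaluate the sticky (stay) predecessor first so ties keep it
            cands = [s] + [x for x in STATES if x != s]
            best_prev, best_val = None, -math.inf
            for prev in cands:
                v = delta[prev] + _log(model.trans(prev, s))
                if v > best_val:
                    best_prev, best_val = prev, v
            new[s] = best_val + emit(s, sym)
            ptr[s] = best_prev
        delta = new
        back.append(ptr)

    last = max(STATES, key=lambda s: (delta[s], s == STATES[0]))
    logp = delta[last]
    path = [last]
    for ptr in reversed(back):
        path.append(ptr[path[-1]])
    path.reverse()
    return path, logp


def path_loglik(model: HmmModel, obs: SymbolSequence, path: list) -> float:
    lp = _log(model.start[path[0]])
    for t, (state, sym) in enumerate(zip(path, obs.symbols)):
        if t > 0:
            lp += _log(model.trans(path[t - 1], state))
        if sym != MISSING:
            lp += _log(model.emission[state][sym])
    return lp


# ---------------------------------------------------------------------------
# Viterbi training (emissions only)
# ---------------------------------------------------------------------------

def viterbi_train(
    model: HmmModel,
    training_obs: list[SymbolSequence],
    max_iter: int = 100,
    tol: float = 1e-4,
) -> HmmModel:
    """Re-estimate emission probabilities by iterated Viterbi decoding.

    Decode with the current model, re-estimate per-state symbol frequencies
    from the decoded paths (Laplace +1 smoothing, missing windows excluded),
    repeat until the largest parameter change drops below ``tol``.  Start and
    transition probabilities are frozen.  States never visited keep their
    emissions (with a warning).
    """
    cur = HmmModel(dict(model.start), model.switch, {s: dict(model.emission[s]) for s in STATES})
    for _it in range(max_iter):
        counts = {s: {sym: 1.0 for sym in SYMBOLS} for s in STATES}  # Laplace +1
        visited = {s: False for s in STATES}
        for obs in training_obs:
            path, _ = viterbi(cur, obs)
            for state, sym in zip(path, obs.symbols):
                if sym != MISSING:
                    counts[state][sym] += 1.0
                    visited[state] = True
        new_emission = {}
        for s in STATES:
            if not visited[s]:
                log.warning("viterbi_train: state %s never visited; emissions unchanged", s)
                new_emission[s] = dict(cur.emission[s])
                continue
            tot = sum(counts[s].values())
            new_emission[s] = {sym: counts[s][sym] / tot for sym in SYMBOLS}
        change = max(
            abs(new_emission[s][sym] - cur.emission[s][sym]) for s in STATES for sym in SYMBOLS
        )
        cur = HmmModel(dict(cur.start), cur.switch, new_emission)
        if change < tol:
            break
    return cur


# ---------------------------------------------------------------------------
# Exchange calls
# ---------------------------------------------------------------------------

def call_exchanges(
    assignment: SubgenomeAssignment,
    decoded: dict,
) -> list[ExchangeCall]:
    """Turn decoded paths into exchange segments.

    ``decoded`` maps scaffold -> (path, SymbolSequence, DensityTrack).
    Maximal runs of windows whose decoded state differs from the scaffold's
    assigned subgenome become window-resolution segments; runs supported only
    by missing windows are discarded.
    """
    calls = []
    for scaffold, (path, obs, track) in decoded.items():
        assigned = assignment[scaffold]
        segments = []
        i = 0
        n = len(path)
        while i < n:
            if path[i] != assigned:
                j = i
                while j < n and path[j] == path[i]:
                    j += 1
                if any(obs.symbols[t] != MISSING for t in range(i, j)):
                    segments.append(
                        Feature(
                            scaffold,
                            int(track.starts[i]),
                            int(track.ends[j - 1]),
                            ".",
                            "exchange_segment",
                            f"hx_{scaffold}_{int(track.starts[i])}",
                            {"state": path[i], "n_windows": j - i},
                        )
                    )
                i = j
            else:
                i += 1
        calls.append(ExchangeCall(scaffold, segments, path, assigned))
    return calls


def pick_training_scaffolds(tracks: dict, assignment: SubgenomeAssignment,
                            n_per_side: int = 1) -> list[str]:
    """Choose the ``n_per_side`` scaffolds of each subgenome with the fewest
    minority-symbol windows — the ones that look exchange-free on their
    density tracks — as emission training material.  One scaffold per side
    guarantees both hidden states are visited during Viterbi training."""
    scores: dict[str, list] = {"A": [], "B": []}
    for scaffold, track in tracks.items():
        side = assignment[scaffold]
        own = "a" if side == "A" else "b"
        syms = majority_symbols(track).symbols
        minority = sum(1 for s in syms if s not in (own, MISSING))
        scores[side].append((minority, scaffold))
    out = []
    for side in ("A", "B"):
        out.extend(s for _, s in sorted(scores[side])[:n_per_side])
    return out


def detect_exchanges(
    tracks: dict,
    assignment: SubgenomeAssignment,
    model: HmmModel | None = None,
    train_scaffolds: list[str] | None = None,
) -> tuple[list[ExchangeCall], HmmModel]:
    """Full exchange scan: symbols -> (optional training) -> decode -> calls."""
    model = model or HmmModel()
    obs = {s: majority_symbols(t) for s, t in tracks.items()}
    if train_scaffolds:
        model = viterbi_train(model, [obs[s] for s in train_scaffolds])
    decoded = {s: (viterbi(model, obs[s])[0], obs[s], tracks[s]) for s in tracks}
    return call_exchanges(assignment, decoded), model
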