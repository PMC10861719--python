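"""In-silico single-regulator perturbation of a signed Boolean network.

Semantics: the chosen regulator is clamped to its control (WT) state and a
synchronous update iterates to a fixed point. Each non-clamped node with at
least one active incoming signal takes the sign-weighted majority of its
regulators' states (activation transmits, inhibition negates); a tied
majority is a conflict and the node retains its disease (TG) state. The
perturbation score counts downstream genes whose post-perturbation state
equals their WT state while their TG state differed — i.e. genes reverted
toward control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn_inference import UNCHANGED, GenotypeNetwork, PriorEdge

__all__ = [
    "PerturbationResult",
    "propagate",
    "perturb_and_score",
    "rank_regulators",
    "brute_force_oracle",
]


@dataclass
class PerturbationResult:
    regulator: str
    score: int
    reverted_genes: list
    unresolved_conflicts: list = field(default_factory=list)
    oscillating: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.score != len(self.reverted_genes):
            raise ValueError("score must equal len(reverted_genes)")
        if self.regulator in self.reverted_genes:
            raise ValueError("regulator cannot revert itself")


def _signed_edges(network) -> list:
    """(source, target, +1/-1) triples; unresolved-sign edges are skipped."""
    if isinstance(network, GenotypeNetwork):
        edges = network.edges
    else:
        edges = list(network)
    out = []
    n_unresolved = 0
    for e in edges:
        if isinstance(e, PriorEdge):
            src, tgt, eff = e.source, e.target, e.effect
        else:
            src, tgt, eff = e
            if eff in (1, -1):
                out.append((src, tgt, int(eff)))
                continue
        if eff == "activation":
            out.append((src, tgt, 1))
        elif eff == "inhibition":
            out.append((src, tgt, -1))
        else:
            n_unresolved += 1
    if n_unresolved:
        warnings.warn(
            f"{n_unresolved} unresolved-sign edges excluded from propagation",
            stacklevel=3,
        )
    return out


def _network_nodes(edges, *state_maps) -> list:
    nodes = {u for u, _, _ in edges} | {v for _, v, _ in edges}
    for m in state_maps:
        nodes |= set(m)
    return sorted(nodes)


def propagate(network, tg_states: dict, clamp: dict, max_rounds: int | None = None):
    """Synchronous propagation from the TG state under clamped nodes.

    Returns (post_states dict, conflicted list, oscillating list). Nodes that
    fail to settle within 2*|nodes| rounds are flagged oscillating and fall
    back to their TG state.
    """
    edges = _signed_edges(network)
    nodes = _network_nodes(edges, tg_states)
    for g in clamp:
        if g not in nodes:
            raise ValueError(f"clamped gene {g!r} not in the network")
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))  # adj[t, s] = edge sign
    has_in = np.zeros(n, dtype=bool)
    for u, v, s in edges:
        adj[idx[v], idx[u]] = s
        has_in[idx[v]] = True
    tg_vec = np.array([tg_states.get(v, UNCHANGED) for v in nodes], dtype=int)
    clamp_mask = np.zeros(n, dtype=bool)
    state = tg_vec.copy()
    for g, s in clamp.items():
        clamp_mask[idx[g]] = True
        state[idx[g]] = s

    bound = max_rounds if max_rounds is not None else 2 * n
    prev = None
    rounds = 0
    while (prev is None or not np.array_equal(state, prev)) and rounds < bound:
        prev = state
        signal = adj @ prev
        active = (adj * (prev != 0)[None, :]).astype(bool).any(axis=1)
        nxt = prev.copy()
        upd = ~clamp_mask & active
        nxt[upd & (signal > 0)] = 1
        nxt[upd & (signal < 0)] = -1
        tied = upd & (signal == 0)
        nxt[tied] = tg_vec[tied]
        state = nxt
        rounds += 1
    oscillating: list = []
    if prev is None or not np.array_equal(state, prev):
        osc_mask = state != prev
        oscillating = [nodes[i] for i in np.flatnonzero(osc_mask)]
        state = np.where(osc_mask, tg_vec, state)
    # conflicts evaluated at the final state
    signal = adj @ state
    active = (adj * (state != 0)[None, :]).astype(bool).any(axis=1)
    conflicted_mask = ~clamp_mask & active & (signal == 0)
    conflicted = [nodes[i] for i in np.flatnonzero(conflicted_mask)]
    post = {v: int(state[idx[v]]) for v in nodes}
    return post, conflicted, oscillating


def perturb_and_score(
    network, tg_states: dict, wt_states: dict, regulator: str
) -> PerturbationResult:
    """Clamp ``regulator`` to its WT state and count reverted DEGs."""
    edges = _signed_edges(network)
    nodes = set(_network_nodes(edges, tg_states))
    if regulator not in nodes:
        raise ValueError(f"regulator {regulator!r} absent from the network")
    post, conflicted, oscillating = propagate(
        network, tg_states, {regulator: wt_states.get(regulator, UNCHANGED)}
    )
    reverted = sorted(
        g
        for g, s in post.items()
        if g != regulator
        and tg_states.get(g, UNCHANGED) != wt_states.get(g, UNCHANGED)
        and s == wt_states.get(g, UNCHANGED)
    )
    return PerturbationResult(
        regulator=regulator,
        score=len(reverted),
        reverted_genes=reverted,
        unresolved_conflicts=conflicted,
        oscillating=oscillating,
    )


def rank_regulators(network, tg_states: dict, wt_states: dict) -> list:
    """Perturb every node with outgoing edges; sort by score desc, then name."""
    edges = _signed_edges(network)
    if not edges:
        raise ValueError("network has no resolvable edges")
    regulators = sorted({u for u, _, _ in edges})
    results = [
        perturb_and_score(network, tg_states, wt_states, r) for r in regulators
    ]
    return sorted(results, key=lambda r: (-r.score, r.regulator))


def ranking_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.regulator,
                "score": r.score,
                "reverted_genes": ",".join(r.reverted_genes),
                "conflicts": ",".join(r.unresolved_conflicts),
                "oscillating": ",".join(r.oscillating),
            }
            for r in results
        ],
        columns=["gene", "score", "reverted_genes", "conflicts", "oscillating"],
    )


def brute_force_oracle(network, tg_states: dict, wt_states: dict, regulator: str) -> int:
    """Reference score by explicit per-node iteration (networks <= 20 nodes).

    Deliberately written with plain dict/loop state vectors and no shared
    code with :func:`propagate`; the production path must match it exactly.
    """
    edges = _signed_edges(network)
    nodes = _network_nodes(edges, tg_states)
    if len(nodes) > 20:
        raise ValueError("brute-force oracle limited to 20 nodes")
    if regulator not in nodes:
        raise ValueError(f"regulator {regulator!r} absent from the network")
    incoming: dict[str, list] = {v: [] for v in nodes}
    for u, v, s in edges:
        incoming[v].append((u, s))

    state = {v: tg_states.get(v, 0) for v in nodes}
    state[regulator] = wt_states.get(regulator, 0)
    prev = None
    rounds = 0
    limit = 2 * len(nodes)
    while state != prev and rounds < limit:
        prev = dict(state)
        new = {}
        for v in nodes:
            if v == regulator:
                new[v] = prev[v]
                continue
            total, active = 0, 0
            for u, s in incoming[v]:
                if prev[u] != 0:
                    total += s * prev[u]
                    active += 1
            if active == 0:
                new[v] = prev[v]
            elif total > 0:
                new[v] = 1
            elif total < 0:
                new[v] = -1
            else:
                new[v] = tg_states.get(v, 0)
        state = new
        rounds += 1
    if state != prev:  # hit the bound: oscillating nodes are not reverted
        for v in nodes:
            if state[v] != prev[v]:
                state[v] = tg_states.get(v, 0)
    score = 0
    for v in nodes:
        if v == regulator:
            continue
        if tg_states.get(v, 0) != wt_states.get(v, 0) and state[v] == wt_states.get(v, 0):
            score += 1
    return score
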