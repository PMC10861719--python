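"""Differential Boolean regulatory-network inference over a prior network.

A prior edge is *consistent* with one phenotype's Boolean states when both
endpoints are differentially expressed and the sign fits: activation demands
matching states, inhibition opposite states. Edges touching an UNCHANGED
node are uninformative (neither rewarded nor penalized). Unknown-sign edges
are resolved to whichever sign makes them consistent before scoring.

A genetic algorithm selects the edge subset maximizing
    fitness = n_consistent + n_DEG_nodes_covered - lambda * n_inconsistent
where a DEG node counts as covered when at least one included consistent
edge touches it. With this separable objective the exhaustive optimum keeps
every consistent edge and drops every inconsistent one, which the GA tests
exploit as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UP",
    "DOWN",
    "UNCHANGED",
    "PriorEdge",
    "BooleanStateMap",
    "GAConfig",
    "GenotypeNetwork",
    "load_prior_edges",
    "booleanize",
    "edge_consistent",
    "resolve_unknown_sign",
    "network_fitness",
    "ga_optimize",
    "build_genotype_networks",
    "exhaustive_optimum",
    "ALLOWED_CATEGORIES",
]

UP, DOWN, UNCHANGED = 1, -1, 0
_STATE_NAME = {UP: "UP", DOWN: "DOWN", UNCHANGED: "UNCHANGED"}

ALLOWED_CATEGORIES = frozenset(
    {
        "Influence on Expression",
        "Transcriptional Regulation",
        "Regulation",
        "co Regulation of Transcription",
        "Binding",
    }
)


@dataclass(frozen=True)
class PriorEdge:
    source: str
    target: str
    effect: str  # activation | inhibition | unknown
    category: str = "uncurated"

    def __post_init__(self) -> None:
        if self.effect not in ("activation", "inhibition", "unknown"):
            raise ValueError(f"bad effect {self.effect!r}")


def load_prior_edges(
    edges: pd.DataFrame, allow_uncurated: bool = False
) -> list:
    """Validate a network table into PriorEdge objects.

    Self-loops are dropped with a warning. Edges whose category is outside
    the curated list are dropped unless ``allow_uncurated`` (they then keep
    the category tag "uncurated").
    """
    out = []
    n_self = 0
    n_uncat = 0
    for row in edges.itertuples(index=False):
        if row.source == row.target:
            n_self += 1
            continue
        cat = row.category
        if cat not in ALLOWED_CATEGORIES:
            if not allow_uncurated:
                n_uncat += 1
                continue
            cat = "uncurated"
        out.append(PriorEdge(str(row.source), str(row.target), str(row.effect), cat))
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop edges", stacklevel=2)
    if n_uncat:
        warnings.warn(
            f"dropped {n_uncat} edges with uncurated categories "
            "(pass allow_uncurated=True to keep them)",
            stacklevel=2,
        )
    return out


@dataclass
class BooleanStateMap:
    """Per-phenotype gene -> state in {UP, DOWN, UNCHANGED} (ints +1/-1/0)."""

    tg: dict
    wt: dict

    def states(self, phenotype: str) -> dict:
        if phenotype == "TG":
            return self.tg
        if phenotype == "WT":
            return self.wt
        raise ValueError(f"unknown phenotype {phenotype!r}")

    def deg_genes(self) -> list:
        return sorted(g for g, s in self.tg.items() if s != UNCHANGED)

    def to_json_dict(self) -> dict:
        return {
            "TG": {g: _STATE_NAME[s] for g, s in sorted(self.tg.items())},
            "WT": {g: _STATE_NAME[s] for g, s in sorted(self.wt.items())},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "BooleanStateMap":
        inv = {v: k for k, v in _STATE_NAME.items()}
        return cls(
            tg={g: inv[s] for g, s in d["TG"].items()},
            wt={g: inv[s] for g, s in d["WT"].items()},
        )


def booleanize(de_stratum: pd.DataFrame, q_thresh: float = 0.05) -> BooleanStateMap:
    """Discretize one stratum's DE table into TG states; WT mirrors DEGs.

    TG state: UP when q < q_thresh and logFC > 0, DOWN when q < q_thresh and
    logFC < 0, else UNCHANGED. WT is the opposite for DEGs and UNCHANGED
    otherwise.
    """
    tg, wt = {}, {}
    for row in de_stratum.itertuples(index=False):
        if row.q < q_thresh and row.logFC > 0:
            s = UP
        elif row.q < q_thresh and row.logFC < 0:
            s = DOWN
        else:
            s = UNCHANGED
        tg[row.gene] = s
        wt[row.gene] = -s
    return BooleanStateMap(tg, wt)


def edge_consistent(edge: PriorEdge, states: dict):
    """True/False for informative edges, None when either endpoint is
    UNCHANGED (or missing)."""
    if edge.effect == "unknown":
        raise ValueError(
            f"edge {edge.source}->{edge.target} has unresolved sign"
        )
    s, t = states.get(edge.source, UNCHANGED), states.get(edge.target, UNCHANGED)
    if s == UNCHANGED or t == UNCHANGED:
        return None
    return (s == t) == (edge.effect == "activation")


def resolve_unknown_sign(edge: PriorEdge, states: dict):
    """The sign making an unknown edge consistent, or None if uninformative."""
    if edge.effect != "unknown":
        raise ValueError("edge sign already known")
    s, t = states.get(edge.source, UNCHANGED), states.get(edge.target, UNCHANGED)
    if s == UNCHANGED or t == UNCHANGED:
        return None
    return "activation" if s == t else "inhibition"


def _edge_status(edges: list, states: dict):
    """Per-edge (+1 consistent / -1 inconsistent / 0 uninformative) and the
    resolved effect string for each edge under these states."""
    status = np.zeros(len(edges), dtype=int)
    resolved = []
    for i, e in enumerate(edges):
        if e.effect == "unknown":
            sign = resolve_unknown_sign(e, states)
            if sign is None:
                resolved.append("unknown")
                continue
            resolved.append(sign)
            status[i] = 1  # resolved to the consistent sign by construction
        else:
            resolved.append(e.effect)
            c = edge_consistent(e, states)
            status[i] = 0 if c is None else (1 if c else -1)
    return status, resolved


def network_fitness(
    included: np.ndarray, edges: list, states: dict, lam: float = 1.0
) -> float:
    """Score one candidate edge subset (boolean include mask)."""
    status, _ = _edge_status(edges, states)
    inc = np.asarray(included, dtype=bool)
    n_cons = int(((status == 1) & inc).sum())
    n_incons = int(((status == -1) & inc).sum())
    covered = set()
    for i, e in enumerate(edges):
        if inc[i] and status[i] == 1:
            covered.add(e.source)
            covered.add(e.target)
    covered = {g for g in covered if states.get(g, UNCHANGED) != UNCHANGED}
    return n_cons + len(covered) - lam * n_incons


@dataclass
class GAConfig:
    population: int = 200
    generations: int = 300
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    elitism: int = 2
    inconsistency_penalty: float = 1.0
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 0 <= self.elitism <= self.population:
            raise ValueError("elitism must be in [0, population]")


@dataclass
class GenotypeNetwork:
    phenotype: str
    edges: list  # PriorEdge with resolved effects (included subset)
    included_mask: np.ndarray
    fitness: float
    n_consistent: int
    n_inconsistent: int
    n_covered_degs: int
    best_fitness_per_generation: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "effect": e.effect,
                    "category": e.category,
                }
                for e in self.edges
            ],
            columns=["source", "target", "effect", "category"],
        )


def _population_fitness(pop, status, cover_incidence, lam):
    """Vectorized fitness for a population matrix (P x E of bools)."""
    popf = pop.astype(float)
    cons = popf @ (status == 1).astype(float)
    incons = popf @ (status == -1).astype(float)
    # covered DEG nodes: any included consistent edge incident to the node
    eff = popf * (status == 1)  # P x E
    covered = (eff @ cover_incidence) > 0  # P x N_deg
    return cons + covered.sum(axis=1) - lam * incons


def ga_optimize(
    prior_edges: list,
    states: dict,
    phenotype: str,
    config: GAConfig | None = None,
) -> GenotypeNetwork:
    """Genetic algorithm over edge-inclusion chromosomes.

    Unknown signs are resolved greedily against ``states`` before scoring.
    Tournament selection (size 3), uniform crossover, per-bit mutation, and
    elitism; deterministic given ``config.seed``.
    """
    config = config or GAConfig()
    edges = list(prior_edges)
    if not edges:
        raise ValueError(
            "insufficient interactions: the prior has no edges among the "
            "stratum's DEGs"
        )
    status, resolved_effects = _edge_status(edges, states)
    deg_nodes = sorted(
        {g for e in edges for g in (e.source, e.target)}
        & {g for g, s in states.items() if s != UNCHANGED}
    )
    node_idx = {g: i for i, g in enumerate(deg_nodes)}
    cover = np.zeros((len(edges), len(deg_nodes)))
    for i, e in enumerate(edges):
        for g in (e.source, e.target):
            if g in node_idx:
                cover[i, node_idx[g]] = 1.0
    lam = config.inconsistency_penalty

    rng = np.random.default_rng(config.seed)
    P, E = config.population, len(edges)
    pop = rng.random((P, E)) < 0.5
    fit = _population_fitness(pop, status, cover, lam)
    history = []
    for _ in range(config.generations):
        best_order = np.argsort(-fit, kind="mergesort")
        history.append(float(fit[best_order[0]]))
        elite = pop[best_order[: config.elitism]]
        # tournament selection
        t = rng.integers(P, size=(P, config.tournament_size))
        winners = t[np.arange(P), np.argmax(fit[t], axis=1)]
        parents = pop[winners]
        # uniform crossover on consecutive pairs
        children = parents.copy()
        do_cx = rng.random(P // 2) < config.crossover_rate
        mask = rng.random((P // 2, E)) < 0.5
        a = parents[0::2][: P // 2]
        b = parents[1::2][: P // 2]
        cx_mask = mask & do_cx[:, None]
        children[0 : 2 * (P // 2) : 2] = np.where(cx_mask, b, a)
        children[1 : 2 * (P // 2) : 2] = np.where(cx_mask, a, b)
        # mutation
        flips = rng.random((P, E)) < config.mutation_rate
        children ^= flips
        if config.elitism:
            children[: config.elitism] = elite
        pop = children
        fit = _population_fitness(pop, status, cover, lam)
    best_i = int(np.argmax(fit))
    history.append(float(fit[best_i]))
    mask = pop[best_i]

    included_edges = []
    n_cons = n_incons = 0
    covered = set()
    for i, e in enumerate(edges):
        if not mask[i]:
            continue
        eff = resolved_effects[i]
        included_edges.append(PriorEdge(e.source, e.target, eff, e.category))
        if status[i] == 1:
            n_cons += 1
            covered |= {e.source, e.target} & set(deg_nodes)
        elif status[i] == -1:
            n_incons += 1
    return GenotypeNetwork(
        phenotype=phenotype,
        edges=included_edges,
        included_mask=mask.copy(),
        fitness=float(fit[best_i]),
        n_consistent=n_cons,
        n_inconsistent=n_incons,
        n_covered_degs=len(covered),
        best_fitness_per_generation=history,
    )


def exhaustive_optimum(prior_edges: list, states: dict, lam: float = 1.0) -> float:
    """Exact optimum fitness by enumerating all 2^E subsets (E <= 20)."""
    edges = list(prior_edges)
    E = len(edges)
    if E > 20:
        raise ValueError("exhaustive search limited to 20 edges")
    status, _ = _edge_status(edges, states)
    deg_nodes = sorted(
        {g for e in edges for g in (e.source, e.target)}
        & {g for g, s in states.items() if s != UNCHANGED}
    )
    node_idx = {g: i for i, g in enumerate(deg_nodes)}
    cover = np.zeros((E, len(deg_nodes)))
    for i, e in enumerate(edges):
        for g in (e.source, e.target):
            if g in node_idx:
                cover[i, node_idx[g]] = 1.0
    subsets = (
        (np.arange(2**E)[:, None] >> np.arange(E)[None, :]) & 1
    ).astype(bool)
    fits = _population_fitness(subsets, status, cover, lam)
    return float(fits.max())


def restrict_prior_to_degs(prior_edges: list, states: dict) -> list:
    """Keep only edges whose endpoints are both DEGs under ``states``."""
    degs = {g for g, s in states.items() if s != UNCHANGED}
    return [e for e in prior_edges if e.source in degs and e.target in degs]


def build_genotype_networks(
    prior_edges: list, state_map: BooleanStateMap, config: GAConfig | None = None
) -> tuple:
    """One GA run per phenotype on the DEG-restricted prior.

    Returns (tg_network, wt_network, shared_edges DataFrame).
    """
    config = config or GAConfig()
    nets = {}
    for phen, states in (("TG", state_map.tg), ("WT", state_map.wt)):
        restricted = restrict_prior_to_degs(prior_edges, states)
        if not restricted:
            raise ValueError(
                "insufficient interactions among DEGs for network construction"
            )
        nets[phen] = ga_optimize(restricted, states, phen, config)
    tg_net, wt_net = nets["TG"], nets["WT"]
    tg_keys = {(e.source, e.target) for e in tg_net.edges}
    wt_keys = {(e.source, e.target) for e in wt_net.edges}
    shared = pd.DataFrame(
        sorted(tg_keys & wt_keys), columns=["source", "target"]
    )
    return tg_net, wt_net, shared
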