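"""Synthetic count matrices, gene sets, and signed regulatory networks.

Everything downstream of raw data is testable against this module: counts are
drawn from a Poisson model with planted genotype effects per gender, and the
network generator plants a Boolean disease state (root-regulator flip
propagated along true edge signs) together with ground-truth perturbation
scores computed by an independent plain-loop propagation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CountMatrix,
    GENDERS,
    GENOTYPES,
    file_sha256,
    write_counts_bundle,
    write_gmt,
    write_metadata,
    write_network_tsv,
)

__all__ = [
    "SimConfig",
    "PlantedEffect",
    "SyntheticNetworkSpec",
    "generate_counts",
    "generate_prior_network",
    "write_bundle",
    "make_default_bundle",
    "effects_from_states",
]

EFFECT_CLASSES = ("neutral", "male_specific", "female_specific", "dimorphic", "null")

MITO_PREFIX = "mt-"


@dataclass
class SimConfig:
    n_genes: int
    cell_types: dict  # label -> cells per (genotype, gender) arm
    baseline_log_mean_range: tuple = (-1.0, 1.5)
    libsize_lognormal_params: tuple = (0.0, 0.25)
    mito_gene_fraction: float = 0.02
    mito_high_cell_fraction: float = 0.0
    seed: int = 0
    # plumbing beyond the core design: cell identity and optional noise
    marker_genes_per_type: int = 10
    marker_log_shift: float = 2.0
    overdispersion: float = 0.0  # gamma-Poisson dispersion; 0 = pure Poisson
    gene_names: list | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        for ct, n in self.cell_types.items():
            if int(n) < 1:
                raise ValueError(f"cell type {ct!r} must have >= 1 cell per arm")
        for frac, name in (
            (self.mito_gene_fraction, "mito_gene_fraction"),
            (self.mito_high_cell_fraction, "mito_high_cell_fraction"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise ValueError("baseline_log_mean_range must be (lo, hi) with lo <= hi")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")


@dataclass(frozen=True)
class PlantedEffect:
    """Genotype (TG vs WT) log-fold-change planted per gender.

    ``logFC_m``/``logFC_f`` are on the natural-log scale and apply to TG cells
    of the matching gender (WT cells stay at baseline).
    """

    gene: str
    cell_type: str  # a config cell type or "ALL"
    effect_class: str
    logFC_m: float
    logFC_f: float

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect_class {self.effect_class!r}")
        m, f = self.logFC_m, self.logFC_f
        ok = {
            "neutral": m != 0 and f != 0 and np.sign(m) == np.sign(f),
            "male_specific": m != 0 and f == 0,
            "female_specific": m == 0 and f != 0,
            "dimorphic": m != 0 and f != 0 and np.sign(m) == -np.sign(f),
            "null": m == 0 and f == 0,
        }[self.effect_class]
        if not ok:
            raise ValueError(
                f"logFCs ({m}, {f}) inconsistent with class {self.effect_class!r} "
                f"for gene {self.gene!r}"
            )


@dataclass
class SyntheticNetworkSpec:
    n_nodes: int
    n_edges: int
    frac_inhibition: float = 0.3
    frac_unknown_sign: float = 0.2
    acyclic: bool = True
    root_regulators: list = field(default_factory=list)
    seed: int = 0
    node_prefix: str = "RG"

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0 < self.n_edges <= self.n_nodes * (self.n_nodes - 1):
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for {self.n_nodes} nodes"
            )
        if self.acyclic and self.n_edges > self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("n_edges too large for an acyclic network")
        for frac in (self.frac_inhibition, self.frac_unknown_sign):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")

    def node_names(self) -> list:
        return [f"{self.node_prefix}{i:03d}" for i in range(self.n_nodes)]


def _design_genes(config: SimConfig):
    """Deterministic gene layout: names, mito mask, baselines, marker sets."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_mito = int(round(config.mito_gene_fraction * n))
    if config.gene_names is not None:
        names = list(config.gene_names)
        mito_mask = np.array([g.startswith(MITO_PREFIX) for g in names])
    else:
        names = [f"{MITO_PREFIX}Gene{i:04d}" for i in range(n_mito)]
        names += [f"Gene{i:04d}" for i in range(n_mito, n)]
        mito_mask = np.array([g.startswith(MITO_PREFIX) for g in names])
    lo, hi = config.baseline_log_mean_range
    base = rng.uniform(lo, hi, size=n)
    # markers drawn from the non-mito tail so they never collide with the
    # caller's effect genes (which by convention sit at the front)
    marker_sets: dict[str, list] = {}
    pool = [i for i in range(n) if not mito_mask[i]]
    pool = pool[::-1]
    k = config.marker_genes_per_type
    for ct in config.cell_types:
        take, pool = pool[:k], pool[k:]
        if len(take) < k:
            raise ValueError("not enough genes to assign cell-type markers")
        marker_sets[ct] = [names[i] for i in sorted(take)]
    return names, mito_mask, base, marker_sets


def generate_counts(config: SimConfig, effects: list) -> tuple:
    """Draw Poisson counts under the planted design.

    Per gene g and cell c: count ~ Poisson(sf_c * exp(base_g + shift_gc))
    where shift collects the cell-type marker elevation and, for TG cells,
    the planted gender-matched logFC.

    Returns (CountMatrix, metadata DataFrame).
    """
    names, mito_mask, base, marker_sets = _design_genes(config)
    name_idx = {g: i for i, g in enumerate(names)}
    for e in effects:
        if e.gene not in name_idx:
            raise ValueError(f"planted effect names unknown gene {e.gene!r}")
        if e.cell_type != "ALL" and e.cell_type not in config.cell_types:
            raise ValueError(
                f"planted effect for {e.gene!r} names unknown cell type "
                f"{e.cell_type!r}"
            )

    rng = np.random.default_rng(config.seed + 1)
    arms = [(gt, gd) for gt in GENOTYPES for gd in GENDERS]
    cols = []
    meta_rows = []
    n = config.n_genes
    marker_idx = {
        ct: np.array([name_idx[g] for g in genes])
        for ct, genes in marker_sets.items()
    }
    mu, sigma = config.libsize_lognormal_params
    for ct, n_per_arm in config.cell_types.items():
        for gt, gd in arms:
            n_cells = int(n_per_arm)
            log_mean = base.copy()
            log_mean[marker_idx[ct]] += config.marker_log_shift
            if gt == "TG":
                for e in effects:
                    if e.cell_type not in ("ALL", ct):
                        continue
                    lfc = e.logFC_m if gd == "M" else e.logFC_f
                    log_mean[name_idx[e.gene]] += lfc
            sf = rng.lognormal(mu, sigma, size=n_cells)
            lam = sf[None, :] * np.exp(log_mean)[:, None]  # genes x cells
            n_high = int(round(config.mito_high_cell_fraction * n_cells))
            if n_high and mito_mask.any():
                # boost mito mass in the first n_high cells of the arm so their
                # expected mito fraction lands near 15% (> the 5% QC cutoff)
                mito_sum = lam[mito_mask, :n_high].sum(axis=0)
                other_sum = lam[~mito_mask, :n_high].sum(axis=0)
                target = 0.15
                factor = target * other_sum / np.maximum(
                    (1 - target) * mito_sum, 1e-12
                )
                lam[np.ix_(mito_mask, np.arange(n_high))] *= factor[None, :]
            if config.overdispersion > 0:
                shape = 1.0 / config.overdispersion
                lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
            counts = rng.poisson(lam)
            cols.append(sp.csc_matrix(counts))
            for i in range(n_cells):
                meta_rows.append(
                    {
                        "barcode": f"{ct}_{gt}{gd}_{i:04d}",
                        "genotype": gt,
                        "gender": gd,
                        "cell_type": ct,
                    }
                )
    matrix = sp.hstack(cols, format="csr").astype(np.int64)
    metadata = pd.DataFrame(meta_rows)
    counts = CountMatrix(matrix, np.array(names, dtype=object),
                         metadata["barcode"].to_numpy(dtype=object))
    return counts, metadata


def marker_gene_sets(config: SimConfig) -> dict:
    """The cell-type marker sets implied by the config (for GMT export)."""
    _, _, _, marker_sets = _design_genes(config)
    return {ct: (f"{ct} markers", genes) for ct, genes in marker_sets.items()}


# ---------------------------------------------------------------------------
# prior-knowledge network with planted Boolean disease state


def _propagate_reference(edges, tg_states, wt_states, clamp_gene, max_rounds=None):
    """Plain-loop synchronous propagation used for ground-truth scores.

    Independent of the perturbation module: dict-based, no arrays. Semantics:
    clamp the regulator to its WT state; every other node with at least one
    active incoming signal takes the sign-weighted majority, ties revert to
    the TG state; iterate to a fixed point (bounded by 2 * n nodes).
    """
    nodes = sorted({e[0] for e in edges} | {e[1] for e in edges} | set(tg_states))
    incoming: dict[str, list] = {v: [] for v in nodes}
    for src, tgt, sign in edges:
        incoming[tgt].append((src, sign))
    state = {v: tg_states.get(v, 0) for v in nodes}
    state[clamp_gene] = wt_states.get(clamp_gene, 0)
    bound = max_rounds or 2 * len(nodes)
    for _ in range(bound):
        nxt = {}
        for v in nodes:
            if v == clamp_gene:
                nxt[v] = state[v]
                continue
            total = 0
            active = 0
            for src, sign in incoming[v]:
                s = state[src]
                if s != 0:
                    total += sign * s
                    active += 1
            if active == 0:
                nxt[v] = state[v]
            elif total > 0:
                nxt[v] = 1
            elif total < 0:
                nxt[v] = -1
            else:
                nxt[v] = tg_states.get(v, 0)  # tied majority -> disease state
        if nxt == state:
            break
        state = nxt
    else:
        # did not converge: oscillating nodes count as not reverted
        for v in nodes:
            if nxt[v] != state[v]:
                nxt[v] = tg_states.get(v, 0)
        state = nxt
    return state


def _reference_score(edges, tg_states, wt_states, regulator) -> int:
    post = _propagate_reference(edges, tg_states, wt_states, regulator)
    return sum(
        1
        for g in post
        if g != regulator
        and tg_states.get(g, 0) != wt_states.get(g, 0)
        and post[g] == wt_states.get(g, 0)
    )


def generate_prior_network(spec: SyntheticNetworkSpec) -> tuple:
    """Build a signed network whose Boolean dynamics realise a planted disease.

    Returns (edges DataFrame as emitted — some signs masked to ``unknown``,
    states dict with 'TG'/'WT' gene->state maps, ground_truth dict with the
    true signs, root regulators, and per-node reference perturbation scores).
    """
    rng = np.random.default_rng(spec.seed)
    nodes = spec.node_names()
    roots = list(spec.root_regulators) or [nodes[0]]
    for r in roots:
        if r not in nodes:
            raise ValueError(f"root regulator {r!r} not among generated nodes")

    ordered = roots + [v for v in nodes if v not in roots]
    order = {v: i for i, v in enumerate(ordered)}
    # spanning structure: every non-root gets one parent from earlier nodes so
    # the disease flip reaches the whole network
    edges: list[tuple] = []
    edge_set = set()
    state = {}
    for r in roots:
        state[r] = 1
    for v in ordered:
        if v in roots:
            continue
        candidates = [u for u in ordered if order[u] < order[v]]
        parent = candidates[rng.integers(len(candidates))]
        sign = -1 if rng.random() < spec.frac_inhibition else 1
        edges.append((parent, v, sign))
        edge_set.add((parent, v))
    # resolve states along the spanning tree (parents precede children)
    for parent, v, sign in edges:
        state[v] = sign * state[parent]
    # extra edges get the sign consistent with the planted states
    n_extra = spec.n_edges - len(edges)
    if n_extra < 0:
        raise ValueError(
            f"n_edges={spec.n_edges} below the {len(edges)} spanning edges"
        )
    attempts = 0
    while n_extra > 0 and attempts < 100 * spec.n_edges:
        attempts += 1
        i, j = rng.integers(spec.n_nodes, size=2)
        u, v = nodes[i], nodes[j]
        if u == v or (u, v) in edge_set:
            continue
        if spec.acyclic and order[u] >= order[v]:
            continue
        sign = 1 if state[u] == state[v] else -1
        edges.append((u, v, sign))
        edge_set.add((u, v))
        n_extra -= 1
    if n_extra > 0:
        raise ValueError("could not place the requested number of edges")

    n_unknown = int(round(spec.frac_unknown_sign * len(edges)))
    unknown_idx = set(
        rng.choice(len(edges), size=n_unknown, replace=False).tolist()
    )
    rows = []
    for i, (u, v, sign) in enumerate(edges):
        effect = "unknown" if i in unknown_idx else (
            "activation" if sign == 1 else "inhibition"
        )
        rows.append(
            {
                "source": u,
                "target": v,
                "effect": effect,
                "category": "Transcriptional Regulation",
            }
        )
    emitted = pd.DataFrame(rows)

    tg_states = dict(state)
    wt_states = {v: -s for v, s in state.items()}
    true_edges = [(u, v, s) for u, v, s in edges]
    scores = {
        v: _reference_score(true_edges, tg_states, wt_states, v) for v in nodes
    }
    ground_truth = {
        "roots": roots,
        "true_signs": {
            f"{u}->{v}": ("activation" if s == 1 else "inhibition")
            for u, v, s in edges
        },
        "tg_states": {v: int(s) for v, s in tg_states.items()},
        "wt_states": {v: int(s) for v, s in wt_states.items()},
        "scores": scores,
    }
    states = {"TG": tg_states, "WT": wt_states}
    return emitted, states, ground_truth


def effects_from_states(tg_states: dict, magnitude: float = 1.0,
                        cell_type: str = "ALL") -> list:
    """Gender-neutral planted effects matching a network's TG states."""
    effects = []
    for gene, s in sorted(tg_states.items()):
        if s == 0:
            continue
        lfc = magnitude * float(s)
        effects.append(
            PlantedEffect(gene, cell_type, "neutral", lfc, lfc)
        )
    return effects


# ---------------------------------------------------------------------------
# bundle assembly


@dataclass
class Bundle:
    config: SimConfig
    effects: list
    counts: CountMatrix
    metadata: pd.DataFrame
    marker_sets: dict
    pathway_sets: dict
    network: pd.DataFrame
    states: dict
    ground_truth: dict


def make_default_bundle(
    seed: int = 0,
    cells_per_arm: int = 300,
    n_genes: int = 600,
    n_network_nodes: int = 40,
    n_network_edges: int = 60,
    n_class_genes: int = 5,
    class_logfc: float = 1.0,
    network_logfc: float = 1.0,
    mito_high_cell_fraction: float = 0.05,
) -> Bundle:
    """The default end-to-end fixture: three cell types, one planted root.

    ``cells_per_arm`` counts cells per (genotype, gender) arm, split evenly
    across the three cell types. Network genes carry gender-neutral effects
    (cell-type ALL) whose sign matches the planted TG Boolean state.
    """
    net_spec = SyntheticNetworkSpec(
        n_nodes=n_network_nodes,
        n_edges=n_network_edges,
        frac_inhibition=0.3,
        frac_unknown_sign=0.2,
        acyclic=True,
        seed=seed,
    )
    network, states, ground_truth = generate_prior_network(net_spec)
    net_nodes = net_spec.node_names()

    cell_types = ("neuron", "astrocyte", "microglia")
    per_type = max(cells_per_arm // len(cell_types), 1)
    rng = np.random.default_rng(seed + 7)

    # gene space: network genes first, then per-class planted genes, then flats
    class_genes = {}
    cursor = len(net_nodes)
    names = list(net_nodes)
    for cls in ("neutral", "male_specific", "female_specific", "dimorphic", "null"):
        class_genes[cls] = [f"{cls[:4].capitalize()}{i:03d}" for i in range(n_class_genes)]
        names += class_genes[cls]
    n_mito = max(int(round(0.02 * n_genes)), 1)
    names += [f"{MITO_PREFIX}Gene{i:04d}" for i in range(n_mito)]
    names += [f"Gene{i:04d}" for i in range(len(names), n_genes)]
    names = names[:n_genes]

    config = SimConfig(
        n_genes=n_genes,
        cell_types={ct: per_type for ct in cell_types},
        baseline_log_mean_range=(0.0, 1.2),
        libsize_lognormal_params=(0.0, 0.2),
        mito_gene_fraction=n_mito / n_genes,
        mito_high_cell_fraction=mito_high_cell_fraction,
        seed=seed,
        marker_genes_per_type=12,
        marker_log_shift=2.5,
        gene_names=names,
    )

    effects = effects_from_states(
        states["TG"], magnitude=network_logfc, cell_type="ALL"
    )
    m = class_logfc
    for g in class_genes["neutral"]:
        sgn = 1 if rng.random() < 0.5 else -1
        effects.append(PlantedEffect(g, "ALL", "neutral", sgn * m, sgn * m))
    for g in class_genes["male_specific"]:
        sgn = 1 if rng.random() < 0.5 else -1
        effects.append(PlantedEffect(g, "ALL", "male_specific", sgn * m, 0.0))
    for g in class_genes["female_specific"]:
        sgn = 1 if rng.random() < 0.5 else -1
        effects.append(PlantedEffect(g, "ALL", "female_specific", 0.0, sgn * m))
    for g in class_genes["dimorphic"]:
        sgn = 1 if rng.random() < 0.5 else -1
        effects.append(PlantedEffect(g, "ALL", "dimorphic", sgn * m, -sgn * m))
    for g in class_genes["null"]:
        effects.append(PlantedEffect(g, "ALL", "null", 0.0, 0.0))

    counts, metadata = generate_counts(config, effects)
    markers = marker_gene_sets(config)

    # pathway sets over the simulated universe: one set planted on DEGs
    universe = [g for g in names if not g.startswith(MITO_PREFIX)]
    pathways = {}
    planted = sorted(states["TG"], key=lambda g: g)[:15]
    pathways["PW_PLANTED"] = ("planted disease module", planted)
    chunk = 20
    flat = [g for g in universe if g not in set(planted)]
    for i in range(10):
        block = flat[i * chunk : (i + 1) * chunk]
        if len(block) >= 10:
            pathways[f"PW_{i:02d}"] = (f"background set {i}", block)

    ground_truth = dict(ground_truth)
    ground_truth["class_genes"] = class_genes
    ground_truth["effects"] = [
        {
            "gene": e.gene,
            "cell_type": e.cell_type,
            "effect_class": e.effect_class,
            "logFC_m": e.logFC_m,
            "logFC_f": e.logFC_f,
        }
        for e in effects
    ]
    return Bundle(
        config=config,
        effects=effects,
        counts=counts,
        metadata=metadata,
        marker_sets=markers,
        pathway_sets=pathways,
        network=network,
        states=states,
        ground_truth=ground_truth,
    )


def write_bundle(dir_path, bundle: Bundle) -> dict:
    """Write every artifact as plain text and return a checksum manifest."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths = write_counts_bundle(d, bundle.counts)
    paths.append(write_metadata(d / "metadata.tsv", bundle.metadata))
    paths.append(write_gmt(d / "markers.gmt", bundle.marker_sets))
    paths.append(write_gmt(d / "pathways.gmt", bundle.pathway_sets))
    paths.append(write_network_tsv(d / "network.tsv", bundle.network))
    gt = d / "ground_truth.json"
    with open(gt, "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)
    paths.append(gt)
    manifest = {
        "files": {p.name: file_sha256(p) for p in paths},
        "n_genes": int(bundle.counts.n_genes),
        "n_cells": int(bundle.counts.n_cells),
        "seed": int(bundle.config.seed),
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
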