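"""Over-representation analysis of classified DEG lists against GMT sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GeneSetCollection", "ora_test", "run_enrichment", "bh_adjust"]


@dataclass
class GeneSetCollection:
    """``sets``: set_id -> (description, frozenset of genes)."""

    sets: dict

    def __post_init__(self) -> None:
        clean = {}
        for sid, val in self.sets.items():
            desc, genes = val if isinstance(val, tuple) else ("na", val)
            genes = frozenset(map(str, genes))
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty")
            clean[sid] = (desc, genes)
        self.sets = clean

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def filtered(self, min_set: int, max_set: int) -> "GeneSetCollection":
        return GeneSetCollection(
            {
                sid: val
                for sid, val in self.sets.items()
                if min_set <= len(val[1]) <= max_set
            }
        )


def ora_test(deg_list, gene_set, universe) -> float:
    """One-sided hypergeometric upper tail P(X >= k).

    Population = |universe|, successes = |set|, draws = DEGs mapped into the
    universe (unmapped genes are dropped with a warning).
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    deg = set(map(str, deg_list))
    mapped = deg & universe
    if len(mapped) < len(deg):
        warnings.warn(
            f"{len(deg) - len(mapped)} DEGs not in the universe were dropped",
            stacklevel=2,
        )
    gene_set = set(map(str, gene_set)) & universe
    k = len(mapped & gene_set)
    return float(
        stats.hypergeom.sf(k - 1, len(universe), len(gene_set), len(mapped))
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_enrichment(
    class_gene_lists: dict,
    collection: GeneSetCollection,
    min_set: int = 10,
    max_set: int = 500,
    min_mapped: int = 3,
) -> pd.DataFrame:
    """ORA of each DEG class list against every retained gene set.

    ``class_gene_lists``: class label -> iterable of genes. Classes with
    fewer than ``min_mapped`` genes mapped into the universe are skipped with
    a warning. q values are BH-adjusted within each class; results sort by
    (q asc, gene_ratio desc). gene_ratio = overlap / mapped DEGs.
    """
    coll = collection.filtered(min_set, max_set)
    if not coll.sets:
        raise ValueError("no gene set survives the size filter")
    universe = coll.universe
    frames = []
    for cls in sorted(class_gene_lists):
        deg = set(map(str, class_gene_lists[cls]))
        mapped = sorted(deg & universe)
        n_mapped = len(mapped)
        if n_mapped < min_mapped:
            warnings.warn(
                f"DEG class {cls!r}: only {n_mapped} genes map to the "
                "collection; skipped",
                stacklevel=2,
            )
            continue
        mapped_set = set(mapped)
        rows = []
        for sid in sorted(coll.sets):
            desc, genes = coll.sets[sid]
            overlap = sorted(mapped_set & genes)
            k, m = len(overlap), len(genes)
            p = float(stats.hypergeom.sf(k - 1, len(universe), m, n_mapped))
            rows.append(
                {
                    "class": cls,
                    "set_id": sid,
                    "description": desc,
                    "k": k,
                    "m": m,
                    "gene_ratio": k / n_mapped,
                    "p": p,
                    "genes": ",".join(overlap),
                }
            )
        df = pd.DataFrame(rows)
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(
            ["q", "gene_ratio", "set_id"], ascending=[True, False, True]
        ).reset_index(drop=True)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "class", "set_id", "description", "k", "m",
                "gene_ratio", "p", "genes", "q",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    cols = ["class", "set_id", "description", "k", "m", "gene_ratio", "p", "q", "genes"]
    return out[cols]
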