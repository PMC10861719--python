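"""Readers and writers for the plain-text interchange formats.

Count matrices travel as Matrix Market triplets (matrix.mtx + features.tsv +
barcodes.tsv), per-cell metadata as TSV, gene sets as GMT, and prior-knowledge
networks as a four-column TSV (source, target, effect, category).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "read_counts_bundle",
    "write_counts_bundle",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_network_tsv",
    "write_network_tsv",
    "file_sha256",
]

GENOTYPES = ("TG", "WT")
GENDERS = ("M", "F")


@dataclass
class CountMatrix:
    """Sparse nonnegative integer gene x cell count matrix with axis labels."""

    matrix: sp.csr_matrix  # genes x cells
    gene_ids: np.ndarray  # str labels, unique
    cell_ids: np.ndarray  # str labels, unique

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != matrix cols {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids are not unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.matrix[:, idx].tocsr(), self.gene_ids, self.cell_ids[idx]
        )

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}


def write_counts_bundle(dir_path, counts: CountMatrix) -> list[Path]:
    """Write matrix.mtx / features.tsv / barcodes.tsv under ``dir_path``."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    mtx = d / "matrix.mtx"
    scipy.io.mmwrite(str(mtx), counts.matrix.tocoo(), field="integer")
    feats = d / "features.tsv"
    pd.DataFrame(
        {"gene_id": counts.gene_ids, "gene_symbol": counts.gene_ids}
    ).to_csv(feats, sep="\t", header=False, index=False)
    bcs = d / "barcodes.tsv"
    pd.Series(counts.cell_ids).to_csv(bcs, sep="\t", header=False, index=False)
    return [mtx, feats, bcs]


def read_counts_bundle(dir_path) -> CountMatrix:
    d = Path(dir_path)
    mtx = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx"))
    feats = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    bcs = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)
    return CountMatrix(
        mtx.astype(np.int64),
        feats.iloc[:, 1].to_numpy(dtype=object),
        bcs.iloc[:, 0].to_numpy(dtype=object),
    )


def write_metadata(path, metadata: pd.DataFrame) -> Path:
    """metadata columns: barcode, genotype, gender, cell_type."""
    required = {"barcode", "genotype", "gender", "cell_type"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    p = Path(path)
    metadata.to_csv(p, sep="\t", index=False)
    return p


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "genotype", "gender", "cell_type"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return md


def write_gmt(path, sets: dict) -> Path:
    """``sets``: name -> iterable of genes, or name -> (description, genes)."""
    p = Path(path)
    with open(p, "w") as fh:
        for name in sets:
            val = sets[name]
            if isinstance(val, tuple) and len(val) == 2:
                desc, genes = val
            else:
                desc, genes = "na", val
            fh.write("\t".join([name, desc, *sorted(map(str, genes))]) + "\n")
    return p


def read_gmt(path) -> dict:
    """Returns name -> (description, frozenset of genes)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return out


def write_network_tsv(path, edges: pd.DataFrame) -> Path:
    """edges columns: source, target, effect, category."""
    required = {"source", "target", "effect", "category"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"network table missing columns: {sorted(missing)}")
    p = Path(path)
    edges.to_csv(p, sep="\t", index=False)
    return p


def read_network_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "effect" not in df.columns:
        df["effect"] = "unknown"
    if "category" not in df.columns:
        df["category"] = "uncurated"
    df["effect"] = df["effect"].fillna("unknown")
    df["category"] = df["category"].fillna("uncurated")
    return df[["source", "target", "effect", "category"]]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
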