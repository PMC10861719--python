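"""Sex-stratified Poisson-GLM differential expression and pattern classes.

The model per gene is log mu = b0 + b1*[TG] + ln(exposure). With only the
group indicator and the exposure offset this GLM has a closed-form MLE
(group rate = group count sum / group exposure sum), so the likelihood-ratio
test is computed exactly rather than iteratively; logFC is b1 on the natural
log scale.

Gender-pattern classification of a gene within a cell type:
  neutral        q_m < 0.05 and q_f < 0.05, same logFC sign
  dimorphic      q_m < 0.05 and q_f < 0.05, opposite signs
  male_specific  q_m < 0.05 and q_f > 0.5 (and symmetric for female)
  unclassified   anything else (including the 0.05 <= q <= 0.5 buffer)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEResult",
    "GenderClass",
    "poisson_glm_test",
    "poisson_lrt_table",
    "bonferroni_adjust",
    "run_stratified_de",
    "classify_gender_pattern",
    "classify_table",
    "compute_pct_expressing",
    "compare_deg_sets",
    "Q_SIG",
    "Q_NULL",
]

Q_SIG = 0.05
Q_NULL = 0.5
CLASS_LABELS = (
    "neutral",
    "male_specific",
    "female_specific",
    "dimorphic",
    "unclassified",
)


@dataclass(frozen=True)
class DEResult:
    gene: str
    cell_type: str  # label or "ALL"
    gender: str
    logFC: float
    p: float
    q: float
    pct_tg: float
    pct_wt: float


@dataclass(frozen=True)
class GenderClass:
    gene: str
    cell_type: str
    label: str


def poisson_lrt_table(y_tg, e_tg, y_wt, e_wt):
    """Vectorized exact two-group Poisson LRT with exposure offsets.

    Arguments are per-gene arrays of group count sums and exposure sums.
    Returns (logFC, deviance, p). Genes with zero counts in both groups get
    logFC 0, deviance 0, p 1. When exactly one group is all-zero the rate
    ratio is undefined; a Haldane-style 0.5 is added to both count sums for
    the logFC only, keeping the deviance (and p) exact.
    """
    y_tg = np.atleast_1d(np.asarray(y_tg, dtype=float))
    y_wt = np.atleast_1d(np.asarray(y_wt, dtype=float))
    e_tg = np.broadcast_to(np.asarray(e_tg, dtype=float), y_tg.shape)
    e_wt = np.broadcast_to(np.asarray(e_wt, dtype=float), y_wt.shape)
    if (y_tg < 0).any() or (y_wt < 0).any():
        raise ValueError("negative counts")
    total = y_tg + y_wt
    pooled = total / (e_tg + e_wt)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * (_safe_term(y_tg, e_tg, pooled) + _safe_term(y_wt, e_wt, pooled))
    dev = np.where(total > 0, np.maximum(dev, 0.0), 0.0)
    p = np.where(total > 0, stats.chi2.sf(dev, df=1), 1.0)

    zero_one = ((y_tg == 0) ^ (y_wt == 0)) & (total > 0)
    num = np.where(zero_one, y_tg + 0.5, y_tg) / e_tg
    den = np.where(zero_one, y_wt + 0.5, y_wt) / e_wt
    with np.errstate(divide="ignore", invalid="ignore"):
        logfc = np.where(total > 0, np.log(num / den), 0.0)
    return logfc, dev, p


def _safe_term(y, e, pooled):
    """y * ln(rate_hat / pooled) with the 0*ln(0) = 0 convention."""
    rate = np.where(y > 0, y / e, 1.0)
    ref = np.where(y > 0, pooled, 1.0)
    return np.where(y > 0, y * np.log(rate / ref), 0.0)


def poisson_glm_test(counts_g, group, exposure):
    """Single-gene Poisson GLM LRT. ``group`` is a boolean TG indicator.

    Returns (logFC, p): logFC = ln(rate_TG / rate_WT), p from the LRT
    statistic against chi-square with one degree of freedom.
    """
    counts_g = np.asarray(counts_g, dtype=float)
    group = np.asarray(group, dtype=bool)
    exposure = np.asarray(exposure, dtype=float)
    if (counts_g < 0).any():
        raise ValueError("negative counts")
    if not group.any() or group.all():
        raise ValueError("both groups must be nonempty")
    logfc, _, p = poisson_lrt_table(
        counts_g[group].sum(),
        exposure[group].sum(),
        counts_g[~group].sum(),
        exposure[~group].sum(),
    )
    return float(logfc[0]), float(p[0])


def bonferroni_adjust(p_values, n_tests: int):
    """q = min(1, p * n_tests)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return np.minimum(p * n_tests, 1.0)


def compute_pct_expressing(counts_g, group):
    """Fractions of TG and WT cells with count > 0."""
    counts_g = np.asarray(counts_g)
    group = np.asarray(group, dtype=bool)
    if not group.any() or group.all():
        raise ValueError("both groups must be nonempty")
    return (
        float((counts_g[group] > 0).mean()),
        float((counts_g[~group] > 0).mean()),
    )


def run_stratified_de(
    counts,
    metadata: pd.DataFrame,
    cell_type_col: str = "cell_type",
    min_cells_detected: int = 3,
    include_all: bool = True,
) -> pd.DataFrame:
    """TG-vs-WT DE per (cell type, gender) stratum plus the (ALL, gender)
    cell-type-agnostic strata. Bonferroni is applied within each stratum over
    the genes actually tested there.

    ``metadata`` rows must align with ``counts.cell_ids`` (matched on the
    barcode column) and carry genotype in {TG, WT} and gender in {M, F}.
    Genes detected in fewer than ``min_cells_detected`` cells of a stratum
    are skipped for that stratum.
    """
    md = metadata.set_index("barcode").loc[list(counts.cell_ids)]
    genotype = md["genotype"].to_numpy()
    gender = md["gender"].to_numpy()
    celltype = md[cell_type_col].to_numpy()
    mat = counts.matrix.tocsr()
    exposure_all = np.asarray(mat.sum(axis=0)).ravel().astype(float)

    strata = [(ct, gd) for ct in pd.unique(celltype) for gd in ("M", "F")]
    if include_all:
        strata += [("ALL", gd) for gd in ("M", "F")]

    frames = []
    for ct, gd in strata:
        in_stratum = (gender == gd) & ((celltype == ct) | (ct == "ALL"))
        tg = in_stratum & (genotype == "TG")
        wt = in_stratum & (genotype == "WT")
        if not tg.any() or not wt.any():
            warnings.warn(
                f"stratum ({ct}, {gd}) lacks a genotype group; skipped",
                stacklevel=2,
            )
            continue
        tg_idx, wt_idx = np.flatnonzero(tg), np.flatnonzero(wt)
        sub = mat[:, np.concatenate([tg_idx, wt_idx])]
        n_tg = len(tg_idx)
        detected = np.asarray((sub > 0).sum(axis=1)).ravel()
        tested = detected >= min_cells_detected
        if not tested.any():
            warnings.warn(
                f"stratum ({ct}, {gd}) has no testable genes; skipped",
                stacklevel=2,
            )
            continue
        sub = sub[tested]
        genes = counts.gene_ids[tested]
        y_tg = np.asarray(sub[:, :n_tg].sum(axis=1)).ravel()
        y_wt = np.asarray(sub[:, n_tg:].sum(axis=1)).ravel()
        e_tg = exposure_all[tg_idx].sum()
        e_wt = exposure_all[wt_idx].sum()
        logfc, _, p = poisson_lrt_table(y_tg, e_tg, y_wt, e_wt)
        q = bonferroni_adjust(p, int(tested.sum()))
        pct_tg = np.asarray((sub[:, :n_tg] > 0).mean(axis=1)).ravel()
        pct_wt = np.asarray((sub[:, n_tg:] > 0).mean(axis=1)).ravel()
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cell_type": ct,
                    "gender": gd,
                    "logFC": logfc,
                    "p": p,
                    "q": q,
                    "pct_tg": pct_tg,
                    "pct_wt": pct_wt,
                }
            )
        )
    if not frames:
        raise ValueError("no stratum could be tested")
    return pd.concat(frames, ignore_index=True)


def classify_gender_pattern(de_m: DEResult, de_f: DEResult) -> GenderClass:
    """Apply the significance/sign rules to one gene's male and female tests."""
    if de_m.gene != de_f.gene or de_m.cell_type != de_f.cell_type:
        raise ValueError("male and female results must match gene and cell type")
    label = _classify(de_m.logFC, de_m.q, de_f.logFC, de_f.q, de_m.gene)
    return GenderClass(de_m.gene, de_m.cell_type, label)


def _classify(lfc_m, q_m, lfc_f, q_f, gene="?") -> str:
    if q_m < Q_SIG and q_f < Q_SIG:
        sm, sf = np.sign(lfc_m), np.sign(lfc_f)
        if sm == 0 or sf == 0:
            warnings.warn(
                f"gene {gene}: significant in both genders with zero logFC; "
                "direction undefined",
                stacklevel=3,
            )
            return "unclassified"
        return "neutral" if sm == sf else "dimorphic"
    if q_m < Q_SIG and q_f > Q_NULL:
        return "male_specific"
    if q_f < Q_SIG and q_m > Q_NULL:
        return "female_specific"
    return "unclassified"


def classify_table(de_results: pd.DataFrame) -> pd.DataFrame:
    """Classify every (gene, cell_type) present in the stratified DE table.

    A gene untested in one gender (below the detection filter there) is
    treated as q=1, logFC=0 in that gender, so it can still be called
    gender-specific from the other gender's test.
    """
    m = de_results[de_results["gender"] == "M"].set_index(["gene", "cell_type"])
    f = de_results[de_results["gender"] == "F"].set_index(["gene", "cell_type"])
    keys = sorted(set(m.index) | set(f.index))
    rows = []
    for gene, ct in keys:
        lm, qm = (
            (m.loc[(gene, ct), "logFC"], m.loc[(gene, ct), "q"])
            if (gene, ct) in m.index
            else (0.0, 1.0)
        )
        lf, qf = (
            (f.loc[(gene, ct), "logFC"], f.loc[(gene, ct), "q"])
            if (gene, ct) in f.index
            else (0.0, 1.0)
        )
        rows.append(
            {
                "gene": gene,
                "cell_type": ct,
                "label": _classify(lm, qm, lf, qf, gene),
                "logFC_m": float(lm),
                "q_m": float(qm),
                "logFC_f": float(lf),
                "q_f": float(qf),
            }
        )
    return pd.DataFrame(rows)


def compare_deg_sets(
    set_a: pd.DataFrame, set_b: pd.DataFrame, map_uppercase: bool = True
) -> pd.DataFrame:
    """Cross-dataset overlap of classified DEGs with direction concordance.

    Inputs are classify_table-shaped frames (gene, cell_type, label, logFC_m,
    logFC_f). ``map_uppercase`` maps both symbol sets to uppercase first
    (mouse -> human convention). Genes classified "unclassified" are ignored.
    Rows report, per (cell_type, label), genes present in both with a
    ``concordant`` flag (same sign of the class-defining logFC).
    """

    def prep(df):
        df = df[df["label"] != "unclassified"].copy()
        df["symbol"] = (
            df["gene"].str.upper() if map_uppercase else df["gene"].astype(str)
        )
        return df.set_index(["symbol", "cell_type", "label"])

    a, b = prep(set_a), prep(set_b)
    shared = sorted(set(a.index) & set(b.index))
    rows = []
    for sym, ct, label in shared:
        col = "logFC_f" if label == "female_specific" else "logFC_m"
        sa = np.sign(a.loc[(sym, ct, label), col])
        sb = np.sign(b.loc[(sym, ct, label), col])
        rows.append(
            {
                "symbol": sym,
                "cell_type": ct,
                "label": label,
                "concordant": bool(sa == sb),
            }
        )
    return pd.DataFrame(rows, columns=["symbol", "cell_type", "label", "concordant"])
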