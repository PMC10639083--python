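"""Cell-type expression and splicing metrics.

The proliferation-index style z-score metric: per feature (gene or intron metric),
z-scores are computed across *all* cell-type replicates (sample sd, n-1), then each
cell type is summarised by the mean of its replicates' z-scores; features constant
across samples are excluded (z undefined).  Gene-set scores use the median of the
top 50% of the set's z-scores.  Splicing efficiency per intron and sample is
EE / (EE + mean(IE)); samples with fewer than five reads on either junction class
are excluded, and per-cell-type values are weighted means with replicate weight
mean(IE) + EE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError
from .stats import bh_adjust


@dataclass
class ZScoreMatrix:
    zscores: pd.DataFrame            # retained features x samples, mean 0 / sd 1 rows
    celltype_means: pd.DataFrame     # features x cell types (mean replicate z)
    excluded_features: list[str]     # zero-variance rows


def zscore_by_feature(matrix: pd.DataFrame, design: pd.Series) -> ZScoreMatrix:
    """Standardise each feature across all samples and summarise per cell type."""
    if matrix.shape[1] < 2:
        raise InsufficientDataError("z-scores need >= 2 samples")
    if not set(matrix.columns) <= set(design.index):
        raise ParameterError("every sample column needs a cell-type assignment")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    excluded = list(matrix.index[~keep])
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    zdf = pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)
    celltype_means = zdf.T.groupby(design.loc[zdf.columns]).mean().T
    return ZScoreMatrix(zdf, celltype_means, excluded)


def group_score(z_values) -> float:
    """Median of the top 50% (ceil(n/2)) of a gene set's z-scores."""
    arr = np.sort(np.asarray(list(z_values), dtype=float))[::-1]
    if arr.size < 2:
        raise InsufficientDataError("group score needs >= 2 values")
    top = arr[: math.ceil(arr.size / 2)]
    return float(np.median(top))


def celltype_group_scores(zmat: ZScoreMatrix, gene_set) -> pd.Series:
    """Group score of a gene set in every cell type."""
    genes = [g for g in gene_set if g in zmat.celltype_means.index]
    if len(genes) < 2:
        raise InsufficientDataError("gene set has < 2 scorable members")
    sub = zmat.celltype_means.loc[genes]
    return sub.apply(lambda col: group_score(col.to_numpy()), axis=0)


# ---------------------------------------------------------------------------
# junction-based splicing metrics
# ---------------------------------------------------------------------------

def _prepare_junctions(junctions: pd.DataFrame, design: pd.Series | None) -> pd.DataFrame:
    df = junctions.copy()
    df["ie_mean"] = (df["ie_left"] + df["ie_right"]) / 2.0
    if design is not None:
        df["cell_type"] = design.loc[df["replicate"]].to_numpy()
    elif "cell_type" not in df:
        df["cell_type"] = "all"
    return df


def splicing_efficiency(
    junctions: pd.DataFrame,
    design: pd.Series | None = None,
    min_reads: int = 5,
    weight_scheme: str = "sum",
) -> pd.DataFrame:
    """Per-intron, per-cell-type weighted mean splicing efficiency.

    ``junctions`` columns: intron_id, replicate, ie_left, ie_right, ee.  A
    sample-intron pair is excluded when ee < min_reads or mean(ie) < min_reads.
    efficiency = ee / (ee + mean(ie)); replicate weight = mean(ie) + ee (the
    'sum' scheme) or mean(ie) * ee ('product').  Introns with every replicate
    filtered in a cell type are reported with NaN for that cell type.
    """
    if weight_scheme not in ("sum", "product"):
        raise ParameterError("weight_scheme must be 'sum' or 'product'")
    df = _prepare_junctions(junctions, design)
    df["efficiency"] = df["ee"] / (df["ee"] + df["ie_mean"])
    df["keep"] = (df["ee"] >= min_reads) & (df["ie_mean"] >= min_reads)
    df["weight"] = np.where(
        df["keep"],
        df["ie_mean"] + df["ee"] if weight_scheme == "sum" else df["ie_mean"] * df["ee"],
        0.0,
    )
    rows = []
    for (intron, ct), g in df.groupby(["intron_id", "cell_type"]):
        w = g.loc[g["keep"], "weight"]
        e = g.loc[g["keep"], "efficiency"]
        value = float((w * e).sum() / w.sum()) if w.sum() > 0 else float("nan")
        rows.append({"intron_id": intron, "cell_type": ct,
                     "efficiency": value, "n_replicates_used": int(g["keep"].sum()),
                     "weight_scheme": weight_scheme})
    return pd.DataFrame(rows)


def retention_weighted_mean(
    retention: pd.DataFrame,
    design: pd.Series | None = None,
    weight_scheme: str = "sum",
    drop_flags: tuple[str, ...] = ("LowSplicing", "LowCover"),
) -> pd.DataFrame:
    """Weighted mean of externally computed per-replicate retention values.

    ``retention`` columns: intron_id, replicate, retention, ie_left, ie_right, ee
    and optional 'flag'; flagged rows ('LowSplicing'/'LowCover') are dropped.  The
    weighting matches :func:`splicing_efficiency`; zero-weight replicates are
    ignored.
    """
    df = _prepare_junctions(retention, design)
    if "flag" in df.columns:
        df = df[~df["flag"].isin(drop_flags)]
    df["weight"] = (df["ie_mean"] + df["ee"] if weight_scheme == "sum"
                    else df["ie_mean"] * df["ee"])
    rows = []
    for (intron, ct), g in df.groupby(["intron_id", "cell_type"]):
        w, r = g["weight"], g["retention"]
        value = float((w * r).sum() / w.sum()) if w.sum() > 0 else float("nan")
        rows.append({"intron_id": intron, "cell_type": ct, "retention": value,
                     "n_replicates_used": int((w > 0).sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired gene-set comparisons
# ---------------------------------------------------------------------------

def geneset_paired_comparison(
    expression: pd.DataFrame,
    gene_set,
    cell_type_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank on a gene set's per-cell-type mean expression.

    ``expression`` is genes x cell types (per-gene means across replicates).  Each
    pair is tested two-sided over the same genes; BH correction across pairs.
    Requires >= 4 gene pairs per comparison.
    """
    genes = [g for g in gene_set if g in expression.index]
    if len(genes) < 4:
        raise InsufficientDataError("paired comparison needs >= 4 genes in the set")
    rows = []
    for a, b in cell_type_pairs:
        x, y = expression.loc[genes, a], expression.loc[genes, b]
        if (x == y).all():
            p = 1.0
        else:
            p = float(sps.wilcoxon(x, y, alternative="two-sided").pvalue)
        rows.append({"cell_type_a": a, "cell_type_b": b, "n_genes": len(genes),
                     "median_a": float(x.median()), "median_b": float(y.median()),
                     "p_wilcoxon": p})
    df = pd.DataFrame(rows)
    df["q_wilcoxon"] = bh_adjust(df["p_wilcoxon"])
    return df
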