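"""Gene-level aggregation of transcript statistics.

p-values are combined with Lancaster's weighted generalization of Fisher's
method using base-mean abundances as weights; expression LFCs with a
base-mean-weighted mean; the splicing LFC is the LFC of the transcript with
the smallest p-value. BH adjustment is applied separately per analysis,
*before* the expression and splicing tables are joined, because the two
analyses have distinct multiplicity universes (all genes vs multi-isoform
genes only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "lancaster",
    "aggregate_expression_lfc",
    "aggregate_splicing_lfc",
    "adjust_bh",
    "aggregate_to_genes",
    "pair_gene_results",
]

_P_FLOOR = 1e-320


def lancaster(p_values, weights, normalize: bool = False) -> float:
    """Combine p-values by Lancaster's method with non-negative weights.

    Each p-value is transformed to the upper quantile of a chi-square with
    weight-valued degrees of freedom (a gamma(w/2, scale 2) tail quantile);
    the sum is referred to a chi-square with the summed degrees of freedom.
    With all weights equal to 2 this is exactly Fisher's method. Zero-weight
    entries are dropped; ``normalize`` rescales weights to sum ``2n`` for
    Fisher comparability.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape or p.ndim != 1:
        raise ValueError("p_values and weights must be equal-length 1-d sequences")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    keep = w > 0
    if not keep.any():
        raise ValueError("all weights are zero")
    p, w = p[keep], w[keep]
    if normalize:
        w = w * (2.0 * len(w) / w.sum())
    p = np.clip(p, _P_FLOOR, 1.0)
    t = stats.chi2.isf(p, df=w).sum()
    return float(stats.chi2.sf(t, df=w.sum()))


def aggregate_expression_lfc(lfcs, base_means) -> float:
    """Base-mean-weighted mean log fold change."""
    lfc = np.asarray(lfcs, dtype=float)
    b = np.asarray(base_means, dtype=float)
    if lfc.shape != b.shape:
        raise ValueError("lfcs and base_means must have equal length")
    total = b.sum()
    if total <= 0:
        raise ValueError("all base means are zero")
    return float((lfc * b).sum() / total)


def aggregate_splicing_lfc(lfcs, p_values, transcript_ids=None) -> float:
    """LFC of the transcript with the smallest p-value.

    Ties on p are broken by larger ``|lfc|``, then by transcript-id
    lexicographic order, so the result is deterministic.
    """
    lfc = np.asarray(lfcs, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if lfc.shape != p.shape or lfc.size == 0:
        raise ValueError("lfcs and p_values must be equal-length, non-empty")
    ids = list(transcript_ids) if transcript_ids is not None else [str(i) for i in range(len(p))]
    order = sorted(range(len(p)), key=lambda i: (p[i], -abs(lfc[i]), ids[i]))
    return float(lfc[order[0]])


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, NaN-aware.

    NaN inputs propagate NaN and do not count toward the multiplicity
    correction. Output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def aggregate_to_genes(transcript_results: pd.DataFrame,
                       normalize_weights: bool = False) -> pd.DataFrame:
    """Collapse a one-analysis transcript table to gene level.

    Expects columns ``gene_id, transcript_id, p_value, lfc, base_mean,
    analysis`` (a single analysis). Returns a gene table with aggregated
    ``p_value``, BH-adjusted ``padj``, aggregated ``lfc`` (weighted mean for
    expression, lowest-p rule for splicing) and ``n_transcripts``.

    For the splicing analysis, a two-transcript gene contributes a single
    distinct test: its two within-gene contrasts are the same statistic with
    opposite sign, so only the higher-base-mean row enters the p-value
    aggregation (combining both would double-count one degree of freedom).
    """
    analyses = transcript_results["analysis"].unique()
    if len(analyses) != 1:
        raise ValueError("aggregate_to_genes expects a single-analysis table")
    analysis = analyses[0]

    df = transcript_results.copy()
    if analysis == "splicing":
        sizes = df.groupby("gene_id")["transcript_id"].transform("size")
        pick = (df.assign(_sz=sizes)
                  .sort_values(["gene_id", "base_mean", "transcript_id"],
                               ascending=[True, False, True]))
        drop = pick[(pick["_sz"] == 2)].duplicated("gene_id", keep="first")
        dup_rows = pick.index[(pick["_sz"] == 2)][drop.to_numpy()]
        df_for_p = df.drop(index=dup_rows)
    else:
        df_for_p = df
    w = df_for_p["base_mean"].to_numpy(dtype=float)
    p = df_for_p["p_value"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(w < 0):
        raise ValueError("base means must be non-negative")
    keep = w > 0
    dfk = df_for_p[keep]
    if dfk.empty:
        raise ValueError("all base-mean weights are zero")
    wk = w[keep]
    if normalize_weights:
        counts = dfk.groupby("gene_id")["p_value"].transform("size").to_numpy()
        wsum = dfk.assign(_w=wk).groupby("gene_id")["_w"].transform("sum").to_numpy()
        wk = wk * 2.0 * counts / wsum
    q = stats.chi2.isf(np.clip(p[keep], _P_FLOOR, 1.0), df=wk)
    gsum = (dfk.assign(_q=q, _w=wk)
               .groupby("gene_id", sort=True)[["_q", "_w"]].sum())
    p_gene = stats.chi2.sf(gsum["_q"].to_numpy(), df=gsum["_w"].to_numpy())

    n_tx = df.groupby("gene_id", sort=True).size()
    if analysis == "expression":
        wl = (df.assign(_wl=df["lfc"] * w, _w=w)
                .groupby("gene_id", sort=True)[["_wl", "_w"]].sum())
        lfc_gene = (wl["_wl"] / wl["_w"]).reindex(gsum.index).to_numpy()
    else:
        ordered = df.assign(_abs=df["lfc"].abs()).sort_values(
            ["gene_id", "p_value", "_abs", "transcript_id"],
            ascending=[True, True, False, True])
        lfc_gene = (ordered.drop_duplicates("gene_id").set_index("gene_id")["lfc"]
                    .reindex(gsum.index).to_numpy())

    out = pd.DataFrame({
        "gene_id": gsum.index,
        "n_transcripts": n_tx.reindex(gsum.index).to_numpy(),
        "lfc": lfc_gene,
        "p_value": p_gene,
    }).reset_index(drop=True)
    out["padj"] = adjust_bh(out["p_value"].to_numpy())
    return out


def pair_gene_results(expr: pd.DataFrame, splice: pd.DataFrame) -> pd.DataFrame:
    """Full outer join of the two gene-level analyses on ``gene_id``.

    Both inputs must already carry their own BH-adjusted ``padj`` (the
    adjustment universes are analysis-specific and must not be recomputed on
    the merged table). Splicing fields are NaN for genes absent from the
    splicing analysis (single-isoform genes).
    """
    for name, df in (("expression", expr), ("splicing", splice)):
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene rows in {name} table (e.g. {dup!r})")
    e = expr.rename(columns={"lfc": "lfc_expr", "p_value": "p_expr", "padj": "padj_expr"})
    s = splice.rename(columns={"lfc": "lfc_splice", "p_value": "p_splice",
                               "padj": "padj_splice"})
    s = s.drop(columns=[c for c in ("n_transcripts",) if c in s.columns])
    merged = e.merge(s, on="gene_id", how="outer")
    cols = ["gene_id", "n_transcripts", "lfc_expr", "p_expr", "padj_expr",
            "lfc_splice", "p_splice", "padj_splice"]
    return merged[cols]
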