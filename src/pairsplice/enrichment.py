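"""Over-representation analysis with analysis-specific backgrounds.

Expression and splicing significant-gene lists are tested against *separate*
universes: every gene tested for expression vs only multi-isoform genes
(single-isoform genes cannot be differentially spliced, so they must not
deflate the splicing background). Each gene set gets a one-sided
hypergeometric p-value, a relative risk

    RR = (overlap / gene_set_size) / (n_significant / n_background)

and the enrichment score ``log2(RR + 0.06)``; the additive offset keeps the
score finite at zero overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import adjust_bh
from .datamodel import GeneSetCollection

logger = logging.getLogger("pairsplice")

__all__ = ["ora", "paired_ora", "compare_enrichments", "ComparisonStats",
           "enrichment_score", "relative_risk"]

RR_OFFSET = 0.06


def relative_risk(overlap: int, gene_set_size: int, n_significant: int,
                  n_background: int) -> float:
    if gene_set_size == 0 or n_background == 0:
        return float("nan")
    if n_significant == 0:
        return float("nan")
    return (overlap / gene_set_size) / (n_significant / n_background)


def enrichment_score(rr: float) -> float:
    """log2 relative risk with a +0.06 offset (finite at zero overlap)."""
    return float(np.log2(rr + RR_OFFSET))


def ora(
    significant_genes: set[str],
    background: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Gene sets are intersected with ``background`` before testing; the
    reported ``gene_set_size`` is that post-intersection size, so the
    hypergeometric p and the relative risk describe the same 2x2 table.
    """
    if not background:
        raise ValueError("background (universe) is empty")
    extra = significant_genes - background
    if extra:
        raise ValueError(f"significant genes not in background: {sorted(extra)[:5]}")
    n_bg = len(background)
    n_sig = len(significant_genes)

    restricted = collection.restricted(background, min_size=max(min_set_size, 1),
                                       max_size=max_set_size)
    rows = []
    for name, genes in restricted:
        size = len(genes)
        overlap = sum(1 for g in genes if g in significant_genes)
        if n_sig == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, n_bg, size, n_sig))
        rr = relative_risk(overlap, size, n_sig, n_bg)
        rows.append((name, overlap, size, n_sig, n_bg, p, rr,
                     enrichment_score(rr) if np.isfinite(rr) else float("nan")))
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "gene_set_size",
                                      "n_significant", "n_background", "p_hyper",
                                      "relative_risk", "enrichment_score"])
    out["padj"] = adjust_bh(out["p_hyper"].to_numpy())
    out["significant"] = out["padj"] < alpha
    return out


def paired_ora(
    paired: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> pd.DataFrame:
    """Run both over-representation analyses and join them by gene set.

    ``paired`` is the gene-level paired result table. The expression
    background is every gene with an expression test; the splicing background
    only genes with a splicing test (multi-isoform). Significance per analysis
    is ``padj < alpha``. A gene significant in both analyses enters both
    significant lists.
    """
    expr_bg = set(paired.loc[paired["p_expr"].notna(), "gene_id"])
    splice_bg = set(paired.loc[paired["p_splice"].notna(), "gene_id"])
    all_set_genes = {g for _, genes in collection for g in genes}
    if not (all_set_genes & expr_bg) and not (all_set_genes & splice_bg):
        raise ValueError("gene-set collection shares no genes with either background")

    sig_expr = set(paired.loc[paired["padj_expr"] < alpha, "gene_id"])
    sig_splice = set(paired.loc[paired["padj_splice"] < alpha, "gene_id"])

    kwargs = dict(alpha=alpha, min_set_size=min_set_size, max_set_size=max_set_size)
    res_e = ora(sig_expr, expr_bg, collection, **kwargs)
    if splice_bg:
        res_s = ora(sig_splice & splice_bg, splice_bg, collection, **kwargs)
    else:  # no multi-isoform genes: splicing side is empty, not an error
        res_s = res_e.iloc[0:0].copy()
    joined = res_e.merge(res_s, on="set_name", how="outer",
                         suffixes=("_expr", "_splice"))
    return joined


@dataclass(frozen=True)
class ComparisonStats:
    """Agreement statistics between the two enrichment profiles."""

    spearman_rho: float
    median_rr_percent_change: float
    n_sets: int
    n_infinite_excluded: int = 0


def compare_enrichments(paired_ora_result: pd.DataFrame,
                        subset: str = "either") -> ComparisonStats:
    """Compare expression vs splicing enrichment over significant gene sets.

    ``subset`` selects which sets enter: significant in ``either`` analysis
    (default), in ``both``, or exclusively in one (``expr_only`` /
    ``splice_only``). The Spearman correlation is computed on the enrichment
    scores; the per-set percent change ``(max(RR) - min(RR)) / min(RR) * 100``
    on the *untransformed* relative risks, with ``min(RR) = 0`` sets excluded
    from the median (counted in ``n_infinite_excluded``).
    """
    df = paired_ora_result
    sig_e = df["significant_expr"].fillna(False).astype(bool)
    sig_s = df["significant_splice"].fillna(False).astype(bool)
    masks = {
        "either": sig_e | sig_s,
        "both": sig_e & sig_s,
        "expr_only": sig_e & ~sig_s,
        "splice_only": ~sig_e & sig_s,
    }
    if subset not in masks:
        raise ValueError(f"subset must be one of {sorted(masks)}")
    sel = df[masks[subset]]
    sel = sel[sel["relative_risk_expr"].notna() & sel["relative_risk_splice"].notna()]
    n = len(sel)

    if n < 3:
        rho = float("nan")
        logger.info("compare_enrichments: only %d set(s) in subset %r; "
                    "correlation undefined", n, subset)
    elif (sel["enrichment_score_expr"].nunique() <= 1
          or sel["enrichment_score_splice"].nunique() <= 1):
        rho = float("nan")  # rank correlation undefined on a constant vector
    else:
        rho = float(stats.spearmanr(sel["enrichment_score_expr"],
                                    sel["enrichment_score_splice"]).statistic)

    rr = sel[["relative_risk_expr", "relative_risk_splice"]].to_numpy(dtype=float)
    if n:
        lo = rr.min(axis=1)
        hi = rr.max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = (hi - lo) / lo * 100.0
        finite = np.isfinite(pct)
        n_inf = int((~finite).sum())
        median_pct = float(np.median(pct[finite])) if finite.any() else float("nan")
        if n_inf:
            logger.info("compare_enrichments: excluded %d set(s) with zero "
                        "minimum relative risk", n_inf)
    else:
        median_pct, n_inf = float("nan"), 0
    return ComparisonStats(spearman_rho=rho, median_rr_percent_change=median_pct,
                           n_sets=n, n_infinite_excluded=n_inf)
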