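"""Comparison-level summary statistics and the confounder expected-FDR estimator.

These are the per-comparison numbers a user needs to summarize how much of a
dataset's transcriptional signal is expression-driven vs splicing-driven, and
to estimate how many discoveries an uncorrected (no surrogate-variable)
analysis owes to confounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import adjust_bh

__all__ = ["ComparisonSummary", "summarize_comparison", "multi_dataset_union",
           "FdrEstimate", "confounder_fdr"]


@dataclass(frozen=True)
class ComparisonSummary:
    """Significance counts and fractions for one baseline-vs-case comparison.

    ``frac_de_also_ds`` — fraction of differentially expressed genes that are
    also differentially spliced. ``ds_fraction_of_signal`` — differentially
    spliced genes as a fraction of the total transcriptional signal (the union
    of significant genes from either analysis). ``median_isoform_contribution``
    — across dual-significant genes, the median fraction of a gene's abundance
    carried by its significantly spliced transcripts.
    """

    n_tested_expr: int
    n_tested_splice: int
    n_sig_expr: int
    n_sig_splice: int
    n_overlap: int
    frac_tested_sig_expr: float
    frac_tested_sig_splice: float
    frac_de_also_ds: float
    ds_fraction_of_signal: float
    median_isoform_contribution: float
    n_dual_significant: int


def summarize_comparison(
    paired: pd.DataFrame,
    transcript_results: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> ComparisonSummary:
    """Summarize a paired gene-level result table at significance ``alpha``.

    ``transcript_results`` (the stacked transcript table) is needed for the
    isoform-contribution statistic: within each dual-significant gene, the
    summed base mean of transcripts whose BH-adjusted splicing p (adjusted
    across all tested transcripts) is below ``alpha``, over the summed base
    mean of all the gene's transcripts.
    """
    tested_expr = paired["p_expr"].notna()
    tested_splice = paired["p_splice"].notna()
    sig_expr = paired["padj_expr"] < alpha
    sig_splice = paired["padj_splice"] < alpha

    n_te, n_ts = int(tested_expr.sum()), int(tested_splice.sum())
    n_se, n_ss = int(sig_expr.sum()), int(sig_splice.sum())
    n_overlap = int((sig_expr & sig_splice).sum())
    n_union = int((sig_expr | sig_splice).sum())

    contribution = float("nan")
    dual_genes = set(paired.loc[sig_expr & sig_splice, "gene_id"])
    if transcript_results is not None and dual_genes:
        tx = transcript_results[transcript_results["analysis"] == "splicing"].copy()
        tx["padj"] = adjust_bh(tx["p_value"].to_numpy())
        per_gene = []
        for gene, grp in tx[tx["gene_id"].isin(dual_genes)].groupby("gene_id"):
            total = grp["base_mean"].sum()
            if total > 0:
                sig_bm = grp.loc[grp["padj"] < alpha, "base_mean"].sum()
                per_gene.append(sig_bm / total)
        if per_gene:
            contribution = float(np.median(per_gene))

    return ComparisonSummary(
        n_tested_expr=n_te,
        n_tested_splice=n_ts,
        n_sig_expr=n_se,
        n_sig_splice=n_ss,
        n_overlap=n_overlap,
        frac_tested_sig_expr=n_se / n_te if n_te else float("nan"),
        frac_tested_sig_splice=n_ss / n_ts if n_ts else float("nan"),
        frac_de_also_ds=n_overlap / n_se if n_se else float("nan"),
        ds_fraction_of_signal=n_ss / n_union if n_union else float("nan"),
        median_isoform_contribution=contribution,
        n_dual_significant=len(dual_genes),
    )


def multi_dataset_union(significant_sets: list[set[str]],
                        multi_isoform_universe: set[str]) -> float:
    """Fraction of the multi-isoform universe significant in >= 1 comparison."""
    if not multi_isoform_universe:
        raise ValueError("multi-isoform universe is empty")
    if not significant_sets:
        raise ValueError("need at least one comparison")
    union: set[str] = set().union(*significant_sets)
    return len(union & multi_isoform_universe) / len(multi_isoform_universe)


@dataclass(frozen=True)
class FdrEstimate:
    """Expected false-discovery rate of an uncorrected analysis.

    Genes significant only without confounder correction are assumed false
    discoveries; genes significant in both carry a residual 5% false-discovery
    allowance (the nominal FDR of the corrected analysis).
    """

    n_false_positives: int
    n_shared: int
    n_without: int
    expected_fdr: float


def confounder_fdr(sig_with: set[str], sig_without: set[str]) -> FdrEstimate:
    """Estimate the expected FDR of the analysis run without confounder correction.

    ``expected_fdr = (|without \\ with| + 0.05 * |without ∩ with|) / |without|``,
    NaN when nothing is significant in the uncorrected analysis.
    """
    only_without = sig_without - sig_with
    shared = sig_without & sig_with
    n_without = len(sig_without)
    if n_without == 0:
        fdr = float("nan")
    else:
        fdr = (len(only_without) + 0.05 * len(shared)) / n_without
    return FdrEstimate(
        n_false_positives=len(only_without),
        n_shared=len(shared),
        n_without=n_without,
        expected_fdr=fdr,
    )
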