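"""End-to-end orchestration: filter → confounders → differential → aggregation → ORA.

The in-memory entry point is :func:`analyze` (count matrix + design in,
result bundle out); :func:`run_paired_analysis` adds file I/O, config
validation, TSV outputs and a JSON run manifest so every figure-level
statistic is re-derivable from the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import aggregate_to_genes, pair_gene_results
from .confounders import (SurrogateVariables, augment_design, estimate_num_sv,
                          fit_surrogate_variables)
from .datamodel import (GeneSetCollection, StudyDesign, TranscriptCountMatrix,
                        filter_low_expression, load_counts, read_gmt)
from .differential import logcpm, normalize_library_sizes, run_differential
from .enrichment import compare_enrichments, paired_ora
from .metrics import ComparisonSummary, FdrEstimate, confounder_fdr, summarize_comparison

logger = logging.getLogger("pairsplice")

__all__ = ["RunConfig", "PairedAnalysisResult", "analyze", "run_paired_analysis",
           "run_confounder_experiment"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    counts: str
    tx2gene: str
    metadata: str
    outdir: str
    gmt: str | None = None
    baseline: str | None = None
    alpha: float = 0.05
    min_mean: float = 10.0
    n_sv: str | int = "auto"  # 'auto', 0 disables correction
    min_set_size: int = 5
    max_set_size: int = 2000
    subset: str = "either"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_mean < 0:
            raise ValueError("min_mean must be >= 0")
        if isinstance(self.n_sv, str):
            if self.n_sv != "auto":
                raise ValueError("n_sv must be 'auto' or a non-negative integer")
        elif self.n_sv < 0:
            raise ValueError("n_sv must be 'auto' or a non-negative integer")
        if self.subset not in ("either", "both", "expr_only", "splice_only"):
            raise ValueError(f"invalid subset {self.subset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PairedAnalysisResult:
    """Everything one paired differential run produces."""

    transcript_results: pd.DataFrame
    gene_results: pd.DataFrame
    summary: ComparisonSummary
    surrogate_variables: SurrogateVariables
    design: StudyDesign
    ora_results: pd.DataFrame | None = None
    comparison_stats: object | None = None
    stage_counts: dict = field(default_factory=dict)


def analyze(
    tcm: TranscriptCountMatrix,
    design: StudyDesign,
    collection: GeneSetCollection | None = None,
    *,
    alpha: float = 0.05,
    min_mean: float = 10.0,
    n_sv: str | int = "auto",
    min_set_size: int = 5,
    max_set_size: int = 2000,
    subset: str = "either",
    seed: int = 0,
) -> PairedAnalysisResult:
    """Run the full paired differential expression / splicing analysis."""
    stage_counts = {"input_transcripts": tcm.n_transcripts,
                    "input_samples": tcm.n_samples}
    tcm = filter_low_expression(tcm, min_mean=min_mean)
    stage_counts["filtered_transcripts"] = tcm.n_transcripts
    stage_counts["multi_isoform_genes"] = len(tcm.multi_isoform_genes())

    Y = logcpm(tcm, lib_sizes=normalize_library_sizes(tcm.counts,
                                                      design.condition_indicator))
    if n_sv == "auto":
        k = estimate_num_sv(Y, design, seed=seed)
    else:
        k = int(n_sv)
    svs = fit_surrogate_variables(Y, design, n_sv=k)
    design_aug = augment_design(design, svs)
    stage_counts["n_surrogate_variables"] = svs.n_sv

    tx = run_differential(tcm, design_aug)
    expr_genes = aggregate_to_genes(tx[tx["analysis"] == "expression"])
    splice_genes = aggregate_to_genes(tx[tx["analysis"] == "splicing"])
    paired = pair_gene_results(expr_genes, splice_genes)
    stage_counts["genes_tested_expression"] = len(expr_genes)
    stage_counts["genes_tested_splicing"] = len(splice_genes)

    summary = summarize_comparison(paired, tx, alpha=alpha)

    ora_res = None
    cmp_stats = None
    if collection is not None:
        ora_res = paired_ora(paired, collection, alpha=alpha,
                             min_set_size=min_set_size, max_set_size=max_set_size)
        cmp_stats = compare_enrichments(ora_res, subset=subset)
        stage_counts["gene_sets_tested"] = len(ora_res)

    return PairedAnalysisResult(
        transcript_results=tx,
        gene_results=paired,
        summary=summary,
        surrogate_variables=svs,
        design=design_aug,
        ora_results=ora_res,
        comparison_stats=cmp_stats,
        stage_counts=stage_counts,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_paired_analysis(config: RunConfig) -> PairedAnalysisResult:
    """File-based pipeline run: load inputs, analyze, write outputs + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tcm, design = load_counts(config.counts, config.tx2gene, config.metadata,
                              baseline=config.baseline)
    collection = read_gmt(config.gmt) if config.gmt else None

    result = analyze(
        tcm, design, collection,
        alpha=config.alpha, min_mean=config.min_mean, n_sv=config.n_sv,
        min_set_size=config.min_set_size, max_set_size=config.max_set_size,
        subset=config.subset, seed=config.seed,
    )

    _write_tsv(result.transcript_results, outdir / "transcript_results.tsv")
    _write_tsv(result.gene_results, outdir / "gene_results.tsv")
    sv = result.surrogate_variables.sv_matrix
    sv_df = pd.DataFrame(sv, index=list(design.sample_ids),
                         columns=[f"SV{i + 1}" for i in range(sv.shape[1])])
    sv_df.index.name = "sample_id"
    sv_df.to_csv(outdir / "surrogate_variables.tsv", sep="\t", float_format="%.10g")
    if result.ora_results is not None:
        _write_tsv(result.ora_results, outdir / "ora_paired.tsv")

    summary_df = pd.DataFrame([dataclasses.asdict(result.summary)])
    _write_tsv(summary_df, outdir / "summary.tsv")

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)

    manifest = {
        "pairsplice_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_counts": result.stage_counts,
        "output_hashes": {
            p.name: _hash_file(p) for p in sorted(outdir.glob("*.tsv"))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", json.dumps(result.stage_counts))
    return result


def run_confounder_experiment(
    tcm: TranscriptCountMatrix,
    design: StudyDesign,
    *,
    alpha: float = 0.05,
    min_mean: float = 10.0,
    seed: int = 0,
) -> tuple[FdrEstimate, PairedAnalysisResult, PairedAnalysisResult]:
    """Expression analysis with vs without confounder correction on one input.

    Returns the expected-FDR estimate together with both runs. The corrected
    run estimates surrogate variables; the uncorrected run skips that step
    entirely; everything else is identical.
    """
    with_sv = analyze(tcm, design, alpha=alpha, min_mean=min_mean,
                      n_sv="auto", seed=seed)
    without_sv = analyze(tcm, design, alpha=alpha, min_mean=min_mean,
                         n_sv=0, seed=seed)
    sig_with = set(with_sv.gene_results.loc[
        with_sv.gene_results["padj_expr"] < alpha, "gene_id"])
    sig_without = set(without_sv.gene_results.loc[
        without_sv.gene_results["padj_expr"] < alpha, "gene_id"])
    est = confounder_fdr(sig_with, sig_without)
    if np.isnan(est.expected_fdr):
        logger.warning("no significant genes without correction; expected FDR undefined")
    return est, with_sv, without_sv
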