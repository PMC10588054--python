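"""Synthetic data generators with ground truth.

Two generators:

* :func:`simulate_counts` — negative-binomial transcript counts for a
  two-group design with designed differential expression (all of a gene's
  transcripts scaled), designed isoform switches (proportion mass moved
  between two transcripts, gene total preserved) and an optional planted
  multiplicative batch confounder, returning a truth table for benchmarking.
* :func:`simulate_enrichment_scenarios` — a gene-label-level simulation of
  the relative-risk enrichment score under four enrichment scenarios
  (splice / expr / both / random), with every size parameter jittered ±25%
  between replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import enrichment
from .datamodel import StudyDesign, TranscriptCountMatrix

__all__ = ["SimTruth", "simulate_counts", "simulate_enrichment_scenarios",
           "SCENARIOS"]

SCENARIOS = ("splice", "expr", "both", "random")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated dataset."""

    de_genes: frozenset
    ds_genes: frozenset
    multi_isoform_genes: frozenset
    batch_samples: frozenset
    batch_affected_genes: frozenset
    de_lfc: float
    switch_shift: float
    batch_lfc: float

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.multi_isoform_genes | self.de_genes |
                       self.batch_affected_genes | self.ds_genes)
        return pd.DataFrame({
            "gene_id": genes,
            "is_de": [g in self.de_genes for g in genes],
            "is_ds": [g in self.ds_genes for g in genes],
            "is_multi_isoform": [g in self.multi_isoform_genes for g in genes],
            "is_batch_affected": [g in self.batch_affected_genes for g in genes],
        })


def _pick_batch_half(rng: np.random.Generator, condition: np.ndarray) -> np.ndarray:
    """Half of the samples forming a strongly condition-confounded batch.

    A batch perfectly balanced across conditions is orthogonal to the contrast
    and not a confounder at all, while one drawn entirely from a single
    condition is unidentifiable from the condition effect. The generator
    plants the strongest identifiable confounder: the half is maximally
    condition-imbalanced while still containing at least one sample of each
    condition (e.g. 5 case + 1 baseline for a 6 vs 6 design). Which samples
    fill the two quotas is random.
    """
    n = len(condition)
    half = n // 2
    case_idx = np.flatnonzero(condition == 1)
    base_idx = np.flatnonzero(condition == 0)
    n_case_in = min(len(case_idx), half - 1)
    n_base_in = half - n_case_in
    if n_base_in > len(base_idx) or n_case_in < 1:
        raise ValueError("cannot form a batch half crossing both conditions")
    pick = np.zeros(n, dtype=bool)
    pick[rng.choice(case_idx, size=n_case_in, replace=False)] = True
    pick[rng.choice(base_idx, size=n_base_in, replace=False)] = True
    return pick


def simulate_counts(
    n_genes: int = 2000,
    frac_multi: float = 2 / 3,
    n_per_group: int = 6,
    de_frac: float = 0.2,
    ds_frac: float = 0.13,
    de_lfc: float = 1.0,
    switch_shift: float = 0.3,
    batch: str = "none",
    batch_lfc: float = 1.0,
    batch_gene_frac: float = 0.3,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[TranscriptCountMatrix, StudyDesign, SimTruth]:
    """Simulate a transcript count matrix with known DE / DS / batch structure.

    Multi-isoform genes (fraction ``frac_multi``) get 2–5 transcripts; gene
    baseline means are log-normal around 500 and isoform proportions flat
    Dirichlet. DE genes scale every transcript by ``2**de_lfc`` in the case
    group; DS genes move ``switch_shift`` of proportion mass from their major
    to a random other transcript in the case group, preserving the gene total.
    With ``batch='planted'`` a random condition-imbalanced half of the samples
    has ``batch_gene_frac`` of genes multiplied by ``2**batch_lfc``. Counts
    are negative binomial with variance ``mu + dispersion * mu**2``.
    Deterministic given ``seed``.
    """
    if not (0 <= de_frac <= 1 and 0 <= ds_frac <= 1 and 0 <= frac_multi <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if batch not in ("none", "planted"):
        raise ValueError("batch must be 'none' or 'planted'")

    rng = np.random.default_rng(seed)
    n_multi = int(round(n_genes * frac_multi))
    n_ds = int(round(n_genes * ds_frac))
    if n_ds > n_multi:
        raise ValueError(f"ds_frac={ds_frac} needs {n_ds} multi-isoform genes "
                         f"but only {n_multi} exist")
    if ds_frac > 0 and n_multi == 0:
        raise ValueError("no DS-eligible (multi-isoform) genes under these parameters")

    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    is_multi = np.zeros(n_genes, dtype=bool)
    is_multi[rng.choice(n_genes, size=n_multi, replace=False)] = True
    n_tx = np.where(is_multi, rng.integers(2, 6, size=n_genes), 1)

    gene_mean = rng.lognormal(mean=np.log(500.0), sigma=1.0, size=n_genes)

    de_idx = rng.choice(n_genes, size=int(round(n_genes * de_frac)), replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    multi_idx = np.flatnonzero(is_multi)
    ds_pick = rng.choice(len(multi_idx), size=n_ds, replace=False)
    is_ds = np.zeros(n_genes, dtype=bool)
    is_ds[multi_idx[ds_pick]] = True

    n_samples = 2 * n_per_group
    condition = np.array([0] * n_per_group + [1] * n_per_group)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]

    if batch == "planted":
        in_batch = _pick_batch_half(rng, condition)
        batch_gene = np.zeros(n_genes, dtype=bool)
        batch_gene[rng.choice(n_genes, size=int(round(n_genes * batch_gene_frac)),
                              replace=False)] = True
    else:
        in_batch = np.zeros(n_samples, dtype=bool)
        batch_gene = np.zeros(n_genes, dtype=bool)

    transcript_ids: list[str] = []
    gene_of: dict[str, str] = {}
    mu_rows: list[np.ndarray] = []
    for g in range(n_genes):
        k = n_tx[g]
        props = rng.dirichlet(np.ones(k))
        base_mu = gene_mean[g] * props  # per-transcript baseline means

        case_props = props.copy()
        if is_ds[g]:
            donor = int(np.argmax(props))
            others = [j for j in range(k) if j != donor]
            recipient = int(rng.choice(others))
            shift = min(switch_shift, 0.9 * props[donor])
            case_props[donor] -= shift
            case_props[recipient] += shift
        case_mu = gene_mean[g] * case_props
        if is_de[g]:
            case_mu = case_mu * 2.0**de_lfc

        mu = np.where(condition[None, :] == 1, case_mu[:, None], base_mu[:, None])
        if batch_gene[g]:
            mu = mu * np.where(in_batch[None, :], 2.0**batch_lfc, 1.0)
        mu_rows.append(mu)
        for t in range(k):
            tid = f"{gene_ids[g]}T{t + 1}"
            transcript_ids.append(tid)
            gene_of[tid] = gene_ids[g]

    mu_all = np.vstack(mu_rows)
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu_all))
    else:
        counts = rng.poisson(mu_all)

    tcm = TranscriptCountMatrix(
        counts=counts,
        transcript_ids=tuple(transcript_ids),
        sample_ids=tuple(sample_ids),
        gene_of=gene_of,
    )
    design = StudyDesign(
        sample_ids=tuple(sample_ids),
        condition=tuple("case" if c else "baseline" for c in condition),
        baseline="baseline",
        case="case",
    )
    truth = SimTruth(
        de_genes=frozenset(np.array(gene_ids)[is_de]),
        ds_genes=frozenset(np.array(gene_ids)[is_ds]),
        multi_isoform_genes=frozenset(np.array(gene_ids)[is_multi]),
        batch_samples=frozenset(np.array(sample_ids)[in_batch]),
        batch_affected_genes=frozenset(np.array(gene_ids)[batch_gene]),
        de_lfc=de_lfc,
        switch_shift=switch_shift,
        batch_lfc=batch_lfc,
    )
    return tcm, design, truth


def _jitter(rng: np.random.Generator, value: float, amount: float) -> int:
    return max(1, int(round(value * rng.uniform(1 - amount, 1 + amount))))


def simulate_enrichment_scenarios(
    n_sims: int = 1000,
    n_genes: int = 15000,
    n_multi: int = 10000,
    n_de: int = 3000,
    n_ds: int = 2000,
    set_size: int = 1000,
    n_enriched_added: int = 1000,
    jitter: float = 0.25,
    seed: int = 0,
    scenarios: tuple[str, ...] = SCENARIOS,
) -> pd.DataFrame:
    """Simulate enrichment-score differences under four enrichment scenarios.

    Per replicate, DE genes are drawn from all genes and DS genes from the
    multi-isoform subset; a random gene set of ``set_size`` genes receives
    ``n_enriched_added`` extra genes drawn from the DS genes (``splice``), the
    DE genes (``expr``), their union (``both``) or nothing (``random``). Both
    enrichment scores are computed with the analysis-specific universes (all
    genes vs multi-isoform genes) and their difference
    ``es_diff = es_expr - es_splice`` recorded. All parameters except
    ``n_genes`` and ``n_multi`` are jittered uniformly by ``±jitter`` per
    replicate. Deterministic given ``seed``.
    """
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenario(s): {sorted(unknown)}")
    if n_multi > n_genes:
        raise ValueError("n_multi cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    # gene indices 0..n_multi-1 are the multi-isoform genes
    records = []
    for scenario in scenarios:
        for sim in range(n_sims):
            k_de = min(_jitter(rng, n_de, jitter), n_genes)
            k_ds = min(_jitter(rng, n_ds, jitter), n_multi)
            k_set = min(_jitter(rng, set_size, jitter), n_genes)
            k_add = _jitter(rng, n_enriched_added, jitter)

            de = rng.choice(n_genes, size=k_de, replace=False)
            ds = rng.choice(n_multi, size=k_ds, replace=False)
            gene_set = set(rng.choice(n_genes, size=k_set, replace=False))

            if scenario == "expr":
                pool = de
            elif scenario == "splice":
                pool = ds
            elif scenario == "both":
                pool = np.union1d(de, ds)
            else:
                pool = None
            if pool is not None:
                k_add_eff = min(k_add, len(pool))
                gene_set |= set(rng.choice(pool, size=k_add_eff, replace=False))

            de_set = set(de.tolist())
            ds_set = set(ds.tolist())
            # both scores over the common all-genes universe: the simulation
            # probes the score's response to enriched gene labels, and a
            # shared universe is what centers the neutral scenarios at zero
            size = len(gene_set)
            rr_e = enrichment.relative_risk(len(gene_set & de_set), size,
                                            len(de_set), n_genes)
            rr_s = enrichment.relative_risk(len(gene_set & ds_set), size,
                                            len(ds_set), n_genes)
            es_e = enrichment.enrichment_score(rr_e)
            es_s = enrichment.enrichment_score(rr_s)
            records.append((scenario, sim, es_e, es_s, es_e - es_s))
    return pd.DataFrame(records, columns=["scenario", "sim", "es_expr",
                                          "es_splice", "es_diff"])
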