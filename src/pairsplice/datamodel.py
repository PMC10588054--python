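"""Core data containers and I/O.

Transcript-level count matrices with a transcript→gene map, the study design
(condition + covariates + surrogate variables), and GMT gene-set collections.
All readers canonicalize sample order to the metadata order so count columns
and design-matrix rows always align.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pairsplice")

__all__ = [
    "TranscriptCountMatrix",
    "StudyDesign",
    "GeneSetCollection",
    "load_counts",
    "read_gmt",
    "write_gmt",
    "filter_low_expression",
]


@dataclass(frozen=True)
class TranscriptCountMatrix:
    """Integer transcript × sample count matrix with a transcript→gene map.

    Parameters
    ----------
    counts
        Non-negative integer array, shape ``(n_transcripts, n_samples)``.
    transcript_ids, sample_ids
        Unique row / column labels.
    gene_of
        Mapping ``transcript_id -> gene_id``; every transcript must map to
        exactly one gene.
    """

    counts: np.ndarray
    transcript_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    gene_of: dict[str, str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional (transcripts x samples)")
        if counts.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.sample_ids)} samples"
            )
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise ValueError("duplicate transcript ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        bad = np.argwhere((counts < 0) | (counts != np.round(counts)))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-integer or negative count at transcript "
                f"'{self.transcript_ids[i]}', sample '{self.sample_ids[j]}': {counts[i, j]}"
            )
        missing = [t for t in self.transcript_ids if t not in self.gene_of]
        if missing:
            raise ValueError(f"transcripts missing from gene map: {missing[:5]}")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def gene_ids(self) -> np.ndarray:
        """Per-transcript gene id, aligned with the rows of ``counts``."""
        return np.asarray([self.gene_of[t] for t in self.transcript_ids])

    def transcripts_per_gene(self) -> pd.Series:
        return pd.Series(self.gene_ids).value_counts()

    def multi_isoform_genes(self) -> set[str]:
        """Genes with >= 2 transcripts in the *current* matrix (never cached)."""
        tpg = self.transcripts_per_gene()
        return set(tpg.index[tpg >= 2])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.transcript_ids), columns=list(self.sample_ids)
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "transcript_id"
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class StudyDesign:
    """Two-group study design with optional covariates and surrogate variables.

    The design matrix is ``[intercept | condition indicator | covariates | SVs]``
    with the condition column coding ``baseline=0, case=1`` so fitted
    coefficients are case-vs-baseline log fold changes.
    """

    sample_ids: tuple[str, ...]
    condition: tuple[str, ...]
    baseline: str
    case: str
    known_covariates: pd.DataFrame | None = None
    surrogate_variables: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.condition):
            raise ValueError("condition length must match sample_ids")
        levels = set(self.condition)
        if levels != {self.baseline, self.case}:
            raise ValueError(
                f"condition must have exactly the two levels "
                f"{{{self.baseline!r}, {self.case!r}}}, got {sorted(levels)}"
            )
        for level in (self.baseline, self.case):
            n = sum(c == level for c in self.condition)
            if n < 2:
                raise ValueError(f"condition level {self.baseline!r}/{self.case!r}: "
                                 f"level {level!r} has {n} < 2 samples")
        X = self.design_matrix()
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"design matrix is rank deficient (columns: {list(X.columns)})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def condition_indicator(self) -> np.ndarray:
        """0/1 vector, 1 for case samples."""
        return np.asarray([1.0 if c == self.case else 0.0 for c in self.condition])

    def design_matrix(self) -> pd.DataFrame:
        n = self.n_samples
        cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
        cols[f"condition[{self.case}]"] = self.condition_indicator
        if self.known_covariates is not None:
            cov = self.known_covariates
            for name in cov.columns:
                col = cov[name]
                if pd.api.types.is_numeric_dtype(col):
                    cols[name] = col.to_numpy(dtype=float)
                else:
                    dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                    for dname in dummies.columns:
                        cols[dname] = dummies[dname].to_numpy(dtype=float)
        if self.surrogate_variables is not None and self.surrogate_variables.size:
            sv = np.atleast_2d(np.asarray(self.surrogate_variables, dtype=float))
            if sv.shape[0] != n:
                raise ValueError("surrogate variable matrix must have one row per sample")
            for k in range(sv.shape[1]):
                cols[f"SV{k + 1}"] = sv[:, k]
        return pd.DataFrame(cols, index=list(self.sample_ids))

    def with_surrogate_variables(self, sv_matrix: np.ndarray) -> "StudyDesign":
        return replace(self, surrogate_variables=np.asarray(sv_matrix, dtype=float))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), with per-set descriptions."""

    sets: dict[str, tuple[str, ...]]
    source_label: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, ...]] = {}
        for name, genes in self.sets.items():
            uniq = tuple(dict.fromkeys(genes))  # dedupe, keep order
            if not uniq:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = uniq
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restricted(self, universe: set[str], min_size: int = 1,
                   max_size: int | None = None) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and drop sets outside the size band."""
        out: dict[str, tuple[str, ...]] = {}
        desc: dict[str, str] = {}
        for name, genes in self.sets.items():
            kept = tuple(g for g in genes if g in universe)
            if len(kept) < min_size:
                continue
            if max_size is not None and len(kept) > max_size:
                continue
            out[name] = kept
            if name in self.descriptions:
                desc[name] = self.descriptions[name]
        return GeneSetCollection(sets=out, source_label=self.source_label, descriptions=desc)


# ---------------------------------------------------------------------------
# readers / writers


def _read_counts_table(counts_path: Path) -> pd.DataFrame:
    suffix = counts_path.suffix.lower()
    if suffix == ".mtx":
        from scipy.io import mmread

        stem = counts_path.with_suffix("")
        rownames = Path(f"{stem}.rownames.txt")
        colnames = Path(f"{stem}.colnames.txt")
        for sidecar in (rownames, colnames):
            if not sidecar.exists():
                raise FileNotFoundError(f"MTX sidecar file missing: {sidecar}")
        mat = np.asarray(mmread(counts_path).todense())
        rows = rownames.read_text().split()
        cols = colnames.read_text().split()
        return pd.DataFrame(mat, index=rows, columns=cols)
    sep = "," if suffix == ".csv" else "\t"
    return pd.read_csv(counts_path, sep=sep, index_col=0)


def load_counts(
    counts_path: str | Path,
    tx2gene_path: str | Path,
    metadata_path: str | Path,
    *,
    baseline: str | None = None,
) -> tuple[TranscriptCountMatrix, StudyDesign]:
    """Load a transcript count matrix, its gene map and the sample metadata.

    ``counts_path`` may be TSV/CSV (first column transcript ids, header sample
    ids) or MatrixMarket ``.mtx`` with ``<stem>.rownames.txt`` /
    ``<stem>.colnames.txt`` sidecars. ``tx2gene_path`` is a headerless
    two-column TSV ``(transcript_id, gene_id)``. ``metadata_path`` is a TSV
    with columns ``sample_id``, ``condition`` and optional covariates.

    Samples are reordered to metadata order; transcripts absent from the gene
    map are dropped with a warning. Fractional counts are rounded half-to-even
    with a warning. ``baseline`` names the reference condition level; default
    is the first level in metadata order.
    """
    counts_path, tx2gene_path, metadata_path = map(Path, (counts_path, tx2gene_path, metadata_path))
    df = _read_counts_table(counts_path)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    missing_samples = [s for s in meta["sample_id"] if s not in df.columns]
    if missing_samples:
        raise ValueError(f"sample(s) in metadata but not in counts: {missing_samples}")
    extra = [s for s in df.columns if s not in set(meta["sample_id"])]
    if extra:
        logger.info("dropping %d count column(s) absent from metadata: %s", len(extra), extra[:5])
    df = df[list(meta["sample_id"])]

    t2g = pd.read_csv(tx2gene_path, sep="\t", header=None, names=["transcript_id", "gene_id"],
                      dtype=str)
    gene_of_full = dict(zip(t2g["transcript_id"], t2g["gene_id"]))
    unmapped = [t for t in df.index if t not in gene_of_full]
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} transcript(s) absent from tx2gene "
            f"(e.g. {unmapped[:3]})",
            stacklevel=2,
        )
        df = df.drop(index=unmapped)
    logger.info("loaded %d transcripts x %d samples", df.shape[0], df.shape[1])

    values = df.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative count at transcript '{df.index[i]}', sample '{df.columns[j]}'"
        )
    if not np.allclose(values, np.round(values)):
        warnings.warn("fractional counts rounded half-to-even on ingest", stacklevel=2)
        values = np.round(values)

    tcm = TranscriptCountMatrix(
        counts=values,
        transcript_ids=tuple(df.index),
        sample_ids=tuple(df.columns),
        gene_of={t: gene_of_full[t] for t in df.index},
    )

    levels = list(dict.fromkeys(meta["condition"]))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 condition levels, got {levels}")
    if baseline is None:
        baseline = levels[0]
    if baseline not in levels:
        raise ValueError(f"baseline {baseline!r} not among condition levels {levels}")
    case = next(lv for lv in levels if lv != baseline)

    covar_cols = [c for c in meta.columns if c not in ("sample_id", "condition")]
    covariates = None
    if covar_cols:
        covariates = meta[covar_cols].copy()
        for c in covar_cols:
            covariates[c] = pd.to_numeric(covariates[c], errors="ignore")
        covariates.index = list(meta["sample_id"])

    design = StudyDesign(
        sample_ids=tuple(meta["sample_id"]),
        condition=tuple(meta["condition"]),
        baseline=baseline,
        case=case,
        known_covariates=covariates,
    )
    return tcm, design


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = tuple(dict.fromkeys(genes))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, source_label=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_low_expression(tcm: TranscriptCountMatrix, min_mean: float = 10) -> TranscriptCountMatrix:
    """Drop transcripts whose mean raw count across all samples is below ``min_mean``.

    The boundary is inclusive: a transcript with mean exactly ``min_mean`` is
    kept. Raises if nothing survives.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    keep = tcm.counts.mean(axis=1) >= min_mean
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"no transcripts pass mean-count filter >= {min_mean}; lower the threshold"
        )
    logger.info("low-expression filter: removed %d of %d transcripts",
                n_removed, tcm.n_transcripts)
    kept_ids = tuple(t for t, k in zip(tcm.transcript_ids, keep) if k)
    return TranscriptCountMatrix(
        counts=tcm.counts[keep],
        transcript_ids=kept_ids,
        sample_ids=tcm.sample_ids,
        gene_of={t: tcm.gene_of[t] for t in kept_ids},
    )
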