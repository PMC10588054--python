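"""Moderated linear-model engine for transcript-level differential analysis.

Two analyses share one weighted least-squares fit per transcript on log2-CPM:

* **expression** — the condition coefficient is tested with an empirical-Bayes
  moderated t-statistic (residual variances shrunk toward a scaled-F prior
  estimated by moment matching).
* **splicing** — each transcript's condition log fold change is contrasted
  against the precision-weighted average LFC of the *other* transcripts of the
  same gene (leave-one-out centering), so only relative isoform-usage changes
  are detected. Single-isoform genes produce no splicing rows.

Count heteroscedasticity is handled with mean-variance precision weights:
per-transcript residual SDs are smoothed against average log-count with a
locally weighted regression and each observation receives the inverse fourth
power of the trend at its fitted log-count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datamodel import StudyDesign, TranscriptCountMatrix

__all__ = [
    "logcpm",
    "base_mean_cpm",
    "effective_library_sizes",
    "recenter_library_sizes",
    "normalize_library_sizes",
    "PrecisionWeights",
    "fit_precision_weights",
    "fit_moderated_expression",
    "fit_splicing",
    "run_differential",
    "adapt_external_results",
]

RESULT_COLUMNS = ["transcript_id", "gene_id", "base_mean", "lfc", "se", "t_stat",
                  "p_value", "analysis"]


def _tmm_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() < 10:
        return 1.0
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # delta-method variance of M for binomial-like sampling
    v = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) \
        + (lib_ref - ref[keep]) / (lib_ref * ref[keep])
    n = len(M)
    loM = np.floor(n * logratio_trim) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * sum_trim) + 1
    hiA = n + 1 - loA
    rM = stats.rankdata(M)
    rA = stats.rankdata(A)
    keep2 = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(2.0**f)


def effective_library_sizes(counts: np.ndarray) -> np.ndarray:
    """Composition-robust effective library sizes (trimmed mean of M-values).

    Raw column totals are biased when a sizeable minority of transcripts
    changes in one direction (20% of transcripts doubling in one condition
    drags every other transcript's rate down). Each sample's scale factor is
    a doubly trimmed, precision-weighted mean of log count ratios against a
    reference sample (the one whose upper quartile is closest to the mean
    upper quartile); effective sizes are raw sizes times these factors,
    rescaled so factors have geometric mean one.
    """
    counts = np.asarray(counts, dtype=float)
    lib_raw = counts.sum(axis=0)
    q75 = np.quantile(counts / lib_raw, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    nf = np.array([
        _tmm_factor(counts[:, j], counts[:, ref_idx], lib_raw[j], lib_raw[ref_idx])
        if j != ref_idx else 1.0
        for j in range(counts.shape[1])
    ])
    nf = nf / np.exp(np.mean(np.log(nf)))
    return lib_raw * nf


def recenter_library_sizes(counts: np.ndarray, lib_sizes: np.ndarray,
                           condition: np.ndarray, bw: float = 0.25) -> np.ndarray:
    """Remove residual between-group normalization offset by mode recentring.

    Even a trimmed normalization retains bias when a sizeable minority of
    transcripts changes in one direction and the change overlaps the counting
    noise. Assuming most transcripts are unchanged (the same assumption every
    global-scaling normalization makes), the mode of the per-transcript
    between-group difference in log-CPM identifies the null peak; half the
    mode is folded into each group's library sizes. Within-gene (splicing)
    contrasts are invariant to this common shift.
    """
    counts = np.asarray(counts, dtype=float)
    cond = np.asarray(condition, dtype=bool)
    if counts.shape[0] < 50 or cond.all() or not cond.any():
        return np.asarray(lib_sizes, dtype=float)
    Y = np.log2((counts + 0.5) / (np.asarray(lib_sizes, dtype=float) + 1.0) * 1e6)
    d = Y[:, cond].mean(axis=1) - Y[:, ~cond].mean(axis=1)
    kde = stats.gaussian_kde(d, bw_method=bw)
    grid = np.linspace(np.quantile(d, 0.02), np.quantile(d, 0.98), 1024)
    mode = float(grid[np.argmax(kde(grid))])
    return np.asarray(lib_sizes, dtype=float) * np.where(cond, 2.0**(mode / 2.0),
                                                         2.0**(-mode / 2.0))


def normalize_library_sizes(counts: np.ndarray,
                            condition: np.ndarray | None = None) -> np.ndarray:
    """TMM effective library sizes, optionally mode-recentred on the contrast."""
    lib = effective_library_sizes(counts)
    if condition is not None:
        lib = recenter_library_sizes(counts, lib, condition)
    return lib


def logcpm(tcm: TranscriptCountMatrix | np.ndarray,
           lib_sizes: np.ndarray | None = None) -> np.ndarray:
    """log2 counts-per-million with offsets: ``log2((c + 0.5)/(lib + 1) * 1e6)``.

    The half-count offset keeps zeros finite; the +1 on the library size keeps
    the transform bounded above by log2 of 1e6 times the largest proportion.
    ``lib_sizes`` defaults to the column sums; pass
    :func:`effective_library_sizes` output for composition-robust rates.
    """
    counts = tcm.counts if isinstance(tcm, TranscriptCountMatrix) else np.asarray(tcm)
    lib = counts.sum(axis=0).astype(float) if lib_sizes is None else np.asarray(lib_sizes, dtype=float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = (
            [tcm.sample_ids[j] for j in zero]
            if isinstance(tcm, TranscriptCountMatrix)
            else list(zero)
        )
        raise ValueError(f"sample(s) with all-zero counts: {names}")
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def base_mean_cpm(tcm: TranscriptCountMatrix,
                  lib_sizes: np.ndarray | None = None) -> np.ndarray:
    """Mean CPM per transcript across all samples (library-size invariant).

    Used downstream as the gene-level aggregation weight.
    """
    lib = tcm.counts.sum(axis=0).astype(float) if lib_sizes is None else np.asarray(lib_sizes, dtype=float)
    cpm = tcm.counts / lib * 1e6
    return cpm.mean(axis=1)


@dataclass(frozen=True)
class PrecisionWeights:
    """Observation-level precision weights and the mean-variance trend.

    ``trend_x``/``trend_y`` tabulate the smoothed sqrt-residual-SD against
    average log-count; ``weights`` is the inverse fourth power of the trend
    evaluated at each observation's fitted log-count.
    """

    weights: np.ndarray
    trend_x: np.ndarray
    trend_y: np.ndarray

    def predict_sqrt_sd(self, log_count: np.ndarray) -> np.ndarray:
        return np.interp(log_count, self.trend_x, self.trend_y)


def _ols_residual_stats(Y: np.ndarray, X: np.ndarray):
    """Unweighted OLS per row of Y: fitted values, residual SD, residual df."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T                      # (G, p)
    fitted = beta @ X.T                    # (G, n)
    resid = Y - fitted
    df = n - p
    if df <= 0:
        raise ValueError("not enough replicates: residual df <= 0")
    sigma = np.sqrt((resid**2).sum(axis=1) / df)
    return fitted, sigma, df


def fit_precision_weights(
    log_expr: np.ndarray,
    design: StudyDesign,
    span: float = 0.5,
    lib_sizes: np.ndarray | None = None,
) -> PrecisionWeights:
    """Estimate mean-variance precision weights for log-CPM data.

    Per-transcript residual SDs from an ordinary least-squares fit are
    smoothed (sqrt scale) against average log-count with lowess; each
    observation's weight is ``trend(fitted log-count) ** -4``. When
    ``lib_sizes`` is given, log-CPM values are shifted to the log-count scale
    per sample, as the trend is a property of counts, not rates.
    """
    Y = np.asarray(log_expr, dtype=float)
    if Y.shape[0] < 10:
        raise ValueError("need >= 10 transcripts to fit a mean-variance trend")
    X = design.design_matrix().to_numpy()
    fitted, sigma, _ = _ols_residual_stats(Y, X)

    if lib_sizes is not None:
        shift = np.log2(np.asarray(lib_sizes, dtype=float) + 1.0) - np.log2(1e6)
    else:
        shift = np.zeros(Y.shape[1])
    sx = Y.mean(axis=1) + shift.mean()
    sy = np.sqrt(sigma)

    if np.ptp(sx) < 1e-12:
        warnings.warn("degenerate mean-variance trend (all means identical); "
                      "using uniform weights", stacklevel=2)
        w = np.ones_like(Y)
        return PrecisionWeights(weights=w, trend_x=np.array([sx[0]]),
                                trend_y=np.array([max(sy.mean(), 1e-6)]))

    smooth = lowess(sy, sx, frac=span, return_sorted=True)
    trend_x, trend_y = smooth[:, 0], np.maximum(smooth[:, 1], 1e-6)
    # de-duplicate x for interpolation
    trend_x, idx = np.unique(trend_x, return_index=True)
    trend_y = trend_y[idx]

    fitted_logcount = fitted + shift[None, :]
    pred = np.interp(fitted_logcount, trend_x, trend_y)
    w = pred**-4.0
    return PrecisionWeights(weights=w, trend_x=trend_x, trend_y=trend_y)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (monotone decreasing)
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed residual variances.

    Returns ``(prior_df, prior_var)``. Sample variances ``s2`` with ``df``
    residual degrees of freedom are assumed ``s0^2 * F(df, d0)`` scaled;
    matching the mean and variance of ``log(s2)`` (via di/trigamma identities)
    yields the prior. ``prior_df`` is ``inf`` when the observed spread of
    log-variances does not exceed its sampling expectation.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


def _posterior_var(s2: np.ndarray, df: float, d0: float, s02: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s02)
    return (d0 * s02 + df * s2) / (d0 + df)


def _p_from_t(t: np.ndarray, df: float) -> np.ndarray:
    if np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def _wls_condition_fit(Y: np.ndarray, W: np.ndarray, X: np.ndarray, coef_idx: int):
    """Weighted least squares per transcript, vectorized over transcripts.

    Returns ``(beta, u2, s2, df)``: condition coefficient, its unscaled
    variance ``[ (X'WX)^-1 ]_cc``, residual variance, residual df.
    """
    G, n = Y.shape
    p = X.shape[1]
    df = n - p
    if df <= 0:
        raise ValueError("not enough replicates: residual df <= 0")
    # A_g = X' diag(w_g) X ; b_g = X' diag(w_g) y_g
    A = np.einsum("si,gs,sj->gij", X, W, X, optimize=True)
    b = np.einsum("si,gs->gi", X, W * Y, optimize=True)
    beta_all = np.linalg.solve(A, b[..., None])[..., 0]   # (G, p)
    resid = Y - beta_all @ X.T
    s2 = (W * resid**2).sum(axis=1) / df
    Ainv = np.linalg.inv(A)
    u2 = Ainv[:, coef_idx, coef_idx]
    return beta_all[:, coef_idx], u2, s2, df


def _condition_column(design: StudyDesign) -> int:
    cols = list(design.design_matrix().columns)
    return cols.index(f"condition[{design.case}]")


def fit_moderated_expression(
    log_expr: np.ndarray,
    weights: PrecisionWeights,
    design: StudyDesign,
    *,
    transcript_ids=None,
    gene_of: dict[str, str] | None = None,
    base_means: np.ndarray | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Transcript-level differential expression with moderated t-statistics.

    ``prior_df`` overrides the estimated prior degrees of freedom: ``0`` gives
    ordinary per-transcript WLS t-statistics, ``inf`` pools all transcripts to
    one common variance.
    """
    Y = np.asarray(log_expr, dtype=float)
    Xdf = design.design_matrix()
    X = Xdf.to_numpy()
    ci = _condition_column(design)
    beta, u2, s2, df = _wls_condition_fit(Y, weights.weights, X, ci)

    if prior_df is None:
        d0, s02 = estimate_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s02 = 0.0, 1.0
    else:
        d0 = float(prior_df)
        _, s02 = estimate_variance_prior(s2, df)
    s2_post = _posterior_var(s2, df, d0, s02) if d0 > 0 else s2
    se = np.sqrt(u2 * s2_post)
    t = beta / se
    p = _p_from_t(t, df + d0)

    ids = _resolve_ids(transcript_ids, Y.shape[0])
    genes = [gene_of[t_] for t_ in ids] if gene_of else ids
    bm = np.ones(Y.shape[0]) if base_means is None else np.asarray(base_means, dtype=float)
    return pd.DataFrame({
        "transcript_id": ids, "gene_id": genes, "base_mean": bm,
        "lfc": beta, "se": se, "t_stat": t, "p_value": p,
        "analysis": "expression",
    })


def fit_splicing(
    log_expr: np.ndarray,
    weights: PrecisionWeights,
    design: StudyDesign,
    gene_of: dict[str, str],
    *,
    transcript_ids=None,
    base_means: np.ndarray | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Within-gene differential transcript usage (splicing) test.

    For each transcript of a multi-isoform gene, the relative LFC is its
    condition LFC minus the precision-weighted mean LFC of the gene's *other*
    transcripts; the contrast variance adds the variance of that leave-one-out
    mean. Genes with a single transcript are not tested.
    """
    Y = np.asarray(log_expr, dtype=float)
    ids = _resolve_ids(transcript_ids, Y.shape[0])
    missing = [t_ for t_ in ids if t_ not in gene_of]
    if missing:
        raise ValueError(f"gene map missing tested transcript(s): {missing[:5]}")
    genes = np.asarray([gene_of[t_] for t_ in ids])

    X = design.design_matrix().to_numpy()
    ci = _condition_column(design)
    beta, u2, s2, df = _wls_condition_fit(Y, weights.weights, X, ci)

    # leave-one-out precision-weighted gene mean of the condition LFC
    w = 1.0 / u2
    gene_codes, _ = pd.factorize(genes)
    W_sum = np.bincount(gene_codes, weights=w)
    S_sum = np.bincount(gene_codes, weights=w * beta)
    n_tx = np.bincount(gene_codes)
    multi = n_tx[gene_codes] >= 2

    W_others = W_sum[gene_codes] - w
    rel_lfc = beta - np.where(multi, (S_sum[gene_codes] - w * beta) /
                              np.where(multi, W_others, 1.0), 0.0)
    u2_rel = u2 + np.where(multi, 1.0 / np.where(multi, W_others, 1.0), 0.0)

    if prior_df is None:
        d0, s02 = estimate_variance_prior(s2[multi], df)
    elif prior_df == 0:
        d0, s02 = 0.0, 1.0
    else:
        d0 = float(prior_df)
        _, s02 = estimate_variance_prior(s2[multi], df)
    s2_post = _posterior_var(s2, df, d0, s02) if d0 > 0 else s2
    se = np.sqrt(u2_rel * s2_post)
    t = rel_lfc / se
    p = _p_from_t(t, df + d0)

    bm = np.ones(Y.shape[0]) if base_means is None else np.asarray(base_means, dtype=float)
    out = pd.DataFrame({
        "transcript_id": ids, "gene_id": genes, "base_mean": bm,
        "lfc": rel_lfc, "se": se, "t_stat": t, "p_value": p,
        "analysis": "splicing",
    })
    return out[multi].reset_index(drop=True)


def run_differential(
    tcm: TranscriptCountMatrix,
    design: StudyDesign,
    span: float = 0.5,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Run both analyses on a count matrix; returns the stacked transcript table.

    Expression rows cover every transcript; splicing rows only transcripts of
    multi-isoform genes. Both analyses share the identical design matrix,
    log-CPM transform (median-of-ratios effective library sizes), precision
    weights and base means.
    """
    lib = normalize_library_sizes(tcm.counts, design.condition_indicator)
    Y = logcpm(tcm, lib_sizes=lib)
    w = fit_precision_weights(Y, design, span=span, lib_sizes=lib)
    bm = base_mean_cpm(tcm, lib_sizes=lib)
    kwargs = dict(transcript_ids=list(tcm.transcript_ids), base_means=bm,
                  prior_df=prior_df)
    expr = fit_moderated_expression(Y, w, design, gene_of=tcm.gene_of, **kwargs)
    splice = fit_splicing(Y, w, design, tcm.gene_of, **kwargs)
    return pd.concat([expr, splice], ignore_index=True)


def adapt_external_results(table: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Adapter seam: validate an externally computed transcript-level table.

    Accepts any engine's per-transcript output with columns
    ``transcript_id, gene_id, base_mean, lfc, p_value`` and returns it in the
    engine's standard layout so aggregation and enrichment can run unchanged.
    """
    if analysis not in ("expression", "splicing"):
        raise ValueError("analysis must be 'expression' or 'splicing'")
    required = ["transcript_id", "gene_id", "base_mean", "lfc", "p_value"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"external result table missing column(s): {missing}")
    out = table[required].copy()
    p = out["p_value"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p_value outside [0, 1]")
    if np.any(out["base_mean"].to_numpy(dtype=float) < 0):
        raise ValueError("base_mean must be >= 0")
    out["se"] = np.nan
    out["t_stat"] = np.nan
    out["analysis"] = analysis
    return out[RESULT_COLUMNS]


def _resolve_ids(transcript_ids, n: int) -> list[str]:
    if transcript_ids is None:
        return [f"tx{i}" for i in range(n)]
    ids = list(transcript_ids)
    if len(ids) != n:
        raise ValueError("transcript_ids length does not match matrix rows")
    return ids
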