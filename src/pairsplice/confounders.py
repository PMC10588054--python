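"""Surrogate-variable estimation for unmodelled confounders.

The number of surrogate variables is chosen by permutation parallel analysis
on the residual matrix (eigenvalues compared against row-permuted nulls), and
the variables themselves by iteratively reweighted SVD: features are weighted
by their evidence of association with the candidate factors, and the weighted
residual matrix re-decomposed. Estimated factors that are nearly collinear
with the condition are dropped rather than allowed to absorb the biological
signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import StudyDesign

logger = logging.getLogger("pairsplice")

__all__ = ["SurrogateVariables", "estimate_num_sv", "fit_surrogate_variables",
           "augment_design"]

#: surrogate variables whose |correlation| with the condition indicator exceeds
#: this are rejected (confounder estimation must not absorb the contrast)
CONDITION_COLLINEARITY_LIMIT = 0.95


@dataclass(frozen=True)
class SurrogateVariables:
    """Estimated sample-level confounder axes (mean-centered columns)."""

    sv_matrix: np.ndarray  # samples x n_sv
    method_label: str = "irw-svd"
    dropped_collinear: int = 0

    def __post_init__(self) -> None:
        sv = np.asarray(self.sv_matrix, dtype=float)
        if sv.ndim == 1:
            sv = sv[:, None]
        if sv.size:
            sv = sv - sv.mean(axis=0, keepdims=True)
        object.__setattr__(self, "sv_matrix", sv)

    @property
    def n_sv(self) -> int:
        return 0 if self.sv_matrix.size == 0 else self.sv_matrix.shape[1]

    @classmethod
    def empty(cls, n_samples: int) -> "SurrogateVariables":
        return cls(sv_matrix=np.zeros((n_samples, 0)))


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project the rows of Y onto the orthogonal complement of col(X)."""
    pinv = np.linalg.pinv(X)
    return Y - (Y @ pinv.T) @ X.T


def estimate_num_sv(
    log_expr: np.ndarray,
    design: StudyDesign,
    n_perm: int = 20,
    seed: int = 0,
    quantile: float = 0.95,
) -> int:
    """Number of significant residual components by permutation parallel analysis.

    Residuals of the expression matrix on the full known design are
    decomposed; each leading eigenvalue is compared with the corresponding
    rank's eigenvalue distribution under independent row-wise permutation of
    the residuals (re-residualized after permuting). Counting stops at the
    first component that does not exceed the permutation ``quantile``.
    """
    Y = np.asarray(log_expr, dtype=float)
    n = Y.shape[1]
    if n < 4:
        warnings.warn("fewer than 4 samples: insufficient replication to "
                      "estimate surrogate variables; returning 0", stacklevel=2)
        return 0
    X = design.design_matrix().to_numpy()
    max_sv = n - np.linalg.matrix_rank(X)
    if max_sv <= 0:
        return 0

    R = _residualize(Y, X)
    s = np.linalg.svd(R, compute_uv=False) ** 2
    eig = s / s.sum()  # variance proportions: invariant to the projection loss

    rng = np.random.default_rng(seed)
    perm_eig = np.empty((n_perm, len(eig)))
    for b in range(n_perm):
        Rp = rng.permuted(R, axis=1)  # permute within each feature row
        Rp = _residualize(Rp, X)
        sp = np.linalg.svd(Rp, compute_uv=False) ** 2
        perm_eig[b] = sp / sp.sum()
    thresh = np.quantile(perm_eig, quantile, axis=0)

    k = 0
    for i in range(min(max_sv, len(eig))):
        if eig[i] > thresh[i]:
            k += 1
        else:
            break
    logger.info("parallel analysis: %d significant residual component(s)", k)
    return k


def fit_surrogate_variables(
    log_expr: np.ndarray,
    design: StudyDesign,
    n_sv: int,
    max_iter: int = 5,
) -> SurrogateVariables:
    """Estimate ``n_sv`` surrogate variables by iteratively reweighted SVD.

    Alternates (a) per-feature F-tests giving the probability that a feature
    is driven by the candidate factors but *not* by the condition, and (b) an
    SVD of the correspondingly weighted, row-centered data matrix whose top
    right-singular vectors become the new candidates. Running the final SVD
    on weighted *data* rather than residuals is essential: a factor estimated
    from residuals is orthogonal to the condition by construction and can
    never absorb the condition-aligned component of a confounder.
    Deterministic given the inputs.
    """
    Y = np.asarray(log_expr, dtype=float)
    n = Y.shape[1]
    if n_sv == 0:
        return SurrogateVariables.empty(n)
    X = design.design_matrix().to_numpy()
    cols = list(design.design_matrix().columns)
    ci = cols.index(f"condition[{design.case}]")
    X0 = np.delete(X, ci, axis=1)  # known design without the condition
    rank_x = np.linalg.matrix_rank(X)
    if n_sv > n - rank_x:
        raise ValueError(f"n_sv={n_sv} exceeds residual degrees of freedom "
                         f"({n} samples - rank {rank_x})")

    def _rss(Ymat: np.ndarray, M: np.ndarray) -> np.ndarray:
        return (_residualize(Ymat, M) ** 2).sum(axis=1)

    R = _residualize(Y, X)
    _, _, Vt = np.linalg.svd(R, full_matrices=False)
    cand = Vt[:n_sv].T
    Yc = Y - Y.mean(axis=1, keepdims=True)
    for _ in range(max_iter):
        Xfull = np.hstack([X, cand])
        df_full = n - np.linalg.matrix_rank(Xfull)
        if df_full <= 0:
            break
        rss_full = _rss(Y, Xfull)
        denom = np.maximum(rss_full / df_full, 1e-300)
        # association with the candidate factors, given the known design
        F_gam = ((_rss(Y, X) - rss_full) / n_sv) / denom
        p_gam = stats.f.sf(F_gam, n_sv, df_full)
        # association with the condition, given factors and other covariates
        X_gam = np.hstack([X0, cand])
        F_b = (_rss(Y, X_gam) - rss_full) / denom
        p_b = stats.f.sf(F_b, 1, df_full)
        # features clearly loading on the factors, softly damped when also
        # condition-driven: a hard 1-p_gam weight lets the many weakly
        # factor-free features drown the factor; a hard p_b damp strips the
        # condition-aligned component a genuine confounder carries
        pi = (p_gam < 0.05) * np.sqrt(p_b)
        _, _, Vt = np.linalg.svd(pi[:, None] * Yc, full_matrices=False)
        cand = Vt[:n_sv].T

    cond = design.condition_indicator
    cond_c = cond - cond.mean()
    keep = []
    dropped = 0
    for k in range(cand.shape[1]):
        col = cand[:, k] - cand[:, k].mean()
        denom = np.linalg.norm(col) * np.linalg.norm(cond_c)
        r = 0.0 if denom == 0 else float(col @ cond_c / denom)
        if abs(r) > CONDITION_COLLINEARITY_LIMIT:
            dropped += 1
            warnings.warn(
                f"surrogate variable {k + 1} is nearly collinear with the "
                f"condition (|r|={abs(r):.3f}); dropping it", stacklevel=2)
        else:
            keep.append(k)
    sv = cand[:, keep] if keep else np.zeros((n, 0))
    return SurrogateVariables(sv_matrix=sv, dropped_collinear=dropped)


def augment_design(design: StudyDesign, svs: SurrogateVariables) -> StudyDesign:
    """Append surrogate-variable columns to the design (returns a new object).

    Raises on rank deficiency after augmentation.
    """
    if svs.n_sv == 0:
        return design
    return design.with_surrogate_variables(svs.sv_matrix)
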