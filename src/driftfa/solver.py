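"""Exact solver for the ridge-penalized temporal factor model.

Model: the row-centered genotype matrix decomposes as
``Y = W + Z B^T + eps`` where ``W`` is the rank-K latent matrix carrying
population structure, ``Z`` the Brownian correction factors of the sample
times, ``B`` the drift effect sizes with ridge penalty ``lambda = sigma^2
/ alpha``, and ``eps`` white noise.  Minimizing

    L(W, B) = 1/2 ||Y - W - Z B^T||_F^2 + lambda/2 ||B||^2

over (W, B) has a closed form: profiling out B leaves the best rank-K
approximation of Y in the norm ``||Y||_A^2 = Tr(Y^T A Y)`` with
``A = P D_lambda P^T`` and ``D_lambda(i,i) = lambda / (lambda + lambda_i)``,
solved by ``W = P D^{-1/2} svd_K(D^{1/2} P^T Y)``.  Factors and loadings
come from the SVD of W.  As ``lambda -> inf`` the weights tend to one and
the solution reduces to ordinary PCA of Y; small ``lambda`` means strong
drift correction.  The cost is dominated by two SVDs, O(npK) for p >> n.

The drift parameter is selected as the largest value on a descending grid
for which the factor scores show no significant linear association with
time (F-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from driftfa.genotype_io import GenotypeMatrix
from driftfa.temporal import DriftBasis, TimeScale, brownian_covariance, spectral_basis


@dataclass
class FAConfig:
    """Settings for a factor-model fit.

    K : number of factors (1 <= K < min(n, p)).
    lam : drift parameter lambda = sigma^2 / alpha (> 0); large values
        approach PCA, small values enforce strong drift correction.
    lambda_grid : optional descending grid for automatic selection.
    center_check : tolerance on row means of Y.
    """

    K: int = 2
    lam: float = 1.0
    lambda_grid: Optional[np.ndarray] = None
    center_check: float = 1e-8

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass
class FAResult:
    """Fitted temporal factor model.

    U columns are orthonormal; singular values are carried in ``d`` and
    the variance-scaled scores (PCA convention) are ``scores = U * d``.
    ``B`` holds the drift effect sizes (p x n basis columns) so that the
    drift component of the fit is ``Z @ B.T``.
    """

    W: np.ndarray
    U: np.ndarray
    V: np.ndarray
    d: np.ndarray
    B: np.ndarray
    D_lam: np.ndarray
    lam: float
    basis: DriftBasis
    varexp_drift: float = np.nan
    varexp_factors: np.ndarray = None
    sample_ids: list = field(default_factory=list)

    @property
    def scores(self) -> np.ndarray:
        """Factor scores scaled by singular values (U * d)."""
        return self.U * self.d

    @property
    def drift_component(self) -> np.ndarray:
        return self.basis.Z @ self.B.T

    @property
    def K(self) -> int:
        return self.U.shape[1]


def _as_centered_array(Y, tol: float = 1e-8) -> np.ndarray:
    if isinstance(Y, GenotypeMatrix):
        arr = Y.values
        if not Y.centered:
            raise ValueError("genotype matrix must be row-centered (center_rows)")
    else:
        arr = np.asarray(Y, dtype=float)
    if np.max(np.abs(arr.mean(axis=1))) > max(tol, 1e-6 * max(np.abs(arr).max(), 1.0)):
        raise ValueError("rows of Y are not centered")
    return arr


def _signfix(U: np.ndarray, V: np.ndarray):
    """Fix each factor's sign so the largest-magnitude loading is positive."""
    idx = np.abs(V).argmax(axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def fit_fa(Y, basis: DriftBasis, cfg: FAConfig) -> FAResult:
    """Fit the temporal factor model by the exact closed form.

    ``basis`` must come from the same samples in the same order as ``Y``.
    The latent matrix is ``W = P D^{-1/2} svd_K(D^{1/2} P^T Y)`` with
    ``D(i,i) = lam / (lam + lambda_i)`` (never an explicit inversion of A;
    zero eigenvalues give weight one and are harmless).  ``B`` is recovered
    conditionally on W by ridge regression of ``Y - W`` on ``Z``; since
    ``Z^T Z = Lambda`` the normal equations are diagonal.
    """
    arr = _as_centered_array(Y, cfg.center_check)
    n, p = arr.shape
    if cfg.K >= min(n, p):
        raise ValueError(f"K={cfg.K} must be < min(n, p) = {min(n, p)}")
    if basis.P is None:
        basis = spectral_basis(basis.C)
    if basis.n != n:
        raise ValueError("basis dimension does not match number of samples")
    P, lam_i, Z = basis.P, basis.Lambda, basis.Z
    lam = cfg.lam

    D = lam / (lam + lam_i)  # diagonal of D_lambda, in (0, 1]
    sqrtD = np.sqrt(D)
    X = sqrtD[:, None] * (P.T @ arr)
    Ux, sx, Vxt = np.linalg.svd(X, full_matrices=False)
    K = cfg.K
    W = (P * (1.0 / sqrtD)) @ (Ux[:, :K] * sx[:K]) @ Vxt[:K]

    Uw, dw, Vwt = np.linalg.svd(W, full_matrices=False)
    U, d, V = Uw[:, :K], dw[:K], Vwt[:K].T
    U, V = _signfix(U, V)

    # ridge recovery of drift effect sizes: (Z^T Z + lam I) B^T = Z^T (Y - W)
    resid = arr - W
    Bt = ((np.sqrt(lam_i) / (lam_i + lam))[:, None]) * (P.T @ resid)
    B = Bt.T

    res = FAResult(
        W=W, U=U, V=V, d=d, B=B, D_lam=D, lam=lam, basis=basis,
        sample_ids=list(Y.sample_ids) if isinstance(Y, GenotypeMatrix) else [],
    )
    res.varexp_drift, res.varexp_factors = variance_components(res, arr)
    return res


def loss(Y, W, B, Z, lam: float) -> float:
    """Penalized reconstruction loss
    ``1/2 ||Y - W - Z B^T||_F^2 + lam/2 ||B||_F^2``."""
    Y = Y.values if isinstance(Y, GenotypeMatrix) else np.asarray(Y, dtype=float)
    resid = Y - W - Z @ B.T
    return 0.5 * float(np.sum(resid**2)) + 0.5 * lam * float(np.sum(B**2))


def anorm(Y, basis: DriftBasis, lam: float) -> float:
    """Squared drift-weighted norm ``||Y||_A^2 = Tr(Y^T P D_lam P^T Y)``.

    Computed via the diagonal weights; tends to the squared Frobenius norm
    as ``lam -> inf``.
    """
    Y = Y.values if isinstance(Y, GenotypeMatrix) else np.asarray(Y, dtype=float)
    if basis.P is None:
        basis = spectral_basis(basis.C)
    D = lam / (lam + basis.Lambda)
    X = np.sqrt(D)[:, None] * (basis.P.T @ Y)
    return float(np.sum(X**2))


def variance_components(res: FAResult, Y) -> tuple:
    """Fractions of total variance captured by the drift term and factors.

    ``varexp_drift = ||Z B^T||_F^2 / ||Y||_F^2`` and per-factor fractions
    ``d_k^2 / ||Y||_F^2``.  The components are not exactly orthogonal, so
    the fractions need not sum to one; on typical fits the residual closes
    the budget to within a couple of percent.
    """
    Y = Y.values if isinstance(Y, GenotypeMatrix) else np.asarray(Y, dtype=float)
    total = float(np.sum(Y**2))
    if total == 0:
        return 0.0, np.zeros(res.K)
    drift = float(np.sum(res.drift_component**2)) / total
    factors = res.d**2 / total
    return drift, factors


def factor_time_pvalues(res: FAResult, t: np.ndarray) -> np.ndarray:
    """F-test P-values of each factor's linear regression on time."""
    from driftfa.evaluation import factor_time_association

    return np.array(
        [factor_time_association(res.U[:, k], t)[2] for k in range(res.K)]
    )


def select_lambda(
    Y,
    ts: TimeScale,
    K: int,
    grid: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
    factors: str = "all",
):
    """Choose the drift parameter: largest grid value removing the time effect.

    Fits the model for each ``lam`` on a descending grid (default
    ``1e1 ... 1e-6`` log-spaced) and regresses factor scores on the
    transformed times.  With ``factors="all"`` (default) the candidate is
    accepted when no factor among the first K shows a significant
    association (F-test P > alpha for every factor); ``factors="last"``
    tests only factor K.  Testing all factors is the more robust reading of
    "remove the effect of time": before correction the drift signal often
    occupies the leading factor rather than the K-th.  If no grid value
    qualifies the smallest is returned with a warning.

    Returns ``(lam_selected, result_at_lam, diagnostics)`` where
    diagnostics is a DataFrame with one row per (lam, factor) holding the
    regression R^2 and P-value.
    """
    if grid is None:
        grid = np.logspace(1, -6, 15)
    grid = np.asarray(sorted(grid, reverse=True), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    basis = spectral_basis(brownian_covariance(ts).C)
    t = ts.times
    rows = []
    selected = None
    selected_res = None
    from driftfa.evaluation import factor_time_association

    for lam in grid:
        res = fit_fa(Y, basis, FAConfig(K=K, lam=lam))
        pvals = []
        for k in range(K):
            r2, F, p = factor_time_association(res.U[:, k], t)
            rows.append({"lam": lam, "factor": k + 1, "r2": r2, "F": F, "p": p})
            pvals.append(p)
        ok = (pvals[-1] > alpha) if factors == "last" else all(p > alpha for p in pvals)
        if ok and selected is None:
            selected, selected_res = lam, res
    diagnostics = pd.DataFrame(rows)
    if selected is None:
        warnings.warn(
            "no grid value removed the time effect; returning smallest lambda"
        )
        selected = grid[-1]
        selected_res = fit_fa(Y, basis, FAConfig(K=K, lam=selected))
    return selected, selected_res, diagnostics
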