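"""Coverage adjustment of centered genotype matrices.

Sequencing coverage of ancient samples can correlate with laboratory
batches and hence with population labels, leaking technical signal into
ordination axes.  Before factor analysis the centered matrix is adjusted
by the regression ``Y_ij = a_j coverage_i + Ytilde_ij + e_ij``: a
per-marker coverage effect plus a low-rank latent part.  The model is fit
by alternating a rank-limited truncated SVD for the latent part with a
per-marker (ridge-stabilized) least-squares update of the coverage
effects; the latent part replaces the genotypes downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from driftfa.genotype_io import GenotypeMatrix


@dataclass
class CoverageModel:
    """Result of the coverage regression.

    ``a`` holds per-marker effect sizes on the standardized coverage scale
    (``coverage_scale`` and ``coverage_mean`` record the transform);
    ``Y_tilde`` is the adjusted latent matrix, same shape as the input.
    """

    a: np.ndarray
    latent_rank: int
    Y_tilde: np.ndarray
    coverage_mean: float
    coverage_scale: float
    n_iter: int
    converged: bool


def adjust_for_coverage(
    Y_centered,
    coverage,
    latent_rank: int = 10,
    ridge: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> CoverageModel:
    """Remove the per-marker coverage effect from a centered matrix.

    Coverage is standardized internally (zero mean, unit variance) for
    conditioning; effects are reported on that scale, so rescaling the
    coverage units rescales ``a`` inversely and leaves ``Y_tilde``
    unchanged.  Constant coverage is not identifiable: the input is
    returned unchanged with a warning.
    """
    if isinstance(Y_centered, GenotypeMatrix):
        Y = Y_centered.values
    else:
        Y = np.asarray(Y_centered, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if cov.shape != (Y.shape[0],):
        raise ValueError("one coverage value per sample required")
    if not np.all(np.isfinite(cov)):
        raise ValueError("coverage must be finite")
    if latent_rank >= min(Y.shape):
        raise ValueError("latent_rank must be < min(n, p)")
    scale = cov.std()
    if scale == 0:
        warnings.warn("constant coverage: nothing to adjust")
        return CoverageModel(
            a=np.zeros(Y.shape[1]), latent_rank=latent_rank, Y_tilde=Y.copy(),
            coverage_mean=float(cov.mean()), coverage_scale=0.0,
            n_iter=0, converged=True,
        )
    x = (cov - cov.mean()) / scale
    xtx = float(x @ x)

    # update the coverage effect first: starting from the rank truncation
    # instead would let the latent part absorb the coverage direction
    L = np.zeros_like(Y)
    a = np.zeros(Y.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        a = (x @ (Y - L)) / (xtx + ridge)
        R = Y - np.outer(x, a)
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        L_new = (U[:, :latent_rank] * s[:latent_rank]) @ Vt[:latent_rank]
        delta = np.linalg.norm(L_new - L) / max(np.linalg.norm(L_new), 1e-12)
        L = L_new
        if delta < tol:
            converged = True
            break
    a = (x @ (Y - L)) / (xtx + ridge)
    if not converged:
        warnings.warn("coverage adjustment did not converge; using last iterate")
    return CoverageModel(
        a=a, latent_rank=latent_rank, Y_tilde=L,
        coverage_mean=float(cov.mean()), coverage_scale=float(scale),
        n_iter=it, converged=converged,
    )
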