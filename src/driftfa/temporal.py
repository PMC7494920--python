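"""Time transformation and the Brownian drift-correction basis.

Genetic drift in a random-mating population is well approximated by a
Brownian motion on allele frequencies: variance accumulates linearly in
time while the mean stays constant.  Sample ages are therefore mapped to a
forward time scale commensurate with the observed allele-frequency
variances, and the resulting Brownian covariance ``c_ij = min(t_i, t_j)``
supplies, through its spectral decomposition, the correction factors
``Z = P sqrt(Lambda)`` that absorb drift in the factor model.

The eigenfunctions of the Brownian (min) kernel are sinusoids — the
Karhunen-Loeve expansion — which is why uncorrected ordinations of serial
samples display horseshoe-shaped arcs.  :func:`kl_approximation` exposes
the analytic eigenvalues and eigenfunctions as an oracle against the
numerical decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from driftfa.genotype_io import GenotypeMatrix


class DegenerateTimeError(ValueError):
    """All sample ages are equal: supply distinct ages or use plain PCA."""


@dataclass
class TimeScale:
    """Sample ages mapped onto the scale of allele-frequency variances.

    ``forward_scaled`` rescales ages to [0, 1] with the most ancient sample
    at 0; ``times`` places them in ``[min(v), max(v)]`` where ``v`` holds
    the per-sample variances of the centered genotype matrix.
    """

    ages: np.ndarray
    forward_scaled: np.ndarray
    row_variances: np.ndarray
    times: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ages)


@dataclass
class DriftBasis:
    """Brownian covariance and its spectral correction basis.

    ``C`` is the n x n matrix ``min(t_i, t_j)``; ``P`` its orthonormal
    eigenvectors (columns, eigenvalues descending in ``Lambda``);
    ``Z = P @ diag(sqrt(Lambda))`` the correction factors, ``Z Z^T = C``.
    """

    C: np.ndarray
    P: Optional[np.ndarray] = None
    Lambda: Optional[np.ndarray] = None
    Z: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.C.shape[0]


def transform_ages(ages, Y_centered: GenotypeMatrix) -> TimeScale:
    """Map sample ages to drift-scaled forward times.

    ``s_i = 1 - (a_i - min a) / (max a - min a)`` converts ages to forward
    values in [0, 1]; the times are then ``t_i = min v + s_i (max v - min v)``
    with ``v_i`` the variance of row i of the centered matrix (denominator
    ``p``; the choice of denominator only rescales ``t`` affinely).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1 or len(ages) < 2:
        raise ValueError("need a vector of at least two ages")
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    if isinstance(Y_centered, GenotypeMatrix):
        if not Y_centered.centered:
            raise ValueError("genotype matrix must be row-centered first")
        Y = Y_centered.values
    else:
        Y = np.asarray(Y_centered, dtype=float)
    if Y.shape[0] != len(ages):
        raise ValueError("one age per sample required")
    span = ages.max() - ages.min()
    if span == 0:
        raise DegenerateTimeError(
            "all ages equal: temporal correction is undefined; "
            "supply distinct ages or use plain PCA"
        )
    s = 1.0 - (ages - ages.min()) / span
    v = Y.var(axis=1)  # population variance (ddof=0)
    t = v.min() + s * (v.max() - v.min())
    return TimeScale(ages=ages, forward_scaled=s, row_variances=v, times=t)


def brownian_covariance(ts) -> DriftBasis:
    """Build the Brownian covariance ``c_ij = min(t_i, t_j)``.

    Accepts a :class:`TimeScale` or a plain vector of non-negative times.
    """
    t = ts.times if isinstance(ts, TimeScale) else np.asarray(ts, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    C = np.minimum.outer(t, t)
    return DriftBasis(C=C)


def spectral_basis(C) -> DriftBasis:
    """Eigendecompose a symmetric PSD covariance into the correction basis.

    Eigenvalues are sorted descending and small negative values (numerical
    noise) are clipped to zero; a negative eigenvalue beyond
    ``-1e-10 * lambda_max`` raises.  Each eigenvector's sign is fixed so
    that its largest-magnitude entry is positive, making ``Z`` reproducible.
    """
    if isinstance(C, DriftBasis):
        C = C.C
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    w, P = np.linalg.eigh(C)
    w = w[::-1]
    P = P[:, ::-1]
    lam_max = max(w[0], 0.0)
    if w[-1] < -1e-10 * max(lam_max, 1.0):
        raise ValueError(f"covariance has negative eigenvalue {w[-1]:.3e}")
    w = np.clip(w, 0.0, None)
    # deterministic sign convention
    idx = np.abs(P).argmax(axis=0)
    signs = np.sign(P[idx, np.arange(P.shape[1])])
    signs[signs == 0] = 1.0
    P = P * signs
    Z = P * np.sqrt(w)
    return DriftBasis(C=C, P=P, Lambda=w, Z=Z)


def kl_approximation(n: int, t) -> tuple:
    """Analytic Karhunen-Loeve approximants for the Brownian basis.

    For ``n`` roughly uniform times on [0, 1], the eigenvalues of the
    discrete min-kernel matrix are approximately
    ``lambda_i = n / ((i - 1/2)^2 pi^2)`` and the correction factors
    ``Z[:, i] ~ f_i(t) sqrt(lambda_i / n)`` with
    ``f_i(t) = sqrt(2) sin((i - 1/2) pi t)``.

    Returns ``(eigenvalues, Z_approx)`` with ``Z_approx`` of shape
    ``(len(t), n)``.
    """
    t = np.asarray(t, dtype=float)
    i = np.arange(1, n + 1)
    lam = n / ((i - 0.5) ** 2 * np.pi**2)
    F = np.sqrt(2.0) * np.sin(np.outer(t, (i - 0.5) * np.pi))
    Z_approx = F * np.sqrt(lam / n)
    return lam, Z_approx
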