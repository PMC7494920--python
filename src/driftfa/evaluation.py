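"""Evaluation metrics for representation and ancestry benchmarks.

Davies-Bouldin cluster separation, the Hudson ratio-of-averages F_ST
estimator, bias/MSE/RMSE of ancestry estimates against truth, and the
F-test of linear association between factor scores and sample times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from driftfa.genotype_io import GenotypeMatrix


@dataclass
class MetricReport:
    name: str
    value: float
    n_items: int
    details: dict = field(default_factory=dict)


def davies_bouldin(points, labels) -> float:
    """Davies-Bouldin index: mean over clusters of the worst ratio
    ``(sigma_i + sigma_j) / d(c_i, c_j)`` where ``sigma`` is the mean
    Euclidean distance of cluster members to their centroid.

    Lower values mean better-separated clusters.  Coincident centroids
    yield +inf with a warning.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    cents = np.vstack([X[labels == u].mean(axis=0) for u in uniq])
    sig = np.array(
        [np.linalg.norm(X[labels == u] - c, axis=1).mean() for u, c in zip(uniq, cents)]
    )
    k = len(uniq)
    ratios = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            dij = np.linalg.norm(cents[i] - cents[j])
            if dij == 0:
                warnings.warn("coincident cluster centroids: index is infinite")
                worst = np.inf
                break
            worst = max(worst, (sig[i] + sig[j]) / dij)
        ratios[i] = worst
    return float(ratios.mean())


def hudson_fst(geno_a, geno_b) -> float:
    """Hudson F_ST, ratio of averages over markers.

    Per-SNP numerator ``(pa - pb)^2 - pa(1-pa)/(na-1) - pb(1-pb)/(nb-1)``
    and denominator ``pa(1-pb) + pb(1-pa)``, summed before dividing.
    Inputs are dosage matrices (individuals x markers) over the same
    marker set, at least two samples per population.
    """
    A = geno_a.values if isinstance(geno_a, GenotypeMatrix) else np.asarray(geno_a, float)
    B = geno_b.values if isinstance(geno_b, GenotypeMatrix) else np.asarray(geno_b, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("marker sets differ")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least two samples per population")
    na, nb = 2 * A.shape[0], 2 * B.shape[0]  # allele (chromosome) counts
    pa = A.mean(axis=0) / 2.0
    pb = B.mean(axis=0) / 2.0
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    total = den.sum()
    if total == 0:
        raise ValueError("all markers monomorphic in both populations")
    return float(num.sum() / total)


def estimate_errors(estimates, truth) -> MetricReport:
    """Bias, MSE and RMSE of estimates against ground truth."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truth must have equal length")
    err = est - tru
    bias = float(err.mean())
    mse = float((err**2).mean())
    return MetricReport(
        name="estimate_errors",
        value=mse,
        n_items=len(est),
        details={"bias": bias, "mse": mse, "rmse": float(np.sqrt(mse))},
    )


def factor_time_association(u, t):
    """Squared Pearson correlation, F-statistic and P-value of the simple
    linear regression of factor scores on times (1 and n-2 df)."""
    u = np.asarray(u, dtype=float)
    t = np.asarray(t, dtype=float)
    n = len(u)
    if n < 3:
        raise ValueError("need at least three samples")
    if u.std() == 0 or t.std() == 0:
        raise ValueError("zero-variance input")
    r = np.corrcoef(u, t)[0, 1]
    r2 = r**2
    if r2 >= 1.0:
        return 1.0, np.inf, 0.0
    F = r2 / (1.0 - r2) * (n - 2)
    p = float(stats.f.sf(F, 1, n - 2))
    return float(r2), float(F), p
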