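"""Independent oracles used by the test suite.

These deliberately avoid the closed-form code paths they are checked
against: the factor-model oracle is a plain alternating minimizer of the
penalized loss, restarted from random points.
"""

import numpy as np

from driftfa import loss


def alt_min_loss(Y, Z, lam, K, rng, restarts=50, iters=200, tol=1e-12):
    """Best loss found by alternating minimization of
    1/2||Y - W - Z B^T||^2 + lam/2 ||B||^2 over rank-K W and B,
    from ``restarts`` random initializations."""
    n, p = Y.shape
    m = Z.shape[1]
    G = Z.T @ Z + lam * np.eye(m)
    best = np.inf
    for _ in range(restarts):
        W = rng.standard_normal((n, K)) @ rng.standard_normal((K, p))
        prev = np.inf
        for _ in range(iters):
            B = np.linalg.solve(G, Z.T @ (Y - W)).T
            R = Y - Z @ B.T
            U, s, Vt = np.linalg.svd(R, full_matrices=False)
            W = (U[:, :K] * s[:K]) @ Vt[:K]
            cur = loss(Y, W, B, Z, lam)
            if prev - cur < tol * max(prev, 1.0):
                break
            prev = cur
        best = min(best, cur)
    return best
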