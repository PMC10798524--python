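"""Independent numerical oracles used only by the tests.

These deliberately avoid the package's own computational paths: the
mixed-model likelihood is integrated by 201-point adaptive Gauss-Hermite
quadrature, and the signed-rank null is enumerated exhaustively.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import special
from scipy.optimize import minimize_scalar


def quadrature_marginal_loglik(
    df, beta: float, sd: float, x_col: str = "x", y_col: str = "y",
    group_col: str = "subject", npts: int = 201,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood for a logistic model
    with one slope and a subject random intercept."""
    nodes, weights = hermgauss(npts)
    total = 0.0
    for _, g in df.groupby(group_col):
        x = g[x_col].to_numpy(dtype=float)
        y = g[y_col].to_numpy(dtype=float)

        def negpen(b):
            eta = beta * x + b
            return -(np.sum(y * eta - np.logaddexp(0, eta)) - 0.5 * b * b / sd**2)

        mode = minimize_scalar(negpen, bounds=(-20, 20), method="bounded").x
        mu = special.expit(beta * x + mode)
        s_hat = 1.0 / np.sqrt(np.sum(mu * (1 - mu)) + 1.0 / sd**2)
        b_nodes = mode + np.sqrt(2.0) * s_hat * nodes
        logf = np.array(
            [
                np.sum(y * (beta * x + b) - np.logaddexp(0, beta * x + b))
                - 0.5 * b * b / sd**2
                - 0.5 * np.log(2 * np.pi * sd**2)
                for b in b_nodes
            ]
        )
        total += special.logsumexp(np.log(weights) + nodes**2 + logf) + np.log(
            np.sqrt(2.0) * s_hat
        )
    return float(total)


def exact_wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p-value by exhaustive enumeration of all
    2^n sign assignments (no ties/zeros handling needed for the fixtures)."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = ranks[diffs > 0].sum()
    mean_w = n * (n + 1) / 4.0
    stat_obs = abs(w_obs - mean_w)
    count = 0
    for mask in range(2**n):
        signs = np.array([(mask >> i) & 1 for i in range(n)])
        w = ranks[signs == 1].sum()
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / 2**n
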