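"""Machine-learning comparator: logistic regression with nonnegative weights.

The spiking network is benchmarked against a logistic classifier fit on
a binarized view of the task: entry (p, n) of the design matrix is 1
iff cortical neuron n spikes at any time during pattern p (all timing
information discarded). The linear coefficients are constrained to be
nonnegative — the same excitatory-only constraint the corticostriatal
weights obey — while the intercept is free. On nested instances where a
rewarded pattern is contained in a non-rewarded one, any nonnegative
weighting scores the superpattern at least as high as the subpattern,
so this baseline cannot exceed 50% accuracy there; the two-MSN circuit
with collateral inhibition can.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .patterns import Pattern

__all__ = ["BinaryPatternMatrix", "binarize", "fit_nonneg_logistic", "LogisticFit"]


@dataclass(frozen=True)
class BinaryPatternMatrix:
    """Binary design matrix (one row per pattern) and reward labels."""

    M: np.ndarray
    r: np.ndarray


def binarize(patterns: Sequence[Pattern], P: int) -> BinaryPatternMatrix:
    """Collapse patterns to channel-occupancy rows over P channels."""
    M = np.zeros((len(patterns), P), dtype=int)
    r = np.zeros(len(patterns), dtype=int)
    for i, p in enumerate(patterns):
        for ch in p.channels:
            if not (1 <= ch <= P):
                raise ValueError(f"channel {ch} outside 1..{P}")
            M[i, ch - 1] = 1
        r[i] = int(p.rewarded)
    return BinaryPatternMatrix(M=M, r=r)


@dataclass
class LogisticFit:
    """Constrained-logistic fit result with optimizer diagnostics."""

    weights: np.ndarray
    intercept: float
    train_accuracy: float
    converged: bool
    message: str
    n_iter: int

    def predict_proba(self, M: np.ndarray) -> np.ndarray:
        return expit(M @ self.weights + self.intercept)

    def predict(self, M: np.ndarray) -> np.ndarray:
        return (self.predict_proba(M) >= 0.5).astype(int)


def fit_nonneg_logistic(
    M: np.ndarray,
    r: np.ndarray,
    l2: float = 1e-4,
    tol: float = 1e-12,
) -> LogisticFit:
    """Maximum-likelihood logistic fit with elementwise weights >= 0.

    Minimizes the negative log-likelihood plus a mild L2 penalty
    (``l2 * ||w||^2 / 2``, intercept excluded) for optimizer stability,
    subject to box constraints w_j >= 0 via L-BFGS-B. Training accuracy
    thresholds the fitted probability at 0.5. Non-convergence is
    surfaced in the returned diagnostics, never swallowed.
    """
    M = np.asarray(M, dtype=float)
    r = np.asarray(r, dtype=float)
    if M.ndim != 2 or M.shape[0] == 0:
        raise ValueError("need at least one pattern row")
    n, P = M.shape

    def nll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:P], theta[P]
        z = M @ w + b
        # log(1 + exp(z)) - r z, computed stably
        nll = float(np.sum(np.logaddexp(0.0, z) - r * z)) + 0.5 * l2 * w @ w
        p = expit(z)
        gw = M.T @ (p - r) + l2 * w
        gb = float(np.sum(p - r))
        return nll, np.concatenate([gw, [gb]])

    theta0 = np.zeros(P + 1)
    bounds = [(0.0, None)] * P + [(None, None)]
    res = minimize(
        nll_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "ftol": tol, "gtol": 1e-10},
    )
    w, b = res.x[:P], float(res.x[P])
    pred = (expit(M @ w + b) >= 0.5).astype(int)
    acc = float(np.mean(pred == r.astype(int)))
    return LogisticFit(
        weights=w,
        intercept=b,
        train_accuracy=acc,
        converged=bool(res.success),
        message=str(res.message),
        n_iter=int(res.nit),
    )
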