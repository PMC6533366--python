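"""Small numerical helpers: finite-difference derivatives shared by the
model-fitting modules."""

from __future__ import annotations

import numpy as np


def fd_grad(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * h[i])
    return g


def fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    # diagonal
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        H[i, i] = (f(x + e) - 2 * f0 + f(x - e)) / h[i] ** 2
    # off-diagonal
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fd_hessian_from_grad(grad, x: np.ndarray, rel_step: float = 1e-5
                         ) -> np.ndarray:
    """Hessian by central differences of an analytic gradient
    (symmetrized)."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        H[i] = (grad(x + e) - grad(x - e)) / (2 * h[i])
    return 0.5 * (H + H.T)


def safe_cov_from_hessian(neg_hess: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert an observed information matrix; returns (cov, spd_flag)."""
    try:
        L = np.linalg.cholesky(neg_hess)
        inv = np.linalg.inv(neg_hess)
        return 0.5 * (inv + inv.T), True
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(neg_hess)
        return 0.5 * (inv + inv.T), False
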