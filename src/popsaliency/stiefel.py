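"""Riemannian gradient ascent on the Stiefel manifold St(n, p).

Minimal first-order optimizer for the smooth trace objectives used in the
subspace analyses: tangent-space projection of the Euclidean gradient, QR
retraction, Armijo backtracking line search with a Barzilai-Borwein-style
step warm start.  The objective is non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


class ConvergenceError(RuntimeError):
    pass


def random_stiefel(n: int, p: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, p)))
    return q * np.sign(np.diag(r))


def project_tangent(q: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Project a Euclidean gradient onto the tangent space at q."""
    qtg = q.T @ g
    return g - q @ ((qtg + qtg.T) / 2.0)


def retract(q: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """QR retraction of q + xi back onto the manifold (sign-fixed)."""
    qn, r = np.linalg.qr(q + xi)
    return qn * np.sign(np.diag(r))


@dataclass
class AscentResult:
    q: np.ndarray
    value: float
    grad_norm: float
    n_iter: int
    converged: bool


def maximize(
    value_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    max_iter: int = 500,
    gtol: float = 1e-6,
    initial_step: float = 1.0,
    armijo: float = 1e-4,
) -> AscentResult:
    """Maximize a smooth function over the Stiefel manifold.

    ``value_and_grad`` returns the objective and its Euclidean gradient.
    Convergence: Riemannian gradient norm below ``gtol * (1 + |f|)``.
    """
    q = q0.copy()
    f, g = value_and_grad(q)
    step = initial_step
    it = 0
    for it in range(1, max_iter + 1):
        rg = project_tangent(q, g)
        gn = float(np.linalg.norm(rg))
        if gn <= gtol * (1.0 + abs(f)):
            return AscentResult(q, f, gn, it, True)
        # Armijo backtracking on the retraction
        accepted = False
        a = step
        for _ in range(40):
            q_new = retract(q, a * rg)
            f_new, g_new = value_and_grad(q_new)
            if f_new >= f + armijo * a * gn * gn:
                accepted = True
                break
            a *= 0.5
        if not accepted:
            return AscentResult(q, f, gn, it, gn <= 10 * gtol * (1.0 + abs(f)))
        q, f, g = q_new, f_new, g_new
        step = min(a * 2.0, 1e3)  # warm start next line search
    rg = project_tangent(q, g)
    return AscentResult(q, f, float(np.linalg.norm(rg)), it, False)
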