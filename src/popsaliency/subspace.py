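"""Orthogonal, exclusive, and shared subspaces of target/singleton activity.

The population activity evoked by the five contralateral stimulus locations in
the 150-200 ms window is summarized by a (locations x time, units) condition
matrix per context (target or singleton).  Subspaces are d-dimensional
orthonormal bases over units found by optimization on the Stiefel manifold:

* the *orthogonal pair* maximizes the summed normalized variance of the two
  contexts subject to mutual orthogonality (a joint N x 2d frame);
* each *exclusive* subspace maximizes one context's normalized variance while
  capping the other context's below a bound ``v`` (quadratic exterior penalty
  with continuation, feasibility verified post hoc);
* the *shared* subspace maximizes the joint normalized variance inside the
  orthogonal complement of both exclusive subspaces (closed form there).

Captured variance is measured by the alignment index
``A = Tr(Q' C Q) / sum_{i<=d} lambda_i(C)`` in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import stiefel
from .decoding import PseudoPopulation


class InputError(ValueError):
    pass


class InfeasibleError(RuntimeError):
    pass


@dataclass
class ConditionMatrix:
    matrix: np.ndarray  # (locations*timepoints, units), column-centered
    context: str
    locations: tuple[int, ...]
    n_timepoints: int

    def covariance(self) -> np.ndarray:
        m = self.matrix
        return m.T @ m / (m.shape[0] - 1)


def build_condition_matrix(
    rates: np.ndarray,
    grid: np.ndarray,
    trial_locations: np.ndarray,
    context: str,
    locations: tuple[int, ...] = (2, 3, 4, 5, 6),
    window: tuple[float, float] = (150.0, 200.0),
) -> ConditionMatrix:
    """Stack per-location mean time courses and center each unit's column.

    ``rates`` is (units, trials, time) on a 1-ms grid; ``trial_locations``
    gives each trial's location of the requested context.  The window is
    inclusive of both endpoints (51 points for 150-200 ms), matching the
    locations x timepoints row count.
    """
    tmask = (grid >= window[0]) & (grid <= window[1])
    blocks = []
    for loc in locations:
        sel = np.flatnonzero(np.asarray(trial_locations) == loc)
        if sel.size == 0:
            raise InputError(f"no trials with {context} at location {loc}")
        blocks.append(rates[:, sel][:, :, tmask].mean(axis=1).T)  # (time, units)
    m = np.vstack(blocks).astype(float)
    m = m - m.mean(axis=0, keepdims=True)
    return ConditionMatrix(m, context, tuple(locations), int(tmask.sum()))


@dataclass
class CovariancePair:
    c_target: np.ndarray
    c_singleton: np.ndarray

    def __post_init__(self):
        for c in (self.c_target, self.c_singleton):
            if not np.allclose(c, c.T, atol=1e-8):
                raise InputError("covariance matrices must be symmetric")


def _top_eigsum(c: np.ndarray, d: int) -> float:
    w = np.linalg.eigvalsh(c)
    return float(w[::-1][:d].sum())


def alignment_index(q: np.ndarray, c: np.ndarray, d: int | None = None) -> float:
    """Normalized captured variance Tr(Q'CQ) / sum of top-d eigenvalues."""
    d = d if d is not None else q.shape[1]
    denom = _top_eigsum(c, d)
    if denom <= 0:
        raise InputError("covariance has no variance (rank 0)")
    return float(np.trace(q.T @ c @ q) / denom)


def _check_orthonormal(q: np.ndarray, tol: float = 1e-8) -> None:
    err = np.linalg.norm(q.T @ q - np.eye(q.shape[1]))
    if err > tol:
        raise RuntimeError(f"basis not orthonormal: residual {err:.2e}")


def _pc_init_pair(c_t: np.ndarray, c_s: np.ndarray, d: int) -> np.ndarray:
    """Initial 2d-frame: target PCs, then singleton PCs re-orthonormalized."""
    wt, vt = np.linalg.eigh(c_t)
    ws, vs = np.linalg.eigh(c_s)
    q = np.hstack([vt[:, ::-1][:, :d], vs[:, ::-1][:, :d]])
    q, _ = np.linalg.qr(q)
    return q


def fit_orthogonal_pair(
    cov: CovariancePair,
    d: int = 5,
    restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, stiefel.AscentResult]:
    """Mutually orthogonal bases maximizing the two normalized variances.

    Optimizes a joint N x 2d Stiefel frame whose first and second d-column
    blocks serve target and singleton respectively; mutual orthogonality is
    automatic from the frame's orthonormality.
    """
    c_t, c_s = cov.c_target, cov.c_singleton
    n = c_t.shape[0]
    if n < 2 * d:
        raise InputError(f"need N >= 2d units (N={n}, d={d})")
    s_t, s_s = _top_eigsum(c_t, d), _top_eigsum(c_s, d)

    def vg(q):
        q1, q2 = q[:, :d], q[:, d:]
        f = np.trace(q1.T @ c_t @ q1) / s_t + np.trace(q2.T @ c_s @ q2) / s_s
        g = np.hstack([2.0 * (c_t @ q1) / s_t, 2.0 * (c_s @ q2) / s_s])
        return float(f), g

    rng = np.random.default_rng(seed)
    inits = [_pc_init_pair(c_t, c_s, d)]
    inits += [stiefel.random_stiefel(n, 2 * d, rng) for _ in range(restarts - 1)]
    best = None
    for q0 in inits:
        res = stiefel.maximize(vg, q0, max_iter=max_iter, gtol=gtol)
        if best is None or res.value > best.value:
            best = res
    if not best.converged and best.grad_norm > 1e-3 * (1 + abs(best.value)):
        raise RuntimeError(
            f"orthogonal-pair optimization did not converge (grad norm {best.grad_norm:.2e})"
        )
    q_t, q_s = best.q[:, :d].copy(), best.q[:, d:].copy()
    _check_orthonormal(best.q)
    return q_t, q_s, best


def fit_exclusive(
    cov_max: np.ndarray,
    cov_limit: np.ndarray,
    v: float = 0.01,
    d: int = 5,
    restarts: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    feas_tol: float = 1e-4,
) -> tuple[np.ndarray, stiefel.AscentResult]:
    """Maximize one context's normalized variance with the other capped at v.

    Exterior quadratic penalty with continuation on the constraint
    ``A_limit(Q) <= v``; feasibility is verified post hoc at tolerance
    ``feas_tol`` above v.
    """
    n = cov_max.shape[0]
    if n < d:
        raise InputError(f"need N >= d units (N={n}, d={d})")
    s_max = _top_eigsum(cov_max, d)
    s_lim = _top_eigsum(cov_limit, d)
    if s_lim <= 0:  # limit context has no variance: constraint is vacuous
        w, vecs = np.linalg.eigh(cov_max)
        q = vecs[:, ::-1][:, :d]
        val = float(w[::-1][:d].sum() / s_max)
        return q, stiefel.AscentResult(q, val, 0.0, 0, True)
    w_lim, v_lim = np.linalg.eigh(cov_limit)  # ascending
    min_alim = float(w_lim[:d].sum() / s_lim)
    if min_alim > v + feas_tol:
        raise InfeasibleError(
            f"limit variance cannot be brought below v={v}: minimum achievable "
            f"is {min_alim:.4f}"
        )

    def a_lim(q):
        return float(np.trace(q.T @ cov_limit @ q) / s_lim)

    # feasible initialization: restrict to the complement of the top limit
    # directions so that even the worst d-dim subspace inside satisfies the cap
    lam_desc = w_lim[::-1]
    k = 0
    while k < n - d and lam_desc[k:][:d].sum() / s_lim > v:
        k += 1
    b = v_lim[:, ::-1][:, k:]  # complement of top-k limit eigenvectors
    m = b.T @ cov_max @ b
    wm, vm = np.linalg.eigh(m)
    q_init = b @ vm[:, ::-1][:, :d]
    q_init, _ = np.linalg.qr(q_init)

    rng = np.random.default_rng(seed)
    inits = [q_init] + [stiefel.random_stiefel(n, d, rng) for _ in range(restarts - 1)]
    best = None
    for q0 in inits:
        q, res = _penalized_exclusive(
            cov_max, cov_limit, q0, v, s_max, s_lim, max_iter, feas_tol
        )
        if q is None:
            continue
        if best is None or res.value > best[1].value:
            best = (q, res)
    if best is None:
        raise RuntimeError("exclusive-subspace optimization found no feasible point")
    q, res = best
    if a_lim(q) > v + feas_tol:
        raise RuntimeError(
            f"constraint violated post hoc: A_limit={a_lim(q):.5f} > v+{feas_tol}"
        )
    _check_orthonormal(q)
    return q, res


def _penalized_exclusive(cov_max, cov_limit, q0, v, s_max, s_lim, max_iter, feas_tol):
    q = q0
    res = None
    # exterior penalty converges to its cap from outside, so aim slightly
    # inside v to guarantee the returned point satisfies the bound itself
    v_target = max(v - feas_tol, 0.5 * v)
    for mu in 10.0 ** np.arange(2, 10):
        def vg(qq, mu=mu):
            am = np.trace(qq.T @ cov_max @ qq) / s_max
            al = np.trace(qq.T @ cov_limit @ qq) / s_lim
            viol = max(0.0, al - v_target)
            f = am - mu * viol * viol
            g = 2.0 * (cov_max @ qq) / s_max
            if viol > 0:
                g = g - mu * 2.0 * viol * 2.0 * (cov_limit @ qq) / s_lim
            return float(f), g

        res = stiefel.maximize(vg, q, max_iter=max_iter, gtol=1e-7)
        q = res.q
        al = float(np.trace(q.T @ cov_limit @ q) / s_lim)
        if al <= v:
            # report the raw captured variance, not the penalized objective
            val = float(np.trace(q.T @ cov_max @ q) / s_max)
            return q, stiefel.AscentResult(q, val, res.grad_norm, res.n_iter, res.converged)
    return None, res


def fit_shared(
    cov: CovariancePair,
    q_excl_target: np.ndarray,
    q_excl_singleton: np.ndarray,
    d: int = 5,
) -> np.ndarray:
    """Joint-variance-maximizing basis orthogonal to both exclusive subspaces.

    Within the orthogonal complement the objective is a single quadratic form,
    so the optimum is the top-d eigenvectors of the projected summed
    (normalized) covariance - computed in closed form.
    """
    c_t, c_s = cov.c_target, cov.c_singleton
    n = c_t.shape[0]
    z = np.hstack([q_excl_target, q_excl_singleton])
    u, sv, _ = np.linalg.svd(z, full_matrices=True)
    rank = int((sv > 1e-10).sum())
    b = u[:, rank:]
    if b.shape[1] < d:
        raise InputError(
            f"orthogonal complement has dimension {b.shape[1]} < d={d}; reduce d"
        )
    s_t, s_s = _top_eigsum(c_t, d), _top_eigsum(c_s, d)
    m = b.T @ (c_t / s_t + c_s / s_s) @ b
    w, vecs = np.linalg.eigh(m)
    q = b @ vecs[:, ::-1][:, :d]
    q, _ = np.linalg.qr(q)
    resid = max(
        np.abs(q.T @ q_excl_target).max(), np.abs(q.T @ q_excl_singleton).max()
    )
    if resid > 1e-6:
        raise RuntimeError(f"shared basis not orthogonal to exclusives: {resid:.2e}")
    _check_orthonormal(q)
    return q


# --------------------------------------------------------------------------
# model assembly, projection, and unit weights
# --------------------------------------------------------------------------


@dataclass
class SubspaceModel:
    d: int
    v: float
    q_orth_target: np.ndarray
    q_orth_singleton: np.ndarray
    q_excl_target: np.ndarray
    q_excl_singleton: np.ndarray
    q_shared: np.ndarray
    alignment: dict[tuple[str, str], float] = field(default_factory=dict)

    def weights(self, basis: str = "shared") -> np.ndarray:
        q = {
            "shared": self.q_shared,
            "orth_target": self.q_orth_target,
            "orth_singleton": self.q_orth_singleton,
            "excl_target": self.q_excl_target,
            "excl_singleton": self.q_excl_singleton,
        }[basis]
        return unit_weights(q)


def fit_subspace_model(
    cov: CovariancePair,
    d: int = 5,
    v: float = 0.01,
    seed: int = 0,
    restarts: int = 5,
) -> SubspaceModel:
    """Fit all five subspaces and tabulate alignment indices per context."""
    q_ot, q_os, _ = fit_orthogonal_pair(cov, d=d, restarts=restarts, seed=seed)
    q_et, _ = fit_exclusive(cov.c_target, cov.c_singleton, v=v, d=d, seed=seed)
    q_es, _ = fit_exclusive(cov.c_singleton, cov.c_target, v=v, d=d, seed=seed)
    q_sh = fit_shared(cov, q_et, q_es, d=d)
    model = SubspaceModel(d, v, q_ot, q_os, q_et, q_es, q_sh)
    for name, q in [
        ("orth_target", q_ot),
        ("orth_singleton", q_os),
        ("excl_target", q_et),
        ("excl_singleton", q_es),
        ("shared", q_sh),
    ]:
        for ctx, c in [("target", cov.c_target), ("singleton", cov.c_singleton)]:
            a = alignment_index(q, c, d)
            if not (-1e-9 <= a <= 1.0 + 1e-9):
                raise RuntimeError(f"alignment index out of [0,1]: {a}")
            model.alignment[(name, ctx)] = a
    return model


def project_population(pop: PseudoPopulation, q: np.ndarray) -> PseudoPopulation:
    """Project a pseudo-population's unit axis onto a d-dimensional basis."""
    if pop.counts.shape[2] != q.shape[0]:
        raise InputError(
            f"unit dimension mismatch: population has {pop.counts.shape[2]}, "
            f"basis has {q.shape[0]} rows"
        )
    projected = np.einsum("rsuw,ud->rsdw", pop.counts, q)
    return PseudoPopulation(projected, pop.labels, pop.window_starts, pop.unit_index)


def projected_decoding(pop: PseudoPopulation, q: np.ndarray, **decode_kwargs):
    """Decode labels from activity projected onto a subspace."""
    from .decoding import decode_timecourse

    return decode_timecourse(project_population(pop, q), **decode_kwargs)


def unit_weights(q: np.ndarray) -> np.ndarray:
    """Per-unit contribution to a subspace: the norm of each row of Q.

    For an orthonormal basis the squared row norms sum to d and each row norm
    lies in [0, 1].
    """
    _check_orthonormal(q, tol=1e-6)
    return np.linalg.norm(q, axis=1)


def weight_class_anova(weights: np.ndarray, classes: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA of subspace weights across selectivity classes."""
    groups = [weights[classes == c] for c in np.unique(classes)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        return float("nan"), float("nan")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
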