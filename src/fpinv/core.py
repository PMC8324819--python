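"""The structured linear computation at the center of the inverse method.

The discrete Fokker-Planck operator is linear both in the density P and in
the drift/diffusion vectors (g, h):

    dP/dt = D1 (g * P) + D2 (h * P) = A(P) w = L(g, h) P

with A(P) = [D1 diag(P), D2 diag(P)] (B x 2B) and
L = D1 diag(g) + D2 diag(h) (B x B).  Multi-offset Euler predictions

    P_pred(t + i dt) = P(t) + i dt (A(P) w)          i in an offset set

make every loss below a quadratic form in its trainable argument, so each
training step has an exact minimizer found by a linear solve.  A plain
gradient-descent minimizer of the same quadratics is provided as the
optional iterative backend.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .forward import FPETerms, fpe_rhs
from .grid import DerivativeOperators

__all__ = ["training_offsets", "eligible_centers", "predict_offsets",
           "evolution_matrix", "loss_gh", "loss_P", "loss_app",
           "solve_terms", "solve_state", "DegenerateSystemError",
           "gradient_descent_quadratic"]


class DegenerateSystemError(RuntimeError):
    """The least-squares system does not determine the requested unknowns."""


def training_offsets(n: int) -> np.ndarray:
    """The symmetric time-offset set {-n, ..., n} used during training."""
    if n < 0:
        raise ValueError("offset half-width n must be >= 0")
    return np.arange(-n, n + 1)


def eligible_centers(n_times: int, n: int) -> np.ndarray:
    """Center frames whose full offset window lies inside the sequence."""
    return np.arange(n, n_times - n)


def evolution_matrix(terms: FPETerms, ops: DerivativeOperators) -> np.ndarray:
    """L = D1 diag(g) + D2 diag(h), so that dP/dt = L P."""
    return ops.d1 * terms.g + ops.d2 * terms.h


def predict_offsets(P: np.ndarray, terms: FPETerms, ops: DerivativeOperators,
                    dt: float, offsets) -> np.ndarray:
    """Euler predictions P + i*dt*(D1(g*P) + D2(h*P)) for each offset i.

    Returns an array of shape (len(offsets), B).  No renormalization is
    applied: the operator itself (approximately) conserves mass for densities
    vanishing at the support edges.
    """
    P = np.asarray(P, dtype=float)
    offsets = np.asarray(offsets)
    rate = fpe_rhs(P, terms, ops)
    return P[None, :] + (offsets[:, None] * dt) * rate[None, :]


# ---------------------------------------------------------------------------
# loss functions


def _frame_loss(P, targets, offsets, terms, ops, dt) -> float:
    pred = predict_offsets(P, terms, ops, dt, offsets)
    return float(np.sum((pred - np.asarray(targets)) ** 2))


def loss_gh(series_list, terms: FPETerms, ops: DerivativeOperators,
            dt: float, n: int) -> float:
    """Sum over sequences, eligible centers and offsets i in {-n..n} of the
    squared L2 distance between the Euler prediction from frame t and the
    frame at t + i*dt of the same (current) series."""
    offsets = training_offsets(n)
    total = 0.0
    for values in _as_value_arrays(series_list):
        idx = eligible_centers(values.shape[0], n)
        rate = fpe_rhs(values[idx], terms, ops)
        for i in offsets:
            res = values[idx] + (i * dt) * rate - values[idx + i]
            total += float(np.sum(res * res))
    return total


def loss_P(P: np.ndarray, targets0: np.ndarray, offsets, terms: FPETerms,
           ops: DerivativeOperators, dt: float) -> float:
    """Single-frame quadratic loss against the fixed smoothed observations.

    ``targets0`` holds the smoothed-observation frames at ``offsets`` around
    the center; unlike :func:`loss_gh`, the targets never move between
    iterations.
    """
    return _frame_loss(P, targets0, offsets, terms, ops, dt)


def loss_app(P: np.ndarray, targets: np.ndarray, terms: FPETerms,
             ops: DerivativeOperators, dt: float, r: int) -> float:
    """Forecast-time state-fitting loss over the trailing offsets {-r..0}."""
    offsets = np.arange(-r, 1)
    return _frame_loss(P, targets, offsets, terms, ops, dt)


# ---------------------------------------------------------------------------
# exact minimizers


def _as_value_arrays(series_list):
    return [s.values if hasattr(s, "values") else np.asarray(s, dtype=float)
            for s in series_list]


def _gh_normal_system(centers_list, rhs_list, ops: DerivativeOperators):
    """Normal equations of the stacked system A(P_t) w ~ y_t over all frames.

    ``centers_list``/``rhs_list`` are matched (m, B) arrays.  Uses the
    identity  diag(P) M diag(P) = M * (P P^T)  to accumulate the four B x B
    blocks from a single Gram matrix S = sum_t P_t P_t^T.
    """
    Pmat = np.concatenate(centers_list, axis=0)
    Ymat = np.concatenate(rhs_list, axis=0)
    S = Pmat.T @ Pmat
    g11 = ops.d1.T @ ops.d1
    g12 = ops.d1.T @ ops.d2
    g22 = ops.d2.T @ ops.d2
    B = S.shape[0]
    M = np.empty((2 * B, 2 * B))
    M[:B, :B] = g11 * S
    M[:B, B:] = g12 * S
    M[B:, :B] = M[:B, B:].T
    M[B:, B:] = g22 * S
    rhs = np.concatenate([(Pmat * (Ymat @ ops.d1)).sum(axis=0),
                          (Pmat * (Ymat @ ops.d2)).sum(axis=0)])
    return M, rhs


def solve_terms(series_list, ops: DerivativeOperators, dt: float, n: int,
                prior: FPETerms | None = None, damping: float = 1e-10) -> FPETerms:
    """Exact minimizer of the gh loss for fixed densities.

    Stacks all eligible samples of all sequences into one least-squares
    problem in the 2B unknowns (g, h) and solves its normal equations.  With
    ``prior=None`` the minimum-norm solution is returned (pseudo-inverse);
    with a prior, directions the data does not determine stay at the prior's
    values via a tiny proximal damping term (``damping`` is relative to the
    mean diagonal of the normal matrix).

    Raises
    ------
    DegenerateSystemError
        If the system carries no information at all (e.g. stationary data
        with ``prior=None`` would be reported by the caller instead, since
        g = h = 0 is then a valid minimum-norm answer; raised only when the
        normal matrix vanishes identically).
    """
    offsets = training_offsets(n)
    s2 = float(np.sum(offsets.astype(float) ** 2))
    if s2 == 0.0:
        raise DegenerateSystemError("n = 0 gives no information about the terms")
    centers, rhs_frames = [], []
    for values in _as_value_arrays(series_list):
        idx = eligible_centers(values.shape[0], n)
        if idx.size == 0:
            continue
        centers.append(values[idx])
        # sum_i i * P(t + i dt); the i-weighted combination is all that the
        # symmetric-offset quadratic retains of the targets
        q = np.zeros_like(values[idx])
        for i in offsets:
            if i != 0:
                q += float(i) * values[idx + i]
        rhs_frames.append(q)
    if not centers:
        raise DegenerateSystemError("no eligible center frames")
    M, rhs = _gh_normal_system(centers, rhs_frames, ops)
    M *= s2 * dt * dt
    rhs *= dt
    scale = float(np.trace(M)) / M.shape[0]
    if scale <= 0.0:
        raise DegenerateSystemError("normal matrix vanishes: densities are zero")
    B = M.shape[0] // 2
    if prior is None:
        w, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    else:
        lam = damping * scale
        w0 = np.concatenate([prior.g, prior.h])
        w = np.linalg.solve(M + lam * np.eye(2 * B), rhs + lam * w0)
    return FPETerms(w[:B], w[B:])


def _pstep_normal(L: np.ndarray, offsets: np.ndarray, dt: float):
    """N = sum_i (I + i dt L)^T (I + i dt L), SPD since 0 is an offset."""
    B = L.shape[0]
    s1 = float(np.sum(offsets))
    s2 = float(np.sum(offsets.astype(float) ** 2))
    N = len(offsets) * np.eye(B) + (dt * s1) * (L + L.T) + (dt * dt * s2) * (L.T @ L)
    return N


def solve_state(targets: np.ndarray, offsets: np.ndarray, terms: FPETerms,
                ops: DerivativeOperators, dt: float,
                factor=None) -> np.ndarray:
    """Exact minimizer over P of the offset-prediction loss for fixed terms.

    ``targets`` has one row per offset.  ``factor`` may carry a pre-computed
    Cholesky factorization of the normal matrix (reused across frames that
    share an offset window).
    """
    offsets = np.asarray(offsets)
    L = evolution_matrix(terms, ops)
    if factor is None:
        factor = cho_factor(_pstep_normal(L, offsets, dt))
    rhs = np.asarray(targets).sum(axis=0) + dt * (L.T @ (offsets @ np.asarray(targets)))
    return cho_solve(factor, rhs)


def state_solver_factor(terms: FPETerms, ops: DerivativeOperators,
                        offsets: np.ndarray, dt: float):
    """Cholesky factorization of the P-step normal matrix for one window."""
    L = evolution_matrix(terms, ops)
    return cho_factor(_pstep_normal(L, np.asarray(offsets), dt))


# ---------------------------------------------------------------------------
# iterative (gradient-descent) backend


def gradient_descent_quadratic(M: np.ndarray, rhs: np.ndarray, w0: np.ndarray,
                               rate: float | None = None, epochs: int = 1000,
                               tol: float = 0.0) -> np.ndarray:
    """Plain gradient descent on the quadratic 0.5 w^T M w - rhs^T w.

    The default step size is 1 / lambda_max(M) with the largest eigenvalue
    estimated by power iteration; descent is then monotone.  ``w0``/``rhs``
    may be a vector or a column stack of independent problems sharing M.
    """
    if rate is None:
        v = np.ones(M.shape[0])
        for _ in range(50):
            nv = M @ v
            nrm = np.linalg.norm(nv)
            if nrm == 0.0:
                return w0.astype(float).copy()
            v = nv / nrm
        rate = 1.0 / float(v @ (M @ v))
    w = w0.astype(float).copy()
    for _ in range(epochs):
        grad = M @ w - rhs
        w -= rate * grad
        if tol > 0.0 and np.linalg.norm(grad) <= tol * max(1.0, np.linalg.norm(rhs)):
            break
    return w


def solve_terms_gd(series_list, ops: DerivativeOperators, dt: float, n: int,
                   start: FPETerms, rate: float | None = None,
                   epochs: int = 1000) -> FPETerms:
    """Gradient-descent counterpart of :func:`solve_terms`."""
    offsets = training_offsets(n)
    s2 = float(np.sum(offsets.astype(float) ** 2))
    centers, rhs_frames = [], []
    for values in _as_value_arrays(series_list):
        idx = eligible_centers(values.shape[0], n)
        centers.append(values[idx])
        q = np.zeros_like(values[idx])
        for i in offsets:
            if i != 0:
                q += float(i) * values[idx + i]
        rhs_frames.append(q)
    M, rhs = _gh_normal_system(centers, rhs_frames, ops)
    M *= s2 * dt * dt
    rhs *= dt
    w0 = np.concatenate([start.g, start.h])
    w = gradient_descent_quadratic(M, rhs, w0, rate, epochs)
    B = M.shape[0] // 2
    return FPETerms(w[:B], w[B:])


def solve_state_gd(targets: np.ndarray, offsets: np.ndarray, terms: FPETerms,
                   ops: DerivativeOperators, dt: float, start: np.ndarray,
                   rate: float | None = None, epochs: int = 1000) -> np.ndarray:
    """Gradient-descent counterpart of :func:`solve_state`."""
    offsets = np.asarray(offsets)
    L = evolution_matrix(terms, ops)
    N = _pstep_normal(L, offsets, dt)
    rhs = np.asarray(targets).sum(axis=0) + dt * (L.T @ (offsets @ np.asarray(targets)))
    return gradient_descent_quadratic(N, rhs, np.asarray(start, dtype=float), rate, epochs)
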