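"""Alternating training: terms step, then densities step, until the summed
loss stops improving.

Each iteration first re-fits the drift/diffusion vectors to the current
denoised densities (targets: the current densities themselves), then re-fits
every density frame to the fixed smoothed observations under the new terms
(targets: always the smoothed observations from initialization, never the
moving densities).  With the exact backend both halves are global quadratic
minimizations, so each weakly decreases its own loss at fixed counterpart.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import core
from .core import loss_gh, solve_terms, solve_terms_gd, state_solver_factor
from .data import Dataset, DensitySeries
from .forward import FPETerms
from .grid import DerivativeOperators, Grid
from .initialization import SGConfig, lls_init, sg_smooth

__all__ = ["TrainConfig", "TrainState", "gh_step", "p_step", "train",
           "initialize_state", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Hyperparameters of the alternating loop.

    ``n`` is the offset half-width: predictions run over {-n..n} time gaps.
    Training stops once the summed loss has failed to improve its running
    best for ``patience`` consecutive iterations (relative improvement
    threshold ``rel_improvement``), or at ``max_iterations``.
    """

    n: int = 2
    patience: int = 20
    max_iterations: int = 200
    rel_improvement: float = 1e-10
    backend: str = "exact"
    sg: SGConfig = field(default_factory=SGConfig)
    # gradient-backend hyperparameters (ignored by the exact backend)
    gd_rate: float | None = None
    gd_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("offset half-width n must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.backend not in ("exact", "gradient"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class TrainState:
    """Mutable state of the alternating loop.

    ``P0`` holds the fixed smoothed observations; ``P_hat`` the trainable
    densities; ``terms`` the current drift/diffusion estimate.  Iteration-0
    artifacts (``terms_init`` from least squares, ``terms_first`` after the
    first terms step, i.e. the best terms obtainable from merely smoothed
    data) are kept for before/after comparisons.  ``best_total``/``best_k``
    track the smallest summed loss seen, which drives the patience-based
    stop; training returns the final (converged) iterate.
    """

    terms: FPETerms
    P_hat: list
    P0: list
    dt: float
    k: int = 0
    history: list = field(default_factory=list)
    metric_history: list = field(default_factory=list)
    terms_init: FPETerms | None = None
    terms_first: FPETerms | None = None
    best_total: float = np.inf
    best_k: int = 0


def initialize_state(train_noisy: list, ops: DerivativeOperators,
                     cfg: TrainConfig) -> TrainState:
    """Smooth the noisy sequences and fit the warm-start terms."""
    P0 = [sg_smooth(s, cfg.sg) for s in train_noisy]
    terms0 = lls_init(P0, ops)
    P_hat = [copy.deepcopy(s) for s in P0]
    return TrainState(terms=terms0, P_hat=P_hat, P0=P0, dt=P0[0].dt,
                      terms_init=copy.deepcopy(terms0))


def gh_step(state: TrainState, cfg: TrainConfig,
            ops: DerivativeOperators) -> FPETerms:
    """Exact (or gradient) minimizer of the terms loss at fixed densities."""
    values = [s.values for s in state.P_hat]
    if cfg.backend == "gradient":
        return solve_terms_gd(values, ops, state.dt, cfg.n, start=state.terms,
                              rate=cfg.gd_rate, epochs=cfg.gd_epochs)
    return solve_terms(values, ops, state.dt, cfg.n)


def _offset_windows(n_times: int, n: int):
    """Group frame indices by their available offset window.

    Interior frames share the full window {-n..n}; frames within ``n`` of a
    sequence edge use the truncated offsets that stay inside the sequence.
    """
    groups = {}
    for t in range(n_times):
        lo = -min(n, t)
        hi = min(n, n_times - 1 - t)
        groups.setdefault((lo, hi), []).append(t)
    return groups


def p_step(state: TrainState, cfg: TrainConfig,
           ops: DerivativeOperators) -> list:
    """Re-fit every density frame to the fixed smoothed observations.

    Frames are independent quadratic problems sharing one normal matrix per
    offset window, so each window is factorized once and solved for all its
    frames (and all sequences) in a single batched solve.
    """
    from scipy.linalg import cho_solve

    n_times = state.P0[0].n_times
    n_seq = len(state.P0)
    B = state.P0[0].grid.n_bins
    windows = _offset_windows(n_times, cfg.n)
    P0a = np.stack([s.values for s in state.P0])       # (S, T, B)
    out = np.empty_like(P0a)
    L = core.evolution_matrix(state.terms, ops)
    for (lo, hi), frames in windows.items():
        offsets = np.arange(lo, hi + 1)
        fr = np.asarray(frames)
        sum0 = np.zeros((n_seq, fr.size, B))
        sum1 = np.zeros((n_seq, fr.size, B))
        for i in offsets:
            sum0 += P0a[:, fr + i, :]
            sum1 += float(i) * P0a[:, fr + i, :]
        rhs = sum0 + state.dt * (sum1 @ L)             # rows times L^T
        if cfg.backend == "gradient":
            start = np.stack([state.P_hat[si].values[fr] for si in range(n_seq)])
            N = core._pstep_normal(L, offsets, state.dt)
            flat = core.gradient_descent_quadratic(
                N, rhs.reshape(-1, B).T, start.reshape(-1, B).T,
                rate=cfg.gd_rate, epochs=cfg.gd_epochs)
            out[:, fr, :] = flat.T.reshape(n_seq, fr.size, B)
        else:
            factor = state_solver_factor(state.terms, ops, offsets, state.dt)
            sol = cho_solve(factor, rhs.reshape(-1, B).T)
            out[:, fr, :] = sol.T.reshape(n_seq, fr.size, B)
    return [DensitySeries(out[si], s.t0, s.dt, s.grid)
            for si, s in enumerate(state.P_hat)]


def _loss_P_total(state: TrainState, cfg: TrainConfig,
                  ops: DerivativeOperators) -> float:
    """Sum of the per-frame density losses over all frames and sequences,
    each frame scored on its own (possibly truncated) offset window."""
    n_times = state.P0[0].n_times
    windows = _offset_windows(n_times, cfg.n)
    P0a = np.stack([s.values for s in state.P0])
    Pha = np.stack([s.values for s in state.P_hat])
    from .forward import fpe_rhs
    rate = fpe_rhs(Pha, state.terms, ops)
    total = 0.0
    for (lo, hi), frames in windows.items():
        fr = np.asarray(frames)
        for i in range(lo, hi + 1):
            res = Pha[:, fr, :] + (i * state.dt) * rate[:, fr, :] - P0a[:, fr + i, :]
            total += float(np.sum(res * res))
    return total


def _record_metrics(state: TrainState, truth) -> None:
    """Append normalized-error metrics for one iteration (simulation truth).

    ``truth`` is (clean_series_list, true FPETerms, interior boolean mask).
    """
    clean, true_terms, interior = truth
    est = np.concatenate([s.values.ravel() for s in state.P_hat])
    ref = np.concatenate([s.values.ravel() for s in clean])

    def rel(a, b):
        return float(np.linalg.norm(a - b) / np.linalg.norm(b))

    state.metric_history.append({
        "k": state.k,
        "E_P": rel(est, ref),
        "E_g": rel(state.terms.g, true_terms.g),
        "E_h": rel(state.terms.h, true_terms.h),
        "E_g_int": rel(state.terms.g[interior], true_terms.g[interior]),
        "E_h_int": rel(state.terms.h[interior], true_terms.h[interior]),
    })


def train(dataset: Dataset | list, cfg: TrainConfig,
          ops: DerivativeOperators, truth=None) -> TrainState:
    """Run the full alternating loop on the training sequences.

    Accepts a :class:`~fpinv.data.Dataset` (its ``train`` split is used) or a
    plain list of noisy :class:`~fpinv.data.DensitySeries`.  Returns the
    final iterate after the patience-based stop on the summed loss.  With
    ``truth=(clean_list, true_terms, interior_mask)`` (simulation studies),
    normalized errors are recorded per iteration in ``metric_history``.
    """
    noisy = dataset.train if isinstance(dataset, Dataset) else dataset
    state = initialize_state(noisy, ops, cfg)
    stall = 0
    for k in range(1, cfg.max_iterations + 1):
        state.k = k
        state.terms = gh_step(state, cfg, ops)
        if k == 1:
            state.terms_first = copy.deepcopy(state.terms)
        l_gh = loss_gh([s.values for s in state.P_hat], state.terms, ops,
                       state.dt, cfg.n)
        state.P_hat = p_step(state, cfg, ops)
        l_p = _loss_P_total(state, cfg, ops)
        total = l_gh + l_p
        state.history.append((l_gh, l_p))
        if truth is not None:
            _record_metrics(state, truth)
        if total < state.best_total * (1.0 - cfg.rel_improvement):
            state.best_total = total
            state.best_k = k
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return state


def save_checkpoint(state: TrainState, path) -> None:
    """Bit-exact checkpoint of (terms, denoised densities, history)."""
    arrays = {"g": state.terms.g, "h": state.terms.h,
              "history": np.asarray(state.history, dtype=float).reshape(-1, 2),
              "k": np.array([state.k]), "best_k": np.array([state.best_k]),
              "best_total": np.array([state.best_total]), "dt": np.array([state.dt])}
    for i, s in enumerate(state.P_hat):
        arrays[f"P_hat_{i:03d}"] = s.values
        arrays[f"t0_{i:03d}"] = np.array([s.t0])
    if state.terms_init is not None:
        arrays["g_init"] = state.terms_init.g
        arrays["h_init"] = state.terms_init.h
    if state.terms_first is not None:
        arrays["g_first"] = state.terms_first.g
        arrays["h_first"] = state.terms_first.h
    np.savez(path, **arrays)


def load_checkpoint(path, grid: Grid) -> TrainState:
    with np.load(path) as npz:
        dt = float(npz["dt"][0])
        P_hat = []
        i = 0
        while f"P_hat_{i:03d}" in npz:
            P_hat.append(DensitySeries(npz[f"P_hat_{i:03d}"],
                                       float(npz[f"t0_{i:03d}"][0]), dt, grid))
            i += 1
        state = TrainState(terms=FPETerms(npz["g"], npz["h"]), P_hat=P_hat,
                           P0=[], dt=dt, k=int(npz["k"][0]),
                           history=[tuple(r) for r in npz["history"]],
                           best_total=float(npz["best_total"][0]),
                           best_k=int(npz["best_k"][0]))
        if "g_init" in npz:
            state.terms_init = FPETerms(npz["g_init"], npz["h_init"])
        if "g_first" in npz:
            state.terms_first = FPETerms(npz["g_first"], npz["h_first"])
    return state
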