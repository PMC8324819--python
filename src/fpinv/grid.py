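"""Uniform 1-D spatial grid and fixed finite-difference derivative operators.

The density, drift and diffusion functions are discretized on bin centers of a
uniform grid.  Spatial derivatives in the discrete Fokker-Planck operator are
taken by fixed (non-trainable) banded matrices: central stencils of a
configurable accuracy order on interior rows, matched-order one-sided stencils
on the edge rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = ["Grid", "DerivativeOperators", "build_grid",
           "build_first_derivative", "build_second_derivative", "fd_weights"]

#: smallest grid the stencils and the default Savitzky-Golay window support
MIN_BINS = 7


@dataclass(frozen=True)
class Grid:
    """Uniform discretization of the observable's support into bins.

    Bin centers sit at ``x_min + (j + 1/2) * dx`` for ``j = 0 .. n_bins-1``,
    so the support edges are treated symmetrically.
    """

    x_min: float
    x_max: float
    n_bins: int

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        j = np.arange(self.n_bins)
        return self.x_min + (j + 0.5) * self.dx


def build_grid(x_min: float, x_max: float, n_bins: int) -> Grid:
    """Validate and build a :class:`Grid`.

    Raises
    ------
    ValueError
        If the support is degenerate or ``n_bins`` is below the minimum the
        derivative stencils require.
    """
    if not x_max > x_min:
        raise ValueError(f"degenerate support: x_max={x_max} must exceed x_min={x_min}")
    n_bins = int(n_bins)
    if n_bins < MIN_BINS:
        raise ValueError(f"n_bins={n_bins} below minimum {MIN_BINS}")
    return Grid(float(x_min), float(x_max), n_bins)


def fd_weights(offsets: np.ndarray, deriv: int) -> np.ndarray:
    """Finite-difference weights on integer ``offsets`` (unit spacing) for the
    ``deriv``-th derivative at offset 0.

    Solves the moment conditions sum_j w_j * o_j**m / m! = delta(m, deriv)
    for m = 0 .. len(offsets)-1, then enforces an exactly zero row sum (the
    weight at the largest-|w| node is recomputed as minus the sum of the
    others) so constants are annihilated in floating point, not merely to
    rounding.
    """
    offsets = np.asarray(offsets, dtype=float)
    p = len(offsets)
    if deriv >= p:
        raise ValueError("stencil too short for requested derivative")
    vander = np.array([offsets**m / factorial(m) for m in range(p)])
    rhs = np.zeros(p)
    rhs[deriv] = 1.0
    w = np.linalg.solve(vander, rhs)
    k = int(np.argmax(np.abs(w)))
    w[k] = 0.0
    w[k] = -w.sum()
    return w


def _derivative_matrix(grid: Grid, deriv: int, order: int, edge: str) -> np.ndarray:
    """Banded derivative matrix: central interior rows, configurable edges.

    A central stencil of accuracy ``order`` for derivative ``deriv`` uses
    ``order + deriv - 1`` (rounded up to odd) points.  Edge policy:

    * ``"zero"`` -- the central stencil is applied everywhere with the
      function treated as identically zero beyond the support (finite-support
      densities).  The resulting advection-diffusion operator is dissipative
      at the support edges, which keeps explicit forward solves stable.
    * ``"onesided"`` -- matched-order one-sided stencils (``order + deriv``
      points) on the first/last ``hw`` rows; exact for polynomials up to the
      edge, but the no-boundary-condition forward operator then has spurious
      growing modes seeded by any boundary tail.
    """
    if order not in (2, 4):
        raise ValueError(f"unsupported stencil order {order}; choose 2 or 4")
    if edge not in ("zero", "onesided"):
        raise ValueError(f"unknown edge policy {edge!r}")
    n = grid.n_bins
    width_c = order + deriv - 1
    if width_c % 2 == 0:
        width_c += 1
    hw = width_c // 2
    width_e = order + deriv
    if n < max(width_c, width_e):
        raise ValueError(f"n_bins={n} smaller than stencil width")

    mat = np.zeros((n, n))
    w_central = fd_weights(np.arange(-hw, hw + 1), deriv)
    for row in range(hw, n - hw):
        mat[row, row - hw:row + hw + 1] = w_central
    for row in range(hw):
        if edge == "zero":
            mat[row, :row + hw + 1] = w_central[hw - row:]
            mat[n - 1 - row, n - 1 - row - hw:] = w_central[:hw + row + 1]
        else:
            offs = np.arange(width_e) - row
            mat[row, :width_e] = fd_weights(offs, deriv)
            offs = np.arange(-width_e + 1, 1) + row
            mat[n - 1 - row, n - width_e:] = fd_weights(offs, deriv)
    return mat / grid.dx**deriv


def build_first_derivative(grid: Grid, order: int = 4, edge: str = "zero") -> np.ndarray:
    """First-derivative matrix D1 (units 1/x)."""
    return _derivative_matrix(grid, 1, order, edge)


def build_second_derivative(grid: Grid, order: int = 4, edge: str = "zero") -> np.ndarray:
    """Second-derivative matrix D2 (units 1/x**2)."""
    return _derivative_matrix(grid, 2, order, edge)


@dataclass
class DerivativeOperators:
    """The pair of fixed derivative matrices acting on per-bin vectors."""

    d1: np.ndarray
    d2: np.ndarray
    order: int = 4
    edge: str = "zero"

    @classmethod
    def build(cls, grid: Grid, order: int = 4, edge: str = "zero") -> "DerivativeOperators":
        return cls(build_first_derivative(grid, order, edge),
                   build_second_derivative(grid, order, edge), order, edge)
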