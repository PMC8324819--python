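"""Forward Fokker-Planck solvers and the three benchmark systems.

The governing equation, in the sign convention used throughout the package, is

    dP/dt = d/dx ( g(x) P ) + d2/dx2 ( h(x) P )

with drift term ``g`` (units x/time) and diffusion term ``h`` (units
x**2/time).  Three parameterized systems supply ground truth:

* ``flux``   -- Ornstein-Uhlenbeck heat-flux dynamics, g = theta*x, h = D;
  has an analytic Gaussian solution.
* ``bubble`` -- generalized Bessel process for DNA-bubble lengths,
  g = mu/x - eps, h = 1/2; solved numerically.
* ``wealth`` -- agent's-wealth dynamics, g = x - m, h = (lambda/2) x**2;
  solved numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid, DerivativeOperators, build_grid

__all__ = ["FPETerms", "ExampleSpec", "example_spec", "example_terms",
           "ou_analytic_density", "fpe_rhs", "rk4_solve", "SolverError",
           "EXAMPLE_NAMES"]

EXAMPLE_NAMES = ("flux", "bubble", "wealth")


class SolverError(RuntimeError):
    """Numeric failure inside a forward solve (instability, non-finite values)."""


@dataclass
class FPETerms:
    """Per-bin drift vector ``g`` and diffusion vector ``h``."""

    g: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.g.shape != self.h.shape or self.g.ndim != 1:
            raise ValueError("g and h must be 1-D vectors of equal length")
        if not (np.isfinite(self.g).all() and np.isfinite(self.h).all()):
            raise ValueError("FPE terms must be finite everywhere on the grid")


@dataclass
class ExampleSpec:
    """One benchmark system: name, parameters, grid and frame spacing dt."""

    name: str
    parameters: dict
    grid: Grid
    dt: float
    #: internal RK4 substeps per saved frame (stability of the explicit solve)
    substeps: int = 10

    def __post_init__(self) -> None:
        if self.name not in EXAMPLE_NAMES:
            raise ValueError(f"unknown example {self.name!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for key in {"flux": ("D", "theta"), "bubble": ("mu",),
                    "wealth": ("lam",)}[self.name]:
            if self.parameters.get(key, 0.0) <= 0:
                raise ValueError(f"parameter {key!r} must be positive")


# Benchmark defaults: the study conditions under which all results are
# generated.  Grids, dt and parameters per system; substeps chosen for
# explicit-RK4 stability at each grid's diffusion number.
_PRESETS = {
    "flux": dict(parameters={"D": 0.0013, "theta": 2.86},
                 support=(-0.01, 0.1), n_bins=110, dt=0.001, substeps=10),
    "bubble": dict(parameters={"mu": 1.0, "eps": 0.2},
                   support=(0.1, 1.1), n_bins=100, dt=0.001, substeps=20),
    "wealth": dict(parameters={"lam": 0.4, "m": 1.0},
                   support=(0.0, 1.0), n_bins=100, dt=5e-4, substeps=10),
}


def example_spec(name: str, **overrides) -> ExampleSpec:
    """Build the default :class:`ExampleSpec` for a named benchmark system."""
    preset = dict(_PRESETS[name])
    preset.update({k: v for k, v in overrides.items() if k != "parameters"})
    params = dict(_PRESETS[name]["parameters"])
    params.update(overrides.get("parameters", {}))
    grid = build_grid(*preset["support"], preset["n_bins"])
    return ExampleSpec(name, params, grid, preset["dt"], preset["substeps"])


def example_terms(spec: ExampleSpec) -> FPETerms:
    """Evaluate the true drift/diffusion vectors of a benchmark on its grid."""
    x = spec.grid.centers
    p = spec.parameters
    if spec.name == "flux":
        return FPETerms(p["theta"] * x, np.full_like(x, p["D"]))
    if spec.name == "bubble":
        if np.any(x <= 0):
            raise ValueError("bubble drift mu/x - eps requires a grid with x > 0")
        return FPETerms(p["mu"] / x - p["eps"], np.full_like(x, 0.5))
    # wealth
    return FPETerms(x - p["m"], 0.5 * p["lam"] * x**2)


def ou_analytic_density(D: float, theta: float, x0: float, t: float,
                        grid: Grid) -> np.ndarray:
    """Analytic Gaussian density of the OU process at time ``t``.

    Mean mu(t) = x0 * exp(-theta t); variance D (1 - exp(-2 theta t)) / theta,
    the stationary variance D/theta approached at rate 2*theta.
    """
    if t <= 0 or theta <= 0 or D <= 0:
        raise ValueError("t, theta and D must all be positive")
    mean = x0 * np.exp(-theta * t)
    var = D * (1.0 - np.exp(-2.0 * theta * t)) / theta
    x = grid.centers
    return np.exp(-((x - mean) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)


def fpe_rhs(P: np.ndarray, terms: FPETerms, ops: DerivativeOperators) -> np.ndarray:
    """Discrete Fokker-Planck right-hand side D1 (g*P) + D2 (h*P)."""
    P = np.asarray(P, dtype=float)
    if P.shape[-1] != terms.g.shape[0]:
        raise ValueError("density length does not match the terms' grid")
    return (terms.g * P) @ ops.d1.T + (terms.h * P) @ ops.d2.T


def rk4_solve(P0: np.ndarray, terms: FPETerms, ops: DerivativeOperators,
              dt: float, n_steps: int, substeps: int = 10) -> np.ndarray:
    """Advance a density with classical RK4, saving frames every ``dt``.

    ``P0`` may be a single density vector or an (m, B) stack of densities
    evolving under the same terms (the operator is linear, so columns evolve
    independently).  Returns an array of ``n_steps + 1`` frames including the
    initial one.

    Raises
    ------
    SolverError
        If non-finite values appear (explicit-scheme instability); the
        message names the failing frame.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    P = np.asarray(P0, dtype=float).copy()
    frames = np.empty((n_steps + 1,) + P.shape)
    frames[0] = P
    hsub = dt / substeps
    for step in range(1, n_steps + 1):
        for _ in range(substeps):
            k1 = fpe_rhs(P, terms, ops)
            k2 = fpe_rhs(P + 0.5 * hsub * k1, terms, ops)
            k3 = fpe_rhs(P + 0.5 * hsub * k2, terms, ops)
            k4 = fpe_rhs(P + hsub * k3, terms, ops)
            P = P + (hsub / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.isfinite(P).all():
            raise SolverError(f"RK4 produced non-finite values at frame {step}; "
                              "increase substeps")
        frames[step] = P
    return frames
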