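"""Initialization: Savitzky-Golay smoothing and least-squares warm start.

The smoothed noisy densities P0 serve two roles: they are the starting value
of the trainable densities and the fixed comparison target of every density-
update step.  The initial drift/diffusion vectors come from a ridge-
stabilized linear least squares fit of the discrete Fokker-Planck relation
to finite-difference time derivatives of the smoothed data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .core import DegenerateSystemError, _gh_normal_system
from .data import DensitySeries
from .forward import FPETerms
from .grid import DerivativeOperators

__all__ = ["SGConfig", "sg_smooth", "lls_init"]


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay filter parameters (smoothing along x only).

    The default (window 15, quartic) was fixed by a bias/variance sweep on
    the three benchmark systems: it suppresses the short-wavelength noise
    that the derivative stencils amplify most, while its quartic fit keeps
    the polynomial bias negligible for the narrowest benchmark features
    (~5 bins per standard deviation).
    """

    window: int = 15
    polyorder: int = 4

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window <= 0:
            raise ValueError("SG window must be odd and positive")
        if not 1 <= self.polyorder < self.window:
            raise ValueError("SG polyorder must satisfy 1 <= polyorder < window")


def sg_smooth(series: DensitySeries, cfg: SGConfig = SGConfig()) -> DensitySeries:
    """Smooth each frame independently along x; the time axis is untouched."""
    if cfg.window > series.grid.n_bins:
        raise ValueError(f"SG window {cfg.window} exceeds n_bins={series.grid.n_bins}")
    smoothed = savgol_filter(series.values, cfg.window, cfg.polyorder,
                             axis=1, mode="interp")
    return replace(series, values=smoothed)


def lls_init(smoothed: list, ops: DerivativeOperators,
             ridge: float = 0.0) -> FPETerms:
    """Initial (g, h) by linear least squares on smoothed densities.

    Time derivatives are estimated by central differences at interior frames
    and first-order one-sided differences at sequence ends, so every frame
    contributes one row block [D1 diag(P), D2 diag(P)] of the stacked system
    dP/dt ~ A(P) (g, h).  The normal matrix of this system spans ~14 decades
    (density values near the support edges are tiny), so the default solve is
    the minimum-norm least-squares solution with a machine-precision singular
    value cutoff; ``ridge`` adds an optional explicit Tikhonov term
    ``ridge * lambda_max`` on top, but any ridge large enough to matter
    visibly biases the recovered terms.

    Raises
    ------
    DegenerateSystemError
        For unidentifiable data (e.g. all-stationary sequences whose time
        derivatives vanish), with diagnostics in the message.
    """
    centers, dPdt = [], []
    for s in smoothed:
        v = s.values
        if v.shape[0] < 3:
            raise DegenerateSystemError("central time differencing needs >= 3 frames")
        y = np.empty_like(v)
        y[1:-1] = (v[2:] - v[:-2]) / (2.0 * s.dt)
        y[0] = (v[1] - v[0]) / s.dt
        y[-1] = (v[-1] - v[-2]) / s.dt
        centers.append(v)
        dPdt.append(y)
    M, rhs = _gh_normal_system(centers, dPdt, ops)
    lam_max = float(np.linalg.norm(M, 2))
    if lam_max == 0.0:
        raise DegenerateSystemError("densities are identically zero")
    rhs_scale = float(np.linalg.norm(rhs))
    if rhs_scale <= 1e-12 * lam_max * np.sqrt(M.shape[0]):
        raise DegenerateSystemError(
            "time derivatives vanish: stationary data does not identify (g, h)")
    B = M.shape[0] // 2
    if ridge > 0.0:
        M = M + ridge * lam_max * np.eye(2 * B)
    w, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    return FPETerms(w[:B], w[B:])
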