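"""Power-law rheology of bone marrow.

Bone marrow is treated as a shear-thinning power-law fluid,

    eta = k * gamma_dot**(n - 1) * H(T),

with consistency k = 0.017 Pa.s^n and index n = 0.708, clamped to the
working range [0.001, 0.01] Pa.s.  The Arrhenius temperature factor H(T)
is the identity under isothermal operation (the default); the full
exponential form is available when `arrhenius_enabled` is set.

Note that k itself exceeds the upper clamp, so at shear rates below
about 6.15 1/s the apparent viscosity sits at the 0.01 Pa.s ceiling;
the clamps are applied exactly as specified rather than reconciling the
constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MarrowRheology:
    """Power-law fluid parameters (SI units)."""

    k: float = 0.017          # consistency, Pa.s^n
    n: float = 0.708          # power-law index
    eta_max: float = 0.01     # upper viscosity clamp, Pa.s
    eta_min: float = 0.001    # lower viscosity clamp, Pa.s
    rho: float = 1050.0       # density, kg/m^3
    arrhenius_enabled: bool = False
    alpha: float = 0.0        # Arrhenius activation ratio
    T0: float = 0.0           # reference offset temperature, K
    Talpha: float = 310.0     # activation temperature, K

    def __post_init__(self) -> None:
        if self.k <= 0 or self.n <= 0:
            raise ValueError("k and n must be > 0")
        if not 0 < self.eta_min < self.eta_max:
            raise ValueError("need 0 < eta_min < eta_max")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")

    @property
    def clamp_crossover(self) -> float:
        """Shear rate where k * g**(n-1) first drops below eta_max."""
        if self.n >= 1 or self.k <= self.eta_max:
            return 0.0
        return (self.k / self.eta_max) ** (1.0 / (1.0 - self.n))


def deformation_rate(grad_u) -> float:
    """Scalar shear rate from a velocity-gradient tensor.

    Uses gamma_dot = sqrt(0.5 * D:D) with D_ij = du_j/dx_i + du_i/dx_j
    (twice the strain-rate tensor), so simple shear du_x/dy = G gives
    gamma_dot = G and any rigid rotation gives zero.  Accepts 2x2 or
    3x3 tensors, or stacked arrays thereof (leading axes preserved).
    """
    g = np.asarray(grad_u, float)
    if not np.all(np.isfinite(g)):
        raise ValueError("velocity gradient contains non-finite entries")
    D = g + np.swapaxes(g, -1, -2)
    gd = np.sqrt(0.5 * np.sum(D * D, axis=(-1, -2)))
    return float(gd) if gd.ndim == 0 else gd


def arrhenius_factor(params: MarrowRheology, T: float | None = None) -> float:
    """Temperature factor H(T); identity unless Arrhenius is enabled."""
    if not params.arrhenius_enabled or T is None:
        return 1.0
    if np.isclose(T, params.T0):
        raise ValueError("T = T0 makes the Arrhenius exponent singular")
    return float(np.exp(params.alpha * (1.0 / (T - params.T0)
                                        - 1.0 / (params.Talpha - params.T0))))


def apparent_viscosity(params: MarrowRheology, gamma_dot,
                       T: float | None = None, clamp: bool = True):
    """Clamped power-law apparent viscosity (Pa.s).

    At zero shear with n < 1 the unclamped law diverges; the clamp limit
    eta_max is returned there.  Scalar in, scalar out; arrays accepted.
    """
    g = np.asarray(gamma_dot, float)
    if np.any(g < 0):
        raise ValueError("shear rate must be >= 0")
    H = arrhenius_factor(params, T)
    with np.errstate(divide="ignore"):
        eta = np.where(g > 0, params.k * np.power(np.maximum(g, 1e-300),
                                                  params.n - 1.0) * H,
                       np.inf if params.n < 1 else (params.k * H if params.n == 1
                                                    else 0.0))
    if clamp:
        eta = np.clip(eta, params.eta_min, params.eta_max)
    out = np.asarray(eta, float)
    return float(out) if out.ndim == 0 else out


def viscosity_table(params: MarrowRheology, gamma_dots) -> "list[tuple]":
    """(gamma_dot, eta) pairs for the diagnostic CLI table."""
    return [(float(g), apparent_viscosity(params, g)) for g in gamma_dots]
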