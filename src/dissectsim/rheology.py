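"""Shear-thinning blood rheology: the Quemada viscosity model.

The Quemada model expresses apparent viscosity as

    mu(gamma) = mu_p * (1 - 0.5 * k(gamma) * H)^-2,
    k(gamma)  = (k0 + k_inf * sqrt(gamma/gamma_c)) / (1 + sqrt(gamma/gamma_c)),

with plasma viscosity ``mu_p``, hematocrit ``H`` and the structural
parameters ``k0`` (zero-shear), ``k_inf`` (infinite-shear) and the
characteristic shear rate ``gamma_c``.  The default parameter set is the
standard whole-blood Quemada parameterization at 45% hematocrit
(mu_p = 1.2 mPa.s, k0 = 4.33, k_inf = 2.07, gamma_c = 1.88 1/s), which puts
the high-shear asymptote near 4.2 mPa.s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: regularization floor inside sqrt(gamma/gamma_c); avoids the infinite
#: derivative of sqrt at zero shear in Newton-type loops.  Kept tiny so the
#: zero-shear viscosity is unaffected well beyond solver tolerance (the
#: zero-shear Quemada factor is near-critical at 45% hematocrit, so a large
#: floor would visibly shift mu(0)).
GAMMA_FLOOR = 1e-12


def shear_rate_magnitude(velocity_gradient: np.ndarray) -> np.ndarray:
    """Scalar shear rate gamma = sqrt(2 D:D) from a 2x2 velocity-gradient
    tensor (or an (..., 2, 2) batch); D is the symmetric strain rate."""
    G = np.asarray(velocity_gradient, float)
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite velocity gradient")
    D = 0.5 * (G + np.swapaxes(G, -1, -2))
    return np.sqrt(2.0 * np.einsum("...ij,...ij->...", D, D))


@dataclass(frozen=True)
class QuemadaParams:
    plasma_viscosity: float = 1.2e-3  # Pa.s
    hematocrit: float = 0.45
    k0: float = 4.33
    k_inf: float = 2.07
    gamma_c: float = 1.88  # 1/s

    def __post_init__(self) -> None:
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError(f"hematocrit must lie in (0, 1), got {self.hematocrit}")
        if self.plasma_viscosity <= 0 or self.gamma_c <= 0:
            raise ValueError("plasma_viscosity and gamma_c must be positive")
        # finite, positive viscosity on gamma in [0, inf) requires
        # 1 - k H / 2 > 0 at both structural limits
        for name, k in (("k0", self.k0), ("k_inf", self.k_inf)):
            if 1.0 - 0.5 * k * self.hematocrit <= 0.0:
                raise ValueError(
                    f"{name} * hematocrit / 2 = {0.5 * k * self.hematocrit:.3f} >= 1: "
                    "viscosity would diverge"
                )

    @property
    def mu_zero_shear(self) -> float:
        return self.plasma_viscosity * (1.0 - 0.5 * self.k0 * self.hematocrit) ** -2

    @property
    def mu_high_shear(self) -> float:
        return self.plasma_viscosity * (1.0 - 0.5 * self.k_inf * self.hematocrit) ** -2


def quemada_viscosity(gamma: np.ndarray | float, params: QuemadaParams) -> np.ndarray | float:
    """Apparent viscosity (Pa.s) at shear rate *gamma* (1/s, >= 0)."""
    g = np.maximum(np.asarray(gamma, float), 0.0)
    s = np.sqrt(np.maximum(g, GAMMA_FLOOR) / params.gamma_c)
    k = (params.k0 + params.k_inf * s) / (1.0 + s)
    mu = params.plasma_viscosity * (1.0 - 0.5 * k * params.hematocrit) ** -2
    if np.isscalar(gamma):
        return float(mu)
    return mu


@dataclass(frozen=True)
class FluidProperties:
    """Bulk fluid model: density plus either Quemada rheology or a constant
    viscosity override (``constant_viscosity`` wins when set)."""

    density: float = 1060.0  # kg/m^3
    rheology: QuemadaParams = QuemadaParams()
    constant_viscosity: float | None = None  # Pa.s

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.constant_viscosity is not None and self.constant_viscosity <= 0:
            raise ValueError("constant viscosity must be positive")

    def viscosity(self, gamma: np.ndarray | float) -> np.ndarray | float:
        if self.constant_viscosity is not None:
            if np.isscalar(gamma):
                return self.constant_viscosity
            return np.full(np.shape(gamma), self.constant_viscosity)
        return quemada_viscosity(gamma, self.rheology)


def viscosity_field(gamma_field: np.ndarray, props: FluidProperties) -> np.ndarray:
    """Pointwise viscosity from a shear-rate field."""
    return np.asarray(props.viscosity(gamma_field), float)
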