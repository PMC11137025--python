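"""Quasi-static force propagation around a bead dragged in the cytoplasm.

Models the optical-tweezer experiment in which a 1 µm bead is displaced by
200 nm and the decay of the surrounding displacement field reports how far
forces propagate.  Full vector elasticity around a translating sphere is
replaced by a pseudo-one-dimensional spreading model: the transmitted force
spreads over an area growing as ``(x / r0)**p`` (default ``p = 2``), so the
local stress is ``F * (r0 / x)**p`` and the local strain follows from
inverting the material law.  This preserves the 1/x displacement decay of
the linear case and makes the strain-stiffening (wild-type) versus
strain-softening (vimentin-null, cytoskeletal damage) comparison
analytically checkable.

All lengths are in µm, strains dimensionless; the drag is quasi-static (the
experimental 2 µm/s drag speed is metadata only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.integrate import cumulative_simpson

from .params import ParameterError


@dataclass(frozen=True)
class MaterialLaw:
    """Uniaxial constitutive law of the cytoplasm.

    * ``linear``:     sigma = e0 * eps
    * ``stiffening``: sigma = e0 * eps * (1 + (eps / eps_c)**(n_exp - 1));
      the secant modulus grows with strain (intact vimentin network).
    * ``softening``:  bilinear, tangent e0 up to eps_c then
      ``residual_fraction * e0`` (damaged cytoskeleton); ``n_exp`` holds the
      residual fraction in (0, 1).
    """

    kind: str = "linear"
    e0: float = 1.0
    eps_c: float = 0.05
    n_exp: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "stiffening", "softening"):
            raise ParameterError(f"unknown material law kind {self.kind!r}")
        if self.e0 <= 0 or self.eps_c <= 0:
            raise ParameterError("e0 and eps_c must be > 0")
        if self.kind == "stiffening" and self.n_exp <= 1:
            raise ParameterError("stiffening requires n_exp > 1")
        if self.kind == "softening" and not 0 < self.n_exp < 1:
            raise ParameterError("softening requires residual fraction in (0, 1)")

    def stress(self, eps):
        """sigma(eps) for eps >= 0 (monotone increasing, sigma(0) = 0)."""
        eps = np.asarray(eps, dtype=float)
        if self.kind == "linear":
            return self.e0 * eps
        if self.kind == "stiffening":
            return self.e0 * eps * (1.0 + (eps / self.eps_c) ** (self.n_exp - 1.0))
        sig_c = self.e0 * self.eps_c
        return np.where(eps <= self.eps_c, self.e0 * eps,
                        sig_c + self.n_exp * self.e0 * (eps - self.eps_c))

    def strain(self, sigma):
        """Inverse law eps(sigma) for sigma >= 0 (elementwise)."""
        sigma = np.asarray(sigma, dtype=float)
        if self.kind == "linear":
            return sigma / self.e0
        if self.kind == "softening":
            sig_c = self.e0 * self.eps_c
            return np.where(sigma <= sig_c, sigma / self.e0,
                            self.eps_c + (sigma - sig_c) / (self.n_exp * self.e0))
        out = np.empty_like(sigma)
        flat = sigma.ravel()
        res = out.ravel()
        for i, s in enumerate(flat):
            if s == 0.0:
                res[i] = 0.0
                continue
            hi = max(s / self.e0, self.eps_c)
            while self.stress(hi) < s:
                hi *= 2.0
            res[i] = optimize.brentq(lambda e: float(self.stress(e)) - s, 0.0, hi,
                                     xtol=1e-16, rtol=8.9e-16)
        return out


@dataclass(frozen=True)
class DragExperiment:
    """Geometry of the bead-drag experiment (lengths in µm)."""

    bead_radius: float = 1.0
    u0: float = 0.2
    domain_length: float = 21.0
    n_nodes: int = 2001
    spread_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.domain_length <= self.bead_radius:
            raise ParameterError("domain_length must exceed bead_radius")
        if self.u0 < 0:
            raise ParameterError("u0 must be >= 0")
        if self.n_nodes < 3:
            raise ParameterError("n_nodes must be >= 3")


@dataclass(frozen=True)
class RadialDisplacementProfile:
    """Displacement and strain along the drag axis, from bead surface to L."""

    x: np.ndarray
    u: np.ndarray
    strain: np.ndarray
    transmitted_force: float

    def interp(self, x):
        return np.interp(x, self.x, self.u)


def _profile_for_force(f: float, x: np.ndarray, exp: DragExperiment,
                       law: MaterialLaw) -> tuple[np.ndarray, np.ndarray]:
    sigma = f * (exp.bead_radius / x) ** exp.spread_exponent
    eps = law.strain(sigma)
    total = cumulative_simpson(eps, x=x, initial=0.0)
    u = total[-1] - total
    return u, eps


def solve_drag_profile(exp: DragExperiment, law: MaterialLaw) -> RadialDisplacementProfile:
    """Find the transmitted force matching the imposed bead displacement.

    Solves ``u0 = integral of eps(x) from r0 to L`` with
    ``eps(x) = law.strain(F * (r0/x)**p)`` by bracketed root finding on the
    force amplitude ``F`` (the integral is strictly increasing in ``F``
    because the inverse law is monotone), then integrates the strain from
    the far boundary to build ``u(x)`` with ``u(L) = 0``.
    """
    x = np.linspace(exp.bead_radius, exp.domain_length, exp.n_nodes)
    if exp.u0 == 0.0:
        zeros = np.zeros_like(x)
        return RadialDisplacementProfile(x=x, u=zeros, strain=zeros.copy(),
                                         transmitted_force=0.0)

    def mismatch(f: float) -> float:
        _, eps = _profile_for_force(f, x, exp, law)
        return cumulative_simpson(eps, x=x, initial=0.0)[-1] - exp.u0

    f_hi = law.e0 * exp.u0 / (exp.domain_length - exp.bead_radius)
    for _ in range(200):
        if mismatch(f_hi) >= 0.0:
            break
        f_hi *= 2.0
    else:  # pragma: no cover
        raise RuntimeError("could not bracket the transmitted force")
    force = optimize.brentq(mismatch, 0.0, f_hi, xtol=1e-300, rtol=8.9e-16,
                            maxiter=200)
    u, eps = _profile_for_force(force, x, exp, law)
    return RadialDisplacementProfile(x=x, u=u, strain=eps, transmitted_force=force)


def closed_form_linear_profile(exp: DragExperiment) -> RadialDisplacementProfile:
    """Analytic displacement profile for the linear law with p = 2.

    ``u(x) = u0 * (1/x - 1/L) / (1/r0 - 1/L)``: the independent oracle for
    :func:`solve_drag_profile`.
    """
    if exp.spread_exponent != 2.0:
        raise ParameterError("closed form requires spread_exponent = 2")
    r0, length = exp.bead_radius, exp.domain_length
    x = np.linspace(r0, length, exp.n_nodes)
    denom = 1.0 / r0 - 1.0 / length
    u = exp.u0 * (1.0 / x - 1.0 / length) / denom
    eps = exp.u0 / denom / x**2
    force = exp.u0 / denom  # with e0 = 1 and unit reference area
    return RadialDisplacementProfile(x=x, u=u, strain=eps, transmitted_force=force)


@dataclass(frozen=True)
class FrontBackField:
    """Signed strain map along the drag axis, antisymmetric about the bead.

    ``x_signed > 0`` is ahead of the bead (compression, negative strain),
    ``x_signed < 0`` behind it (tension, positive strain).
    """

    x_signed: np.ndarray
    strain_signed: np.ndarray
    u_magnitude: np.ndarray


def front_back_field(profile: RadialDisplacementProfile) -> FrontBackField:
    """Mirror the radial solution into the two-sided signed strain field."""
    x = profile.x
    x_signed = np.concatenate([-x[::-1], x])
    strain_signed = np.concatenate([profile.strain[::-1], -profile.strain])
    u_mag = np.concatenate([profile.u[::-1], profile.u])
    return FrontBackField(x_signed=x_signed, strain_signed=strain_signed,
                          u_magnitude=u_mag)


#: Pinned genotype laws for the tweezer comparison: intact vimentin networks
#: strain-stiffen; vimentin-null cytoplasm accumulates damage and softens.
LAW_PRESETS = {
    "linear": MaterialLaw(kind="linear"),
    "stiffening": MaterialLaw(kind="stiffening", eps_c=0.05, n_exp=2.0),
    "softening": MaterialLaw(kind="softening", eps_c=0.05, n_exp=0.3),
}
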