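"""Axisymmetric contractile disc on an elastic foundation.

A circular micropatterned cell is reduced to a thin plane-stress disc of
five-element material tiled over radius: each material point carries the
active circuit of :mod:`cytomech.core` independently in the two principal
directions (radial and hoop), Poisson coupling neglected.  The disc rests on
an elastic foundation whose stiffness stands in for the substrate modulus;
focal adhesions are modelled as a two-level foundation that stiffens where
the local traction magnitude exceeds a threshold.  A non-contractile,
stiffer nucleus region occupies the centre.

Force balance (thin film, uniform thickness ``h``)::

    d(sigma_rr)/dr + (sigma_rr - sigma_tt)/r = Y(u) * u / h,

with ``u(0) = 0`` and a traction-free edge ``sigma_rr(R) = 0``.  The
contractility field obeys the tension feedback on the local in-plane mean
stress, ``rho = f_m * (sigma_rr + sigma_tt)/2 + f0_rho0``, applied
isotropically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import spsolve

from .core import series_branch_stiffness, parallel_branch_stiffness
from .params import CellParameters, ParameterError


class DiscConvergenceError(RuntimeError):
    """Outer fixed-point loop failed to converge."""


#: Passive, stiffer material standing in for the nucleus: no active stress,
#: no feedback, linear springs in both branches.
NUCLEUS_DEFAULT = CellParameters(
    c_mt=10.0, c_v1=0.0, c_i=10.0, beta=0.0, sigma_sat=1.0, c_v2=0.0,
    f_m=0.0, f0_rho0=0.0, g_gef=0.0, region_label="nucleus",
)


@dataclass(frozen=True)
class DiscModel:
    """Geometry and material layout of the contractile disc."""

    radius: float = 20.0
    nucleus_radius: float = 5.0
    thickness: float = 1.0
    n_nodes: int = 201
    foundation_stiffness: float = 1.0
    fa_threshold: float = 0.1
    fa_stiff_factor: float = 1.5
    cyto_params: CellParameters = field(default_factory=CellParameters)
    nuc_params: CellParameters = field(default_factory=lambda: NUCLEUS_DEFAULT)

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_radius < self.radius:
            raise ParameterError("need 0 < nucleus_radius < radius")
        if self.n_nodes < 50:
            raise ParameterError("n_nodes must be >= 50")
        if self.foundation_stiffness <= 0:
            raise ParameterError("foundation_stiffness must be > 0")
        if self.fa_stiff_factor < 1:
            raise ParameterError("fa_stiff_factor must be >= 1")
        if self.thickness <= 0:
            raise ParameterError("thickness must be > 0")
        if self.nuc_params.f0_rho0 != 0.0:
            raise ParameterError("nucleus region must be non-contractile (f0_rho0 = 0)")


@dataclass(frozen=True)
class RadialFields:
    """Converged radial fields of the disc solution."""

    r: np.ndarray
    u: np.ndarray
    sigma_rr: np.ndarray
    sigma_tt: np.ndarray
    sigma_c: np.ndarray
    sigma_t: np.ndarray
    rho: np.ndarray
    residual: float
    iterations: int = 0


def disc_preset(substrate: str = "stiff", **overrides) -> DiscModel:
    """Pinned soft/stiff micropattern presets (foundation stiffness proxies)."""
    levels = {"stiff": 1.0, "soft": 0.002}
    if substrate not in levels:
        raise ParameterError(f"substrate must be one of {sorted(levels)}")
    kwargs = dict(foundation_stiffness=levels[substrate])
    kwargs.update(overrides)
    return DiscModel(**kwargs)


def rve_constitutive(eps_principal, rho: float, params: CellParameters,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stress response of one five-element material point.

    For each principal direction ``d`` the total strain splits over the two
    branches in series, ``eps_d = eps_p_d + eps_s_d``, with a common branch
    stress ``sigma_d = rho + C_p * eps_p_d = C_s(sigma_d) * eps_s_d``.

    Returns ``(sigma, sigma_c, sigma_t)``: the total stress per direction,
    the compressive-branch stress magnitude (``|C_p * eps_p_d|`` where the
    parallel branch is compressed, else 0), and the tensile-branch stress
    (``max(sigma_d, 0)``).
    """
    eps = np.atleast_1d(np.asarray(eps_principal, dtype=float))
    c_p = parallel_branch_stiffness(params)
    sigma = np.empty_like(eps)
    for i, e in enumerate(eps):
        sigma[i] = _solve_direction(e, rho, c_p, params)
    if c_p > 0:
        eps_p = (sigma - rho) / c_p
    else:
        cs = np.array([series_branch_stiffness(s, params) for s in sigma])
        eps_p = eps - np.divide(sigma, cs, out=np.zeros_like(sigma), where=cs > 0)
    sigma_c = np.where(eps_p < 0, c_p * (-eps_p), 0.0)
    sigma_t = np.maximum(sigma, 0.0)
    return sigma, sigma_c, sigma_t


def _solve_direction(eps_d: float, rho: float, c_p: float, params: CellParameters) -> float:
    """Root of (sigma - rho)/C_p + sigma/C_s(sigma) = eps_d (monotone in sigma)."""
    if c_p == 0.0:
        # parallel branch carries exactly the active stress
        return rho

    def f(s: float) -> float:
        c_s = series_branch_stiffness(s, params)
        if c_s == 0.0:
            return (s - rho) / c_p - eps_d
        return (s - rho) / c_p + s / c_s - eps_d

    lo, hi = -1.0, 1.0
    scale = max(abs(rho), abs(eps_d) * c_p, 1.0)
    lo, hi = -scale, scale
    for _ in range(200):
        if f(lo) <= 0.0 <= f(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:  # pragma: no cover
        raise RuntimeError("could not bracket the per-node stress")
    if f(lo) == 0.0:
        return lo
    return optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)


def _region_masks(model: DiscModel, r: np.ndarray) -> np.ndarray:
    return r < model.nucleus_radius


#: Relative half-width of the linear ramp regularizing the two-level
#: focal-adhesion law around its traction threshold (keeps the outer
#: fixed-point iteration from limit-cycling on nodes at the threshold).
FA_RAMP_WIDTH = 0.05


def _foundation_stiffness(u: np.ndarray, model: DiscModel) -> np.ndarray:
    """Two-level focal-adhesion foundation with a narrow transition ramp.

    Adhesions are soft below the traction threshold and stiffer (by
    ``fa_stiff_factor``) above it; the switch is linearly ramped over
    ``+- FA_RAMP_WIDTH`` of the threshold for numerical determinism.
    """
    kf = model.foundation_stiffness
    traction = kf * np.abs(u)
    lo = model.fa_threshold * (1.0 - FA_RAMP_WIDTH)
    hi = model.fa_threshold * (1.0 + FA_RAMP_WIDTH)
    t = np.clip((traction - lo) / (hi - lo), 0.0, 1.0)
    return kf * (1.0 + (model.fa_stiff_factor - 1.0) * t)


def _strains(u: np.ndarray, r: np.ndarray, dr: float) -> tuple[np.ndarray, np.ndarray]:
    eps_rr = np.gradient(u, dr, edge_order=2)
    eps_tt = np.empty_like(u)
    eps_tt[1:] = u[1:] / r[1:]
    eps_tt[0] = eps_rr[0]  # limit u/r -> u'(0)
    return eps_rr, eps_tt


def solve_disc(model: DiscModel, tol: float = 1e-9, max_outer: int = 400,
               relax: float = 0.7) -> RadialFields:
    """Solve the disc by secant-stiffness fixed-point iteration.

    Each outer pass freezes the secant moduli ``K_d = C_p C_s / (C_p + C_s)``
    and active prestress ``P_d = rho C_s / (C_p + C_s)`` per node and
    direction (with ``C_s`` evaluated at the previous stress), solves the
    resulting linear finite-difference system for ``u``, recovers the exact
    per-node stresses from :func:`rve_constitutive`, and updates the
    contractility and foundation level.  Starts from the uniform isotropic
    stress-free state.
    """
    n = model.n_nodes
    r = np.linspace(0.0, model.radius, n)
    dr = r[1] - r[0]
    nuc = _region_masks(model, r)
    h = model.thickness

    f_m = np.where(nuc, model.nuc_params.f_m, model.cyto_params.f_m)
    f0 = np.where(nuc, 0.0, model.cyto_params.f0_rho0)
    c_p = np.where(nuc, parallel_branch_stiffness(model.nuc_params),
                   parallel_branch_stiffness(model.cyto_params))

    def c_s_at(sig: np.ndarray) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            p = model.nuc_params if nuc[i] else model.cyto_params
            out[i] = series_branch_stiffness(sig[i], p)
        return out

    u = np.zeros(n)
    sig_rr = np.zeros(n)
    sig_tt = np.zeros(n)
    rho = f0.copy()
    stress_scale = max(model.cyto_params.f0_rho0, 1e-30)

    if model.cyto_params.f0_rho0 == 0.0:
        # nothing contracts: trivial stress-free state
        zeros = np.zeros(n)
        return RadialFields(r=r, u=zeros, sigma_rr=zeros.copy(), sigma_tt=zeros.copy(),
                            sigma_c=zeros.copy(), sigma_t=zeros.copy(), rho=rho,
                            residual=0.0, iterations=0)

    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        cs_r = c_s_at(sig_rr)
        cs_t = c_s_at(sig_tt)
        k_r = np.where(c_p + cs_r > 0, c_p * cs_r / (c_p + cs_r), 0.0)
        k_t = np.where(c_p + cs_t > 0, c_p * cs_t / (c_p + cs_t), 0.0)
        # c_p = 0 nodes transmit rho directly; c_s = 0 nodes transmit nothing
        p_r = np.where(c_p + cs_r > 0, rho * cs_r / (c_p + cs_r), rho)
        p_t = np.where(c_p + cs_t > 0, rho * cs_t / (c_p + cs_t), rho)
        y = _foundation_stiffness(u, model)

        u_new = _solve_linear_disc(r, dr, k_r, k_t, p_r, p_t, y / h)
        u = relax * u_new + (1.0 - relax) * u

        eps_rr, eps_tt = _strains(u, r, dr)
        new_rr = np.empty(n)
        new_tt = np.empty(n)
        for i in range(n):
            p = model.nuc_params if nuc[i] else model.cyto_params
            s, _, _ = rve_constitutive([eps_rr[i], eps_tt[i]], rho[i], p)
            new_rr[i], new_tt[i] = s
        d_sig = max(np.max(np.abs(new_rr - sig_rr)), np.max(np.abs(new_tt - sig_tt)))
        sig_rr, sig_tt = new_rr, new_tt
        rho_new = f_m * 0.5 * (sig_rr + sig_tt) + f0
        d_rho = np.max(np.abs(rho_new - rho))
        rho = rho_new
        if max(d_sig, d_rho) < tol * stress_scale:
            converged = True
            break
    if not converged:
        raise DiscConvergenceError(
            f"outer loop not converged after {max_outer} iterations "
            f"(last change {max(d_sig, d_rho):.3e})"
        )

    # exact branch stresses and the nonlinear FD residual at convergence
    eps_rr, eps_tt = _strains(u, r, dr)
    sigma_c = np.empty(n)
    sigma_t = np.empty(n)
    for i in range(n):
        p = model.nuc_params if nuc[i] else model.cyto_params
        _, sc, st = rve_constitutive([eps_rr[i], eps_tt[i]], rho[i], p)
        sigma_c[i] = sc.max()
        sigma_t[i] = st.max()
    y = _foundation_stiffness(u, model)
    cs_r = c_s_at(sig_rr)
    cs_t = c_s_at(sig_tt)
    k_r = np.where(c_p + cs_r > 0, c_p * cs_r / (c_p + cs_r), 0.0)
    k_t = np.where(c_p + cs_t > 0, c_p * cs_t / (c_p + cs_t), 0.0)
    p_r = np.where(c_p + cs_r > 0, rho * cs_r / (c_p + cs_r), rho)
    p_t = np.where(c_p + cs_t > 0, rho * cs_t / (c_p + cs_t), rho)
    A, b = _assemble_linear_disc(r, dr, k_r, k_t, p_r, p_t, y / h)
    alg = np.abs(A @ u - b)
    # interior rows are in stress/length units; scale by dr to report a
    # stress-valued residual comparable with the peak stress
    residual = float(max(np.max(alg[1:-1]) * dr, alg[-1]))
    return RadialFields(r=r, u=u, sigma_rr=sig_rr, sigma_tt=sig_tt,
                        sigma_c=sigma_c, sigma_t=sigma_t, rho=rho,
                        residual=residual, iterations=it)


def _solve_linear_disc(r, dr, k_r, k_t, p_r, p_t, y_over_h) -> np.ndarray:
    """One linear solve of the frozen-coefficient thin-film balance."""
    A, b = _assemble_linear_disc(r, dr, k_r, k_t, p_r, p_t, y_over_h)
    return spsolve(A, b)


def _assemble_linear_disc(r, dr, k_r, k_t, p_r, p_t, y_over_h):
    """Assemble the finite-difference system for the frozen-coefficient balance.

    Discretizes ``d/dr(K_r u' + P_r) + (K_r u' + P_r - K_t u/r - P_t)/r
    = (Y/h) u`` with central differences, ``u(0) = 0`` and the traction-free
    edge ``K_r u'(R) + P_r(R) = 0`` (second-order one-sided stencil).
    """
    n = len(r)
    A = sparse.lil_matrix((n, n))
    b = np.zeros(n)

    A[0, 0] = 1.0  # u(0) = 0
    for i in range(1, n - 1):
        km = 0.5 * (k_r[i - 1] + k_r[i])
        kp = 0.5 * (k_r[i] + k_r[i + 1])
        ri = r[i]
        A[i, i - 1] = km / dr**2 - k_r[i] / (2 * dr * ri)
        A[i, i] = -(km + kp) / dr**2 - k_t[i] / ri**2 - y_over_h[i]
        A[i, i + 1] = kp / dr**2 + k_r[i] / (2 * dr * ri)
        b[i] = -(p_r[i + 1] - p_r[i - 1]) / (2 * dr) - (p_r[i] - p_t[i]) / ri
    # free edge: K_r u'(R) = -P_r(R)
    A[n - 1, n - 1] = 3.0 * k_r[n - 1] / (2 * dr)
    A[n - 1, n - 2] = -4.0 * k_r[n - 1] / (2 * dr)
    A[n - 1, n - 3] = 1.0 * k_r[n - 1] / (2 * dr)
    b[n - 1] = -p_r[n - 1]
    return A.tocsr(), b


def principal_extrema(fields: RadialFields, nucleus_radius: float | None = None,
                      ) -> dict[str, float]:
    """Summarise the tension/compression maps into two scalar readouts.

    Returns the mean compressive-branch stress just outside the nucleus
    (nodes with ``nucleus_radius <= r <= 1.2 * nucleus_radius``) and the
    mean tensile-branch stress over the outermost 10% of the radius.
    """
    r = fields.r
    if nucleus_radius is None:
        # first node where contractility is nonzero marks the nucleus edge
        active = np.nonzero(fields.rho > 0)[0]
        nucleus_radius = r[active[0]] if active.size else 0.0
    juxta = (r >= nucleus_radius) & (r <= 1.2 * nucleus_radius)
    peri = r >= 0.9 * r[-1]
    return {
        "sigma_c_juxtanuclear": float(fields.sigma_c[juxta].mean()) if juxta.any() else 0.0,
        "sigma_t_periphery": float(fields.sigma_t[peri].mean()),
    }
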