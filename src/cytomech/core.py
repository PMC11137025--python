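"""Steady state of the one-dimensional five-element cell circuit.

Force balance and compatibility
-------------------------------
With tension positive, the active element generates contractility ``rho``
(a stress), the parallel compression branch of stiffness ``C_p = c_mt + c_v1``
carries strain ``eps_p <= 0``, and the series tension branch of
stress-dependent stiffness ``C_s(sigma)`` transmits the cell-generated
stress ``sigma`` to the matrix spring ``k_m``:

* balance:        ``rho = -C_p * eps_p + sigma``
* activity:       ``rho = f_m * sigma + f0_rho0`` (tension-contractility feedback)
* constitutive:   ``sigma = C_s(sigma) * eps_s = k_m * eps_m``
* compatibility:  ``-eps_p = eps_s + eps_m`` (fixed far boundary)

Eliminating strains gives a single scalar residual in sigma,

    g(sigma) = sigma * (1 + C_p * (1/C_s(sigma) + 1/k_m) - f_m) - f0_rho0,

which has exactly one root in ``(0, f0_rho0 / (1 - f_m)]`` whenever
``f_m < 1``:  g(0) = -f0_rho0 < 0 and g is strictly increasing because
``sigma / C_s(sigma)`` is increasing for the saturating stiffening law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import CellParameters, MatrixModel, ParameterError


class ConvergenceError(RuntimeError):
    """Root-finder failed to meet the residual tolerance."""


class StabilityError(ValueError):
    """Unbounded positive feedback: f_m >= 1."""


def actin_stiffness(sigma: float, params: CellParameters) -> float:
    """Tangent stiffness of the actin element at tensile stress ``sigma``.

    The actin network stiffens with tension (stress-fibre formation) but not
    in compression:  ``C_A = c_i + beta * s / (1 + s / sigma_sat)`` with
    ``s = max(sigma, 0)``.  The stiffening part vanishes at zero tension and
    saturates at ``beta * sigma_sat``.
    """
    s = max(float(sigma), 0.0)
    return params.c_i + params.beta * s / (1.0 + s / params.sigma_sat)


def series_branch_stiffness(sigma: float, params: CellParameters) -> float:
    """Stiffness of the tension branch: actin in parallel with vimentin-2."""
    return actin_stiffness(sigma, params) + params.c_v2


def parallel_branch_stiffness(params: CellParameters) -> float:
    """Stiffness of the compression branch: microtubules in parallel with vimentin-1."""
    return params.c_mt + params.c_v1


@dataclass(frozen=True)
class SteadyState:
    """Converged solution of the 1D circuit.

    Attributes
    ----------
    rho:
        Contractility (active stress) at steady state.
    sigma:
        Cell-generated tensile stress transmitted through the series branch
        to the matrix (the traction proxy).
    eps_p, eps_s, eps_m:
        Strains of the parallel branch (<= 0), series branch (>= 0) and
        matrix spring (>= 0); compatibility gives ``-eps_p = eps_s + eps_m``.
    c_a_eff:
        Effective actin stiffness ``C_A(sigma)`` at the converged stress.
    residual:
        Absolute value of the scalar balance residual g(sigma).
    iterations:
        Function evaluations used by the root finder (0 for closed forms).
    """

    rho: float
    sigma: float
    eps_p: float
    eps_s: float
    eps_m: float
    c_a_eff: float
    residual: float
    iterations: int = 0


def _balance_residual(sigma: float, params: CellParameters, k_m: float) -> float:
    c_p = parallel_branch_stiffness(params)
    c_s = series_branch_stiffness(sigma, params)
    if c_s == 0.0:
        # zero-stiffness tension branch: no transmission at positive stress
        return np.inf if sigma > 0 else -params.f0_rho0
    return sigma * (1.0 + c_p * (1.0 / c_s + 1.0 / k_m) - params.f_m) - params.f0_rho0


def _assemble_state(sigma: float, params: CellParameters, k_m: float,
                    iterations: int = 0) -> SteadyState:
    c_s = series_branch_stiffness(sigma, params)
    eps_s = sigma / c_s if c_s > 0 else 0.0
    eps_m = sigma / k_m
    eps_p = -(eps_s + eps_m)
    rho = params.f_m * sigma + params.f0_rho0
    resid = abs(rho - (-parallel_branch_stiffness(params) * eps_p + sigma))
    return SteadyState(rho=rho, sigma=sigma, eps_p=eps_p, eps_s=eps_s,
                       eps_m=eps_m, c_a_eff=actin_stiffness(sigma, params),
                       residual=resid, iterations=iterations)


def solve_steady_state(params: CellParameters, matrix: MatrixModel,
                       tol: float = 1e-10, max_iter: int = 200) -> SteadyState:
    """Solve the self-consistent steady state of the circuit.

    Finds the unique root of the balance residual on the bracket
    ``(0, f0_rho0 / (1 - f_m)]`` with a safeguarded bracketing method and
    verifies ``|g(sigma)| <= tol``.  The degenerate case of a tension branch
    with zero stiffness at every admissible stress is returned as
    ``sigma = 0`` (total loss of force transmission).
    """
    if params.f_m >= 1.0:
        raise StabilityError("unbounded positive feedback: f_m must be < 1")
    k_m = matrix.k_m
    if params.f0_rho0 == 0.0:
        return _assemble_state(0.0, params, k_m)
    sigma_hi = params.f0_rho0 / (1.0 - params.f_m)
    if series_branch_stiffness(sigma_hi, params) == 0.0:
        # c_i = c_v2 = beta = 0: nothing can carry tension
        return _assemble_state(0.0, params, k_m)

    # g(0) = -f0_rho0 < 0 (the singular 1/C_s term is suppressed at zero
    # stress) and g(sigma_hi) >= 0, so [0, sigma_hi] always brackets the root.
    g_hi = _balance_residual(sigma_hi, params, k_m)
    if g_hi < 0.0:  # pragma: no cover - excluded analytically for f_m < 1
        raise ConvergenceError(f"no sign change on bracket; g(hi) = {g_hi}")

    evals = [0]

    def g(sigma: float) -> float:
        evals[0] += 1
        return _balance_residual(sigma, params, k_m)

    try:
        sigma = optimize.brentq(g, 0.0, sigma_hi, xtol=1e-15, rtol=8.9e-16,
                                maxiter=max_iter)
    except RuntimeError as exc:  # pragma: no cover
        raise ConvergenceError(
            f"steady-state solve did not converge in {max_iter} iterations: {exc}"
        ) from exc
    resid = abs(_balance_residual(sigma, params, k_m))
    if resid > tol:  # pragma: no cover
        raise ConvergenceError(
            f"residual {resid:.3e} exceeds tolerance {tol:.3e} after solve"
        )
    return _assemble_state(sigma, params, k_m, iterations=evals[0])


def closed_form_linear(params: CellParameters, matrix: MatrixModel) -> SteadyState:
    """Analytic steady state for the linear circuit (``beta = 0``).

    With a stress-independent series stiffness the balance is affine in
    sigma and ``sigma = f0_rho0 / (1 + C_p (1/C_s + 1/k_m) - f_m)``.
    Serves as the independent oracle for :func:`solve_steady_state`.
    """
    if params.beta != 0.0:
        raise ParameterError("closed_form_linear requires beta = 0")
    if params.f_m >= 1.0:
        raise StabilityError("unbounded positive feedback: f_m must be < 1")
    c_p = parallel_branch_stiffness(params)
    c_s = params.c_i + params.c_v2
    if c_s == 0.0 or params.f0_rho0 == 0.0:
        return _assemble_state(0.0, params, matrix.k_m)
    denom = 1.0 + c_p * (1.0 / c_s + 1.0 / matrix.k_m) - params.f_m
    sigma = params.f0_rho0 / denom
    return _assemble_state(sigma, params, matrix.k_m)
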