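"""Matrix-stiffness sweeps, genotype comparisons and crossover detection.

The central prediction of the model is that deleting both vimentin elements
(vimentin-null genotype) *lowers* the transmitted stress on soft matrices,
where the force-transmitting vimentin element dominates, but *raises* it on
stiff matrices, where the microtubule-reinforcing element dominates.  The
two regimes are separated by a crossover matrix stiffness ``k_star``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SteadyState, solve_steady_state
from .params import CellParameters, MatrixModel, ParameterError, Perturbation, apply_perturbation

#: Default log grid of matrix spring stiffnesses for genotype comparisons.
#: Spans soft hydrogels to effectively rigid glass in model units.
DEFAULT_KM_GRID = np.logspace(-1.0, 3.0, 57)


class NoCrossoverError(RuntimeError):
    """The genotype stress difference does not change sign on the grid."""

    def __init__(self, message: str, delta_low: float, delta_high: float):
        super().__init__(message)
        self.delta_low = delta_low
        self.delta_high = delta_high


@dataclass(frozen=True)
class SweepResult:
    """Steady states tabulated over a matrix-stiffness grid for one genotype."""

    k_m_grid: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    eps_m: np.ndarray
    genotype_label: str
    states: tuple[SteadyState, ...] = field(repr=False, default=())

    def __post_init__(self):
        if np.any(np.diff(self.k_m_grid) <= 0):
            raise ParameterError("k_m grid must be strictly ascending")
        n = len(self.k_m_grid)
        if not (len(self.sigma) == len(self.rho) == len(self.eps_m) == n):
            raise ParameterError("sweep arrays must share the grid length")


@dataclass(frozen=True)
class CrossoverReport:
    """Location of the sign change of ``delta = sigma_KO - sigma_WT``."""

    k_star: float
    delta_low: float
    delta_high: float
    bracket: tuple[float, float]


def stiffness_sweep(params: CellParameters, k_m_grid, *, tol: float = 1e-10) -> SweepResult:
    """Solve the steady state at every matrix stiffness on an ascending grid."""
    grid = np.asarray(k_m_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ParameterError("k_m grid must be a non-empty 1D array")
    if np.any(grid <= 0):
        raise ParameterError("all k_m must be > 0")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("k_m grid must be strictly ascending")
    states = []
    for k_m in grid:
        try:
            states.append(solve_steady_state(params, MatrixModel(k_m=k_m), tol=tol))
        except Exception as exc:
            raise RuntimeError(f"steady-state solve failed at k_m = {k_m}") from exc
    return SweepResult(
        k_m_grid=grid,
        sigma=np.array([s.sigma for s in states]),
        rho=np.array([s.rho for s in states]),
        eps_m=np.array([s.eps_m for s in states]),
        genotype_label=params.region_label or "unnamed",
        states=tuple(states),
    )


def compare_genotypes(params_wt: CellParameters, k_m_grid=None) -> tuple[SweepResult, SweepResult]:
    """Sweep the wild type and its vimentin-null knockout on a shared grid.

    Returns ``(wt, ko)``.  The input must actually carry both vimentin
    elements, otherwise the comparison is vacuous.
    """
    if params_wt.c_v1 <= 0 or params_wt.c_v2 <= 0:
        raise ParameterError(
            "compare_genotypes requires c_v1 > 0 and c_v2 > 0 in the wild type"
        )
    if k_m_grid is None:
        k_m_grid = DEFAULT_KM_GRID
    params_ko = apply_perturbation(params_wt, Perturbation("vimentin_null"))
    wt = stiffness_sweep(params_wt, k_m_grid)
    ko = stiffness_sweep(params_ko, k_m_grid)
    return wt, ko


def find_crossover(wt: SweepResult, ko: SweepResult, *,
                   params_wt: CellParameters | None = None,
                   refine_tol: float = 1e-6) -> CrossoverReport:
    """Locate the matrix stiffness where the genotype ordering flips.

    Scans ``delta(k_m) = sigma_KO - sigma_WT`` for a sign change on the grid
    and, when ``params_wt`` is supplied, refines the bracket by bisection on
    fresh steady-state solves to a relative width of ``refine_tol``.  Ties
    are broken toward the lower stiffness.
    """
    if wt.k_m_grid.shape != ko.k_m_grid.shape or np.any(wt.k_m_grid != ko.k_m_grid):
        raise ParameterError("genotype sweeps must share the k_m grid")
    delta = ko.sigma - wt.sigma
    delta_low, delta_high = float(delta[0]), float(delta[-1])
    signs = np.sign(delta)
    nonzero = signs != 0
    changes = np.nonzero(np.diff(signs[nonzero]) != 0)[0]
    if changes.size == 0:
        raise NoCrossoverError("no crossover in range: genotype stress difference "
                               "keeps one sign on the grid", delta_low, delta_high)
    idx_nz = np.nonzero(nonzero)[0]
    i_lo = idx_nz[changes[0]]
    i_hi = idx_nz[changes[0] + 1]
    k_lo, k_hi = float(wt.k_m_grid[i_lo]), float(wt.k_m_grid[i_hi])

    if params_wt is None:
        # grid-resolution estimate: log-linear interpolation of the zero
        d_lo, d_hi = delta[i_lo], delta[i_hi]
        t = d_lo / (d_lo - d_hi)
        k_star = float(np.exp(np.log(k_lo) + t * (np.log(k_hi) - np.log(k_lo))))
        return CrossoverReport(k_star=k_star, delta_low=delta_low,
                               delta_high=delta_high, bracket=(k_lo, k_hi))

    params_ko = apply_perturbation(params_wt, Perturbation("vimentin_null"))

    def delta_at(k_m: float) -> float:
        mat = MatrixModel(k_m=k_m)
        return (solve_steady_state(params_ko, mat).sigma
                - solve_steady_state(params_wt, mat).sigma)

    d_lo = delta_at(k_lo)
    a, b = k_lo, k_hi
    while (b - a) / a > refine_tol:
        mid = float(np.sqrt(a * b))
        d_mid = delta_at(mid)
        if d_mid == 0.0 or np.sign(d_mid) == np.sign(d_lo):
            a, d_lo = mid, d_mid
            if d_mid == 0.0:
                b = mid
                break
        else:
            b = mid
    return CrossoverReport(k_star=a, delta_low=delta_low, delta_high=delta_high,
                           bracket=(k_lo, k_hi))
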