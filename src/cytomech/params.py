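"""Parameter containers for the five-element chemo-mechanical cell circuit.

The cell is modelled as an active (myosin) element with a compression-bearing
branch in parallel (microtubules plus one vimentin element) connected in
series with a tension-bearing branch (actin plus a second vimentin element)
and a linear matrix spring.  All stiffnesses and stresses are expressed in
consistent model units; the matrix spring stiffness plays the role of the
substrate elastic modulus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class CellParameters:
    """Stiffnesses and activity constants of one cell circuit.

    Parameters
    ----------
    c_mt:
        Microtubule element stiffness (compression branch).
    c_v1:
        Vimentin element in parallel with the microtubules (compression
        branch, "microtubule-reinforcing" vimentin).
    c_i:
        Initial (low-tension) stiffness of the actin element.
    beta:
        Gain of the tension-driven actin stiffening law (dimensionless
        slope of the stiffening stiffness versus tensile stress).
    sigma_sat:
        Tensile-stress scale at which actin stiffening saturates; the
        stiffening contribution is bounded by ``beta * sigma_sat``.
    c_v2:
        Vimentin element in parallel with actin (tension branch,
        "force-transmitting" vimentin).
    f_m:
        Mechanosensing feedback gain coupling contractility to cytoskeletal
        tension (Rho-ROCK / Ca2+ signalling, coarse grained).  Must satisfy
        ``0 <= f_m < 1`` for a bounded steady state.
    f0_rho0:
        Basal active stress: the product of the zero-tension motor activity
        and the basal contractility, lumped into one stress-valued constant.
    g_gef:
        GEF-H1 coupling gain: fractional boost of basal contractility per
        unit depolymerised microtubule fraction.
    region_label:
        Free-text label (genotype, region, preset name).
    """

    c_mt: float = 3.5
    c_v1: float = 0.5
    c_i: float = 0.02
    beta: float = 6.0
    sigma_sat: float = 3.0
    c_v2: float = 0.15
    f_m: float = 0.5
    f0_rho0: float = 1.0
    g_gef: float = 0.5
    region_label: str = ""

    def __post_init__(self) -> None:
        for name in ("c_mt", "c_v1", "c_i", "beta", "c_v2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.sigma_sat <= 0:
            raise ParameterError(f"sigma_sat must be > 0, got {self.sigma_sat}")
        if not 0.0 <= self.f_m < 1.0:
            raise ParameterError(
                f"f_m must satisfy 0 <= f_m < 1 (positive-feedback stability "
                f"bound), got {self.f_m}"
            )
        if self.f0_rho0 < 0:
            raise ParameterError(f"f0_rho0 must be >= 0, got {self.f0_rho0}")
        if self.g_gef < 0:
            raise ParameterError(f"g_gef must be >= 0, got {self.g_gef}")

    def replace(self, **changes) -> "CellParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Short deterministic hash of the numeric content (for run metadata)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class MatrixModel:
    """Linear elastic matrix reduced to a single spring.

    ``k_m`` is the spring stiffness in stress units per unit strain; use a
    large sentinel (e.g. 1e9) for the rigid-substrate limit.
    """

    k_m: float = 1.0

    def __post_init__(self) -> None:
        if self.k_m <= 0:
            raise ParameterError(f"k_m must be > 0, got {self.k_m}")


RIGID_KM = 1.0e9

#: Pinned wild-type preset used across the test suite and examples.  The
#: stiffness ratios place the vimentin-null/wild-type traction crossover
#: inside the default sweep grid (model units are not calibrated to kPa).
WT_DEFAULT = CellParameters(region_label="wt_default")

#: Linear preset: no actin stiffening, so the steady state has a closed form.
LINEAR_DEFAULT = CellParameters(beta=0.0, region_label="linear_default")

PRESETS = {
    "wt_default": WT_DEFAULT,
    "linear_default": LINEAR_DEFAULT,
}


@dataclass(frozen=True)
class Perturbation:
    """A cytoskeletal perturbation: drug treatment or genetic knockout.

    ``magnitude`` is the retained fraction of the targeted quantity
    (0 = complete disruption, 1 = untouched) and must lie in [0, 1].
    """

    kind: str
    magnitude: float = 0.0

    KINDS = ("control", "vimentin_null", "mt_depoly", "actin_disrupt", "myosin_inhibit")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ParameterError(
                f"unknown perturbation kind {self.kind!r}; expected one of {self.KINDS}"
            )
        if not 0.0 <= self.magnitude <= 1.0:
            raise ParameterError(
                f"magnitude must be in [0, 1] (retained fraction), got {self.magnitude}"
            )


def apply_perturbation(params: CellParameters, perturbation: Perturbation) -> CellParameters:
    """Return a new parameter set with a perturbation applied.

    * ``vimentin_null`` zeroes both vimentin elements (knockout).
    * ``mt_depoly`` scales the microtubule stiffness by the retained fraction
      and boosts basal contractility by ``1 + g_gef * (1 - magnitude)``,
      modelling GEF-H1 / Rho-ROCK activation upon depolymerisation.
    * ``actin_disrupt`` scales both the initial actin stiffness and the
      stiffening gain.
    * ``myosin_inhibit`` scales the basal active stress.
    * ``control`` is the identity.

    The input object is never modified.
    """
    kind, m = perturbation.kind, perturbation.magnitude
    if kind == "control":
        return params
    if kind == "vimentin_null":
        return params.replace(c_v1=0.0, c_v2=0.0,
                              region_label=_tag(params.region_label, "vim-null"))
    if kind == "mt_depoly":
        boost = 1.0 + params.g_gef * (1.0 - m)
        return params.replace(c_mt=m * params.c_mt, f0_rho0=params.f0_rho0 * boost,
                              region_label=_tag(params.region_label, "mt-depoly"))
    if kind == "actin_disrupt":
        return params.replace(c_i=m * params.c_i, beta=m * params.beta,
                              region_label=_tag(params.region_label, "actin-disrupt"))
    if kind == "myosin_inhibit":
        return params.replace(f0_rho0=m * params.f0_rho0,
                              region_label=_tag(params.region_label, "myosin-inhibit"))
    raise ParameterError(f"unknown perturbation kind {kind!r}")  # pragma: no cover


def _tag(label: str, suffix: str) -> str:
    return f"{label}+{suffix}" if label else suffix
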