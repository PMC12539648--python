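"""Cross-sectional equilibrium of a uniform cylindrical segment.

The segment is reduced to a thin-walled ring at the insult apex.
Equilibrium is imposed in membrane (deviatoric) form: the reaction-free
hoop response sigma_tt - sigma_rr carries the transmural Laplace load
P_tm a/h, where P_tm subtracts a constant perivascular support pressure
(calibrated by ``gnr_equilibrium.init_homeostatic`` so the reported
in-vivo geometry is an exact equilibrium at systole). For reported
stress components the radial datum is the mid-wall average
sigma_rr = -P_tm/2, which also enters the one-third-trace intramural
stress. The axial direction is held at the in-vivo stretch (fixed ends).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy.optimize import brentq

from .config import (P_DIASTOLIC_MMHG, P_SYSTOLIC_MMHG, WallParams,
                     mmhg_to_kpa)
from .constitutive import MixtureComposition, mixture_response


@dataclass(frozen=True)
class LoadState:
    """External load on the segment."""

    pressure_mmhg: float
    axial_stretch: float = 1.0
    flow_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.pressure_mmhg < 0:
            raise ValueError("pressure must be non-negative")
        if self.axial_stretch <= 0:
            raise ValueError("axial stretch must be positive")


@dataclass(frozen=True)
class VesselState:
    """Geometry, mixture deformation, composition and load at one section."""

    a_mm: float
    h_mm: float
    lambda_theta: float
    lambda_z: float
    composition: MixtureComposition
    load: LoadState

    def __post_init__(self) -> None:
        if self.a_mm <= 0 or self.h_mm <= 0:
            raise ValueError("geometry must be positive")
        if self.lambda_theta <= 0 or self.lambda_z <= 0:
            raise ValueError("stretches must be positive")

    @classmethod
    def from_stretch(cls, comp: MixtureComposition, lam_theta: float,
                     lam_z: float, load: LoadState) -> "VesselState":
        a, h = section_geometry(comp.params, lam_theta, lam_z,
                                comp.growth_volume_ratio)
        return cls(a, h, lam_theta, lam_z, comp, load)

    @classmethod
    def baseline(cls, params: WallParams,
                 pressure_mmhg: float = P_SYSTOLIC_MMHG) -> "VesselState":
        return cls.from_stretch(MixtureComposition.baseline(params), 1.0, 1.0,
                                LoadState(pressure_mmhg))


@dataclass(frozen=True)
class HomeostaticTargets:
    """Homeostatic set-points established at the in-vivo systolic state."""

    sigma_o_kPa: float
    tau_wo: float  # wall shear normalized to 1 at baseline radius
    a0_mm: float
    h0_mm: float
    perivascular_kPa: float

    def __post_init__(self) -> None:
        if self.sigma_o_kPa <= 0:
            raise ValueError("homeostatic stress target must be positive")

    def shear_ratio(self, a_mm: float) -> float:
        """tau_w / tau_wo under fixed flow: inverse cube of radius ratio."""
        return (self.a0_mm / a_mm) ** 3


@dataclass(frozen=True)
class MetricSet:
    """The reported geometric/mechanical metrics, evaluated at diastole."""

    W_kPa: float
    c_tttt_MPa: float
    c_zzzz_MPa: float
    distensibility_per_mmhg: float
    inner_diameter_mm: float
    thickness_mm: float
    diameter_ratio_wt: float | None = None

    def as_dict(self) -> dict:
        d = {
            "W_kPa": self.W_kPa,
            "c_tttt_MPa": self.c_tttt_MPa,
            "c_zzzz_MPa": self.c_zzzz_MPa,
            "distensibility_per_mmHg": self.distensibility_per_mmhg,
            "inner_diameter_mm": self.inner_diameter_mm,
            "thickness_mm": self.thickness_mm,
        }
        if self.diameter_ratio_wt is not None:
            d["diameter_ratio_WT"] = self.diameter_ratio_wt
        return d


def section_geometry(params: WallParams, lam_theta: float, lam_z: float,
                     growth_volume_ratio: float = 1.0) -> tuple[float, float]:
    """Inner radius and thickness (mm) from mid-wall stretch and added mass.

    The mid-wall radius convects with the circumferential stretch; wall
    cross-sectional area scales with total referential mass over axial
    stretch (incompressible constituents, constant true density).
    """
    rm0 = params.a0_mm + 0.5 * params.h0_mm
    area0 = 2.0 * math.pi * rm0 * params.h0_mm
    rm = lam_theta * rm0
    h = area0 * growth_volume_ratio / (2.0 * math.pi * rm * lam_z)
    return rm - 0.5 * h, h


def laplace_stress(pressure_mmhg: float, a_mm: float, h_mm: float) -> float:
    """Mean circumferential (Laplace) stress P a / h in kPa."""
    if h_mm <= 0:
        raise ValueError("thickness must be positive")
    return mmhg_to_kpa(pressure_mmhg) * a_mm / h_mm


def equilibrium_residual(comp: MixtureComposition, lam_theta: float,
                         lam_z: float, pressure_mmhg: float,
                         perivascular_kPa: float = 0.0) -> float:
    """Membrane equilibrium defect sigma_tt - sigma_rr - P_tm a/h (kPa).

    The deviatoric (reaction-free) hoop response must carry the Laplace
    load; the radial stress datum enters only the reported stress triple,
    not the equilibrium requirement.
    """
    _, s_t, _, s_r, J = mixture_response(comp, lam_theta, lam_z)
    a, h = section_geometry(comp.params, lam_theta, lam_z, J)
    p_tm = mmhg_to_kpa(pressure_mmhg) - perivascular_kPa
    return (s_t - s_r) - p_tm * (a / h)


def solve_elastic_state(state: VesselState, pressure_mmhg: float,
                        lambda_z: float | None = None,
                        perivascular_kPa: float = 0.0,
                        rtol: float = 1e-11) -> VesselState:
    """Pure elastic equilibrium at a new pressure with composition frozen.

    Root-finds the circumferential stretch such that the mean wall stress
    balances the transmural Laplace load at fixed axial stretch. Raises if
    no bracket is found or the residual fails the tolerance.
    """
    comp = state.composition
    lam_z = state.lambda_z if lambda_z is None else lambda_z
    scale = abs(mmhg_to_kpa(pressure_mmhg)) * comp.params.a0_mm / comp.params.h0_mm

    def res(lt: float) -> float:
        return equilibrium_residual(comp, lt, lam_z, pressure_mmhg,
                                    perivascular_kPa)

    lo = hi = state.lambda_theta
    flo = fhi = res(lo)
    for _ in range(120):
        if flo > 0:
            lo *= 0.985
            flo = res(lo)
        elif fhi < 0:
            hi *= 1.015
            fhi = res(hi)
        else:
            break
    if flo * fhi > 0:
        raise RuntimeError(
            f"no equilibrium bracket in [{lo:.3f}, {hi:.3f}] at "
            f"{pressure_mmhg} mmHg (residuals {flo:.3g}, {fhi:.3g})")
    lt = brentq(res, lo, hi, xtol=1e-14, rtol=8.9e-16)
    if abs(res(lt)) > rtol * max(scale, 1.0):
        raise RuntimeError(f"equilibrium residual {res(lt):.3g} kPa above tolerance")
    return VesselState.from_stretch(comp, lt, lam_z, LoadState(pressure_mmhg))


def compute_metrics(systolic: VesselState, diastolic: VesselState,
                    wild_type_refs: Mapping[str, float] | None = None,
                    pressure_for_stiffness: float = P_DIASTOLIC_MMHG) -> MetricSet:
    """Six reported metrics from paired systolic/diastolic states.

    Energy, stiffness and geometry come from the diastolic state;
    distensibility uses the diameter-based clinical form
    (d_sys - d_dia) / (d_dia * (P_sys - P_dia)) in 1/mmHg.
    """
    from .constitutive import mixture_stored_energy, small_on_large_stiffness

    if systolic.composition is not diastolic.composition and \
            systolic.composition != diastolic.composition:
        raise ValueError("states must share one composition")
    d_sys = 2.0 * systolic.a_mm
    d_dia = 2.0 * diastolic.a_mm
    dp = systolic.load.pressure_mmhg - diastolic.load.pressure_mmhg
    if dp <= 0:
        raise ValueError("systolic pressure must exceed diastolic")
    dist = (d_sys - d_dia) / (d_dia * dp)
    c_t, c_z = small_on_large_stiffness(diastolic, pressure_for_stiffness)
    ratio = None
    if wild_type_refs is not None:
        ratio = d_dia / (2.0 * wild_type_refs["a_dia_mm"]) \
            if "a_dia_mm" in wild_type_refs \
            else d_dia / wild_type_refs["inner_diameter_mm"]
    return MetricSet(
        W_kPa=mixture_stored_energy(diastolic),
        c_tttt_MPa=c_t,
        c_zzzz_MPa=c_z,
        distensibility_per_mmhg=dist,
        inner_diameter_mm=d_dia,
        thickness_mm=diastolic.h_mm,
        diameter_ratio_wt=ratio,
    )
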