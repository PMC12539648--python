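"""Constituent-level hyperelasticity for the elastin/muscle/collagen mixture.

The wall is a constrained mixture of amorphous elastin-dominated matrix
(neo-Hookean), circumferential smooth muscle and four collagen fibre
families (Fung exponential; axial, circumferential and a symmetric
diagonal pair at angle alpha0 from the axial direction). Each constituent
carries its own natural configuration through a deposition (pre-)stretch,
and contributes to the mixture energy through the rule of mixtures
W = sum_a phi^a W^a with current mass-fraction weights.

Orientation convention: angles are measured from the axial direction, so
smooth muscle sits at 90 deg. The mixture reference configuration is the
original in-vivo (systolic) state; stretches (lambda_theta, lambda_z) are
measured relative to it. Fibre natural configurations reset when matrix
turns over: a composition records the mixture stretch at its last
growth-and-remodelling state (``reset_stretch``), and fibre elastic
stretches compose the deposition stretch with the mixture stretch
relative to that state. Elastin is never re-deposited, so its elastic
deformation always composes the full mixture deformation with its
deposition stretch tensor.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

from .config import WallParams, mmhg_to_kpa

if TYPE_CHECKING:  # pragma: no cover
    from .vessel_mechanics import VesselState

#: exponent bound beyond which the Fung form is treated as non-physical
_FUNG_EXP_MAX = 700.0


class NonPhysicalStateError(FloatingPointError):
    """Raised when a constituent is driven into a non-physical regime."""


@dataclass(frozen=True)
class ConstituentParams:
    """Material description of one constituent.

    ``deposition_stretch`` is a diagonal (r, theta, z) triple for elastin
    and a scalar for smooth muscle / collagen.
    """

    kind: str  # elastin | smc | collagen
    ce: float | None = None
    c1: float | None = None
    c2: float | None = None
    deposition_stretch: tuple[float, float, float] | float = 1.0
    orientation_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("elastin", "smc", "collagen"):
            raise ValueError(f"unknown constituent kind {self.kind!r}")
        if self.kind == "elastin":
            gr, gt, gz = self.deposition_stretch  # type: ignore[misc]
            if abs(gr * gt * gz - 1.0) > 1e-9:
                raise ValueError("elastin deposition stretch must be isochoric")
        else:
            if self.c2 is None or self.c2 <= 0:
                raise ValueError("Fung exponent c2 must be positive")
            if float(self.deposition_stretch) <= 1.0:  # type: ignore[arg-type]
                raise ValueError("scalar deposition stretch must exceed 1")
        if not 0.0 <= self.orientation_angle_deg <= 90.0:
            raise ValueError("orientation angle must lie in [0, 90] deg")


def neo_hookean_energy(I1: float, ce: float, *, half: bool = True) -> float:
    """Neo-Hookean energy density (kPa) at first invariant ``I1``.

    With ``half`` (default) returns (ce/2)(I1-3); the alternative ce(I1-3)
    is kept as a documented switch.
    """
    if not math.isfinite(I1):
        raise ValueError("non-finite I1")
    fac = 0.5 if half else 1.0
    return fac * ce * (I1 - 3.0)


def fung_fiber_energy(I4: float, c1: float, c2: float) -> float:
    """Fung exponential fibre energy density (kPa) at squared stretch ``I4``.

    W = c1/(4 c2) (exp(c2 (I4-1)^2) - 1); symmetric in (I4-1).
    """
    if I4 <= 0:
        raise ValueError("I4 must be positive")
    x = I4 - 1.0
    e = c2 * x * x
    if e > _FUNG_EXP_MAX:
        raise NonPhysicalStateError(
            f"fibre energy exponent {e:.3g} exceeds overflow guard (I4={I4:.4g})")
    return c1 / (4.0 * c2) * (math.exp(e) - 1.0)


def _fung_stress(I4: float, c1: float, c2: float) -> float:
    """Uniaxial fibre Cauchy extra stress 2 I4 dW/dI4 (kPa)."""
    x = I4 - 1.0
    e = c2 * x * x
    if e > _FUNG_EXP_MAX:
        raise NonPhysicalStateError(
            f"fibre stress exponent {e:.3g} exceeds overflow guard (I4={I4:.4g})")
    return c1 * I4 * x * math.exp(e)


def _fung_stress_dI4(I4: float, c1: float, c2: float) -> float:
    """d/dI4 of the uniaxial fibre Cauchy stress."""
    x = I4 - 1.0
    e = c2 * x * x
    if e > _FUNG_EXP_MAX:
        raise NonPhysicalStateError(
            f"fibre tangent exponent {e:.3g} exceeds overflow guard (I4={I4:.4g})")
    return c1 * math.exp(e) * (x + I4 + 2.0 * c2 * x * x * I4)


@dataclass(frozen=True)
class MixtureComposition:
    """Referential mass state and (possibly insulted) material parameters.

    ``m_m`` and ``m_c`` are evolved-to-baseline referential mass ratios
    (elastin's is identically 1). ``elastin_loss`` and ``collagen_G_loss``
    are the fractional insult reductions of the elastin modulus and of the
    collagen deposition stretch. ``reset_stretch`` is the mixture stretch
    (theta, z) of the growth-and-remodelling state at which smooth muscle
    and collagen natural configurations were last reset.
    """

    params: WallParams
    m_m: float = 1.0
    m_c: float = 1.0
    elastin_loss: float = 0.0
    collagen_G_loss: float = 0.0
    alpha0_deg: float | None = None
    reset_stretch: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.m_m <= 0 or self.m_c <= 0:
            raise ValueError("mass ratios must be positive")
        if not 0.0 <= self.elastin_loss < 1.0:
            raise ValueError("elastin integrity loss must lie in [0, 1)")
        if not 0.0 <= self.collagen_G_loss < 1.0:
            raise ValueError("collagen deposition-stretch loss must lie in [0, 1)")
        if self.alpha0_deg is None:
            object.__setattr__(self, "alpha0_deg", self.params.alpha0_deg)

    @classmethod
    def baseline(cls, params: WallParams) -> "MixtureComposition":
        return cls(params=params)

    @property
    def growth_volume_ratio(self) -> float:
        """Current-to-baseline wall volume ratio J from added mass.

        Normalized by the printed fraction sum so the baseline weights
        equal the printed mass fractions exactly.
        """
        p = self.params
        return (p.phi_e + p.phi_m * self.m_m + p.phi_c * self.m_c) / p.phi_sum

    def weights(self) -> tuple[float, float, float]:
        """Current mass-fraction weights (elastin, muscle, collagen)."""
        p = self.params
        J = self.growth_volume_ratio
        return p.phi_e / J, p.phi_m * self.m_m / J, p.phi_c * self.m_c / J

    def constituents(self) -> tuple[ConstituentParams, ...]:
        """Constituent parameter set with current effective values."""
        p = self.params
        ce_eff = p.ce_kPa * (1.0 - self.elastin_loss)
        gc_eff = p.Gc * (1.0 - self.collagen_G_loss)
        a0 = float(self.alpha0_deg)  # type: ignore[arg-type]
        return (
            ConstituentParams("elastin", ce=ce_eff,
                              deposition_stretch=(p.G_r_e, p.G_theta_e, p.G_z_e)),
            ConstituentParams("smc", c1=p.c1m_kPa, c2=p.c2m,
                              deposition_stretch=p.Gm, orientation_angle_deg=90.0),
            ConstituentParams("collagen", c1=p.c1c_kPa, c2=p.c2c,
                              deposition_stretch=gc_eff, orientation_angle_deg=90.0),
            ConstituentParams("collagen", c1=p.c1c_kPa, c2=p.c2c,
                              deposition_stretch=gc_eff, orientation_angle_deg=0.0),
            ConstituentParams("collagen", c1=p.c1c_kPa, c2=p.c2c,
                              deposition_stretch=gc_eff, orientation_angle_deg=a0),
        )

    def with_(self, **kw) -> "MixtureComposition":
        return replace(self, **kw)


def _collagen_families(comp: MixtureComposition):
    """(beta, sin^2, cos^2) per collagen family; diagonal pair merged."""
    p = comp.params
    a0 = math.radians(float(comp.alpha0_deg))  # type: ignore[arg-type]
    s2, c2_ = math.sin(a0) ** 2, math.cos(a0) ** 2
    return (
        (p.beta_theta, 1.0, 0.0),
        (p.beta_z, 0.0, 1.0),
        (p.beta_d, s2, c2_),  # +/- pair shares beta_d equally; sin^2 identical
    )


def mixture_response(comp: MixtureComposition, lam_theta: float, lam_z: float):
    """Energy and extra Cauchy stress of the mixture at a given stretch.

    ``lam_theta``/``lam_z`` are mixture stretches relative to the original
    in-vivo reference. Returns
    ``(W, s_theta, s_z, s_r, J)`` with W the stored energy per unit
    current volume (kPa), ``s_*`` the constituent ("extra") Cauchy stress
    components before the incompressibility reaction, and J the growth
    volume ratio.
    """
    if lam_theta <= 0 or lam_z <= 0:
        raise ValueError("stretches must be positive")
    p = comp.params
    lth, lzh = comp.reset_stretch
    fe, fm, fc = comp.weights()
    J = comp.growth_volume_ratio

    lam_r = 1.0 / (lam_theta * lam_z)
    # elastin: full mixture deformation composed with its deposition tensor
    ce_eff = p.ce_kPa * (1.0 - comp.elastin_loss)
    if not p.neo_hookean_half:
        ce_eff *= 2.0
    ler = lam_r * p.G_r_e
    let = lam_theta * p.G_theta_e
    lez = lam_z * p.G_z_e
    ler2, let2, lez2 = ler * ler, let * let, lez * lez
    W = fe * 0.5 * ce_eff * (ler2 + let2 + lez2 - 3.0)
    s_t = fe * ce_eff * let2
    s_z = fe * ce_eff * lez2
    s_r = fe * ce_eff * ler2

    # smooth muscle: circumferential, natural configuration reset at lth
    u = lam_theta / lth
    I4m = (p.Gm * u) ** 2
    W += fm * fung_fiber_energy(I4m, p.c1m_kPa, p.c2m)
    s_t += fm * _fung_stress(I4m, p.c1m_kPa, p.c2m)

    # collagen families
    w_ax = lam_z / lzh
    gc_eff = p.Gc * (1.0 - comp.collagen_G_loss)
    gc2 = gc_eff * gc_eff
    u2, w2 = u * u, w_ax * w_ax
    for beta, s2, c2_ in _collagen_families(comp):
        l2 = u2 * s2 + w2 * c2_
        I4 = gc2 * l2
        W += fc * beta * fung_fiber_energy(I4, p.c1c_kPa, p.c2c)
        sf = _fung_stress(I4, p.c1c_kPa, p.c2c)
        s_t += fc * beta * sf * u2 * s2 / l2
        s_z += fc * beta * sf * w2 * c2_ / l2
    return W, s_t, s_z, s_r, J


def _deviatoric_tangents(comp: MixtureComposition, lam_theta: float,
                         lam_z: float) -> tuple[float, float]:
    """Analytic d(sigma_tt - sigma_rr)/dln(lam_theta) and axial analogue (kPa).

    Derivatives are taken at fixed transverse stretch with the
    incompressibility constraint eliminating the radial stretch, i.e. the
    tangent of the condensed membrane response.
    """
    p = comp.params
    lth, lzh = comp.reset_stretch
    fe, fm, fc = comp.weights()

    lam_r = 1.0 / (lam_theta * lam_z)
    ce_eff = p.ce_kPa * (1.0 - comp.elastin_loss)
    if not p.neo_hookean_half:
        ce_eff *= 2.0
    ler2 = (lam_r * p.G_r_e) ** 2
    let2 = (lam_theta * p.G_theta_e) ** 2
    lez2 = (lam_z * p.G_z_e) ** 2
    c_t = fe * 2.0 * ce_eff * (let2 + ler2)
    c_z = fe * 2.0 * ce_eff * (lez2 + ler2)

    u = lam_theta / lth
    w_ax = lam_z / lzh
    u2, w2 = u * u, w_ax * w_ax
    I4m = (p.Gm * u) ** 2
    c_t += fm * 2.0 * I4m * _fung_stress_dI4(I4m, p.c1m_kPa, p.c2m)

    gc2 = (p.Gc * (1.0 - comp.collagen_G_loss)) ** 2
    for beta, s2, c2_ in _collagen_families(comp):
        l2 = u2 * s2 + w2 * c2_
        I4 = gc2 * l2
        sf = _fung_stress(I4, p.c1c_kPa, p.c2c)
        dsf = _fung_stress_dI4(I4, p.c1c_kPa, p.c2c)
        ut, wt = u2 * s2, w2 * c2_
        c_t += fc * beta * 2.0 * (dsf * gc2 * ut * ut / l2 + sf * ut * wt / (l2 * l2))
        c_z += fc * beta * 2.0 * (dsf * gc2 * wt * wt / l2 + sf * ut * wt / (l2 * l2))
    return c_t, c_z


# ---------------------------------------------------------------------------
# state-facing operations


def mixture_stored_energy(state: "VesselState") -> float:
    """Stored energy per unit current volume (kPa) of a vessel state."""
    W, *_ = mixture_response(state.composition, state.lambda_theta, state.lambda_z)
    return W


def mixture_cauchy_stress(state: "VesselState", pressure_mmhg: float,
                          perivascular_kPa: float = 0.0):
    """Cauchy stress triple (sigma_tt, sigma_zz, sigma_rr) in kPa.

    The incompressibility reaction is fixed by the mid-wall radial
    traction sigma_rr = -P_tm/2, with P_tm the transmural pressure after
    subtracting perivascular support.
    """
    _, s_t, s_z, s_r, _ = mixture_response(
        state.composition, state.lambda_theta, state.lambda_z)
    p_tm = mmhg_to_kpa(pressure_mmhg) - perivascular_kPa
    srr = -0.5 * p_tm
    return s_t - s_r + srr, s_z - s_r + srr, srr


def small_on_large_stiffness(state: "VesselState", pressure_mmhg: float = 0.0):
    """Linearized material stiffness (c_tttt, c_zzzz) in MPa.

    Components of the small-on-large stiffness about the loaded state:
    the sensitivity of the circumferential (axial) Cauchy stress to a
    superposed logarithmic stretch increment at fixed transverse stretch,
    with the incompressibility reaction eliminated. Computed analytically
    from constituent second derivatives of the stored energy; the
    ``pressure_mmhg`` argument documents the evaluation state and does not
    enter the material tangent.
    """
    if state.lambda_theta <= 0 or state.lambda_z <= 0:
        raise ValueError("degenerate state")
    c_t, c_z = _deviatoric_tangents(
        state.composition, state.lambda_theta, state.lambda_z)
    return c_t / 1e3, c_z / 1e3
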