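"""Mechanobiologically equilibrated growth-and-remodelling solver.

At mechanobiological equilibrium matrix production balances removal and
the stress-mediated turnover stimuli vanish, so the hereditary
constrained-mixture integrals collapse to an algebraic system: smooth
muscle and collagen carry exactly their deposition stretches, elastin
carries the full mixture deformation composed with its deposition
tensor, and the unknowns are the evolved mixture stretch and constituent
mass ratios.

Two regimes are solved:

* intact shear sensing (Ktauw/Ksigma > 0): the muscle and collagen
  stimulus conditions are generically independent, forcing the intramural
  and wall-shear deviations to vanish separately; the mass ratios m_m and
  m_c are both unknowns.
* apex of the insult region (Ktauw/Ksigma = 0): only the intramural
  condition (1-delta) sigma = sigma_o remains, and the muscle-to-collagen
  turnover ratio closes the system through m_m = (m_c)^eta.

The insult (and any pressure change) is ramped over a fixed number of
continuation increments; the equilibrium is path-independent, so the
increments serve only to keep the root-finder on the physical branch.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import pandas as pd
from scipy.optimize import brentq, fsolve

from .config import P_DIASTOLIC_MMHG, P_SYSTOLIC_MMHG, WallParams, mmhg_to_kpa
from .constitutive import MixtureComposition, mixture_response
from .insult_model import (REGULATION_SWEEP_CAP, SENSING_SWEEP_CAP,
                           InsultParams, elastic_fibre_insult,
                           normalize_porosity)
from .vessel_mechanics import (HomeostaticTargets, LoadState, MetricSet,
                               VesselState, compute_metrics,
                               equilibrium_residual, section_geometry,
                               solve_elastic_state)

SCENARIOS = ("elastic_only", "sensing_only", "regulation_only", "combined")


@dataclass(frozen=True)
class GnRParams:
    """Growth-and-remodelling gains and couplings.

    Basal production/removal rates m_o^a = rho_o^a k_o^a drop out at
    equilibrium and are not carried. ``omega`` weights the quadratic
    removal stimulus; at equilibrium it only shifts the stimulus balance
    and defaults to zero.
    """

    eta: float = 0.9
    gain_ratio: float = 0.9  # Ktauw / Ksigma
    gamma: float = 0.2
    delta: float = 0.0
    xi: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.gain_ratio < 0 or self.gamma < 0:
            raise ValueError("gain ratio and gamma must be non-negative")
        for name in ("delta", "xi"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")

    @classmethod
    def from_params(cls, params: WallParams) -> "GnRParams":
        return cls(eta=params.eta, gain_ratio=params.Ktauw_over_Ksigma,
                   gamma=params.gamma, delta=params.delta, xi=params.xi,
                   omega=params.omega)

    def at_apex(self) -> "GnRParams":
        """Apex values inside the insult region: eta=1, shear gain off."""
        return replace(self, eta=1.0, gain_ratio=0.0)


def init_homeostatic(params: WallParams,
                     pressure_mmhg: float = P_SYSTOLIC_MMHG
                     ) -> tuple[VesselState, HomeostaticTargets]:
    """Pre-load step: establish the in-vivo state and homeostatic targets.

    The perivascular support pressure is calibrated (unless fixed in the
    parameter file) so that the reported in-vivo geometry is an exact
    thin-ring equilibrium at the systolic pressure; the intramural target
    is one-third of the stress trace there and the shear target is
    normalized to one.
    """
    comp = MixtureComposition.baseline(params)
    _, s_t, s_z, s_r, _ = mixture_response(comp, 1.0, 1.0)
    p_sys = mmhg_to_kpa(pressure_mmhg)
    if params.perivascular_kPa is None:
        pext = p_sys - (s_t - s_r) / (params.a0_mm / params.h0_mm)
    else:
        pext = params.perivascular_kPa
    p_tm = p_sys - pext
    sigma_o = (s_t + s_z - 2.0 * s_r) / 3.0 - 0.5 * p_tm
    state = VesselState.from_stretch(comp, 1.0, 1.0, LoadState(pressure_mmhg))
    targets = HomeostaticTargets(sigma_o_kPa=sigma_o, tau_wo=1.0,
                                 a0_mm=params.a0_mm, h0_mm=params.h0_mm,
                                 perivascular_kPa=pext)
    return state, targets


def _evolved_composition(params: WallParams, lth: float, m_c: float,
                         m_m: float, vce: float, vgc: float,
                         gamma: float) -> MixtureComposition:
    """Composition of the equilibrated state at evolved stretch ``lth``."""
    alpha0 = math.degrees(math.atan(lth ** gamma
                                    * math.tan(math.radians(params.alpha0_deg))))
    return MixtureComposition(params=params, m_m=m_m, m_c=m_c,
                              elastin_loss=vce, collagen_G_loss=vgc,
                              alpha0_deg=alpha0, reset_stretch=(lth, 1.0))


def _solve_mech(params: WallParams, m_c: float, m_m: float, vce: float,
                vgc: float, gamma: float, pressure_mmhg: float,
                pext: float, lth_guess: float) -> float:
    """Inner solve: evolved stretch satisfying mechanical equilibrium."""

    def res(lth: float) -> float:
        comp = _evolved_composition(params, lth, m_c, m_m, vce, vgc, gamma)
        return equilibrium_residual(comp, lth, 1.0, pressure_mmhg, pext)

    # fast path: secant from the warm guess, validated against the guess
    try:
        x0, x1 = lth_guess, lth_guess * 1.001
        f0, f1 = res(x0), res(x1)
        for _ in range(40):
            if f1 == f0:
                break
            x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
            if not (0.05 < x2 < 20.0 * lth_guess):
                break
            x0, f0, x1, f1 = x1, f1, x2, res(x2)
            if abs(f1) < 1e-11 * max(abs(mmhg_to_kpa(pressure_mmhg))
                                     * params.a0_mm / params.h0_mm, 1.0):
                if abs(math.log(x1 / lth_guess)) < 0.5:
                    return x1
                break
    except (FloatingPointError, OverflowError, ValueError):
        pass

    # walk outward from the guess on both sides; bracket the nearest root
    # (the residual may cross zero twice -- continuation from the previous
    # converged stretch keeps us on the physical branch)
    def safe(lth: float) -> float | None:
        try:
            return res(lth)
        except (FloatingPointError, OverflowError, ValueError):
            return None

    f0 = safe(lth_guess)
    if f0 is None:
        raise RuntimeError("mechanical residual not evaluable at the guess "
                           f"(lth={lth_guess:.3g})")
    lo = hi = lth_guess
    flo: float | None = f0
    fhi: float | None = f0
    for _ in range(400):
        if flo is not None:
            nlo = lo * 0.99
            fnlo = safe(nlo)
            if fnlo is not None and flo * fnlo <= 0.0:
                return brentq(res, nlo, lo, xtol=1e-14, rtol=8.9e-16)
            lo, flo = nlo, fnlo
        if fhi is not None:
            nhi = hi * 1.01
            fnhi = safe(nhi)
            if fnhi is not None and fhi * fnhi <= 0.0:
                return brentq(res, hi, nhi, xtol=1e-14, rtol=8.9e-16)
            hi, fhi = nhi, fnhi
        if (flo is None and fhi is None) or lo < 0.05:
            break
    raise RuntimeError("mechanical equilibrium bracket not found "
                       f"(m_c={m_c:.3g}, insults=({vce:.3g},{vgc:.3g}))")


def _stimuli(params: WallParams, comp: MixtureComposition, lth: float,
             pressure_mmhg: float, targets: HomeostaticTargets,
             delta: float, xi: float) -> tuple[float, float]:
    """Normalized intramural and wall-shear stimulus deviations."""
    _, s_t, s_z, s_r, J = mixture_response(comp, lth, 1.0)
    p_tm = mmhg_to_kpa(pressure_mmhg) - targets.perivascular_kPa
    sigma = (s_t + s_z - 2.0 * s_r) / 3.0 - 0.5 * p_tm
    a, _ = section_geometry(params, lth, 1.0, J)
    d_sigma = ((1.0 - delta) * sigma - targets.sigma_o_kPa) / targets.sigma_o_kPa
    d_tau = (1.0 - xi) * targets.shear_ratio(a) / targets.tau_wo - 1.0
    return d_sigma, d_tau


def solve_equilibrated(apex_insults: tuple[float, float, float],
                       gnr: GnRParams, targets: HomeostaticTargets,
                       params: WallParams,
                       pressure_mmhg: float = P_SYSTOLIC_MMHG,
                       n_increments: int = 10,
                       rtol: float = 1e-9,
                       start: tuple[float, float, float] | None = None
                       ) -> VesselState:
    """Evolved, equilibrated state under apex insults at fixed pressure.

    ``apex_insults`` is (theta_ce, theta_delta, theta_gc). The evolved
    state is returned at the solve pressure with the composition's
    natural-configuration reset at the evolved stretch. ``start`` may
    supply a warm-start (lambda_theta, m_c, m_m) from a nearby solution;
    the converged equilibrium does not depend on it.
    """
    vce_t, vdelta_t, vgc_t = apex_insults
    if not (0.0 <= vce_t < 1.0 and 0.0 <= vdelta_t < 1.0 and 0.0 <= vgc_t < 1.0):
        raise ValueError("insult magnitudes must lie in [0, 1)")
    p0 = P_SYSTOLIC_MMHG
    lth, m_c, m_m = (1.0, 1.0, 1.0) if start is None else start
    last_ok = 0
    for k in range(1, n_increments + 1):
        f = k / n_increments
        vce, vdelta, vgc = f * vce_t, f * vdelta_t, f * vgc_t
        pres = p0 + f * (pressure_mmhg - p0)
        delta = gnr.delta + vdelta
        try:
            if gnr.gain_ratio == 0.0:
                # apex: single intramural condition + eta mass coupling
                def stim(log_mc: float) -> float:
                    mc = math.exp(log_mc)
                    mm = mc ** gnr.eta
                    lt = _solve_mech(params, mc, mm, vce, vgc, gnr.gamma,
                                     pres, targets.perivascular_kPa, lth)
                    comp = _evolved_composition(params, lt, mc, mm, vce, vgc,
                                                gnr.gamma)
                    ds, _ = _stimuli(params, comp, lt, pres, targets,
                                     delta, gnr.xi)
                    return ds

                z = math.log(m_c)
                root = None
                # fast path: secant from the warm start
                try:
                    z0, z1 = z, z + 1e-3
                    g0, g1 = stim(z0), stim(z1)
                    for _ in range(40):
                        if g1 == g0:
                            break
                        z2 = z1 - g1 * (z1 - z0) / (g1 - g0)
                        if abs(z2 - z) > 3.0:
                            break
                        z0, g0, z1, g1 = z1, g1, z2, stim(z2)
                        if abs(g1) < 1e-12:
                            root = z1
                            break
                except (RuntimeError, FloatingPointError, OverflowError,
                        ValueError):
                    root = None
                if root is None:
                    zlo = zhi = z
                    flo = fhi = stim(z)
                    for _ in range(200):
                        nlo, nhi = zlo - 0.05, zhi + 0.05
                        fnlo, fnhi = stim(nlo), stim(nhi)
                        if flo * fnlo <= 0.0:
                            root = brentq(stim, nlo, zlo,
                                          xtol=1e-13, rtol=8.9e-16)
                            break
                        if fhi * fnhi <= 0.0:
                            root = brentq(stim, zhi, nhi,
                                          xtol=1e-13, rtol=8.9e-16)
                            break
                        zlo, flo, zhi, fhi = nlo, fnlo, nhi, fnhi
                if root is None:
                    raise RuntimeError("stimulus bracket not found")
                m_c = math.exp(root)
                m_m = m_c ** gnr.eta
            else:
                # intact shear gain: both deviations vanish separately
                def res(y):
                    mc, mm = math.exp(y[0]), math.exp(y[1])
                    lt = _solve_mech(params, mc, mm, vce, vgc, gnr.gamma,
                                     pres, targets.perivascular_kPa, lth)
                    comp = _evolved_composition(params, lt, mc, mm, vce, vgc,
                                                gnr.gamma)
                    return _stimuli(params, comp, lt, pres, targets,
                                    delta, gnr.xi)

                y, info, ier, msg = fsolve(res, [math.log(m_c), math.log(m_m)],
                                           xtol=1e-13, full_output=True)
                if ier != 1:
                    raise RuntimeError(f"stimulus solve failed: {msg}")
                m_c, m_m = math.exp(y[0]), math.exp(y[1])
            lth = _solve_mech(params, m_c, m_m, vce, vgc, gnr.gamma, pres,
                              targets.perivascular_kPa, lth)
            last_ok = k
        except (RuntimeError, FloatingPointError, OverflowError) as exc:
            raise RuntimeError(
                f"equilibrated G&R failed at increment {k}/{n_increments} "
                f"(last converged {last_ok}): {exc}") from exc

    comp = _evolved_composition(params, lth, m_c, m_m, vce_t, vgc_t, gnr.gamma)
    # verify final residuals
    ds, dt = _stimuli(params, comp, lth, pressure_mmhg, targets,
                      gnr.delta + vdelta_t, gnr.xi)
    mech = equilibrium_residual(comp, lth, 1.0, pressure_mmhg,
                                targets.perivascular_kPa)
    stim_res = abs(ds) if gnr.gain_ratio == 0.0 else max(abs(ds), abs(dt))
    if stim_res > rtol * 10 or abs(mech) > rtol * 10 * targets.sigma_o_kPa:
        raise RuntimeError(
            f"equilibrium residuals above tolerance (stimulus {stim_res:.3g}, "
            f"mechanical {mech:.3g} kPa)")
    return VesselState.from_stretch(comp, lth, 1.0, LoadState(pressure_mmhg))


def scenario_insults(porosity: float, A: InsultParams,
                     scenario: str) -> tuple[float, float, float]:
    """Apex insult triple for a named single/combined-contributor scenario.

    Single-contributor sensing/regulation sweeps ramp linearly in
    normalized porosity up to their stated caps.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    eb = normalize_porosity(porosity, A.porosity_lb, A.porosity_ub)
    if scenario == "elastic_only":
        return (elastic_fibre_insult(eb, A.theta_ce_max), 0.0, 0.0)
    if scenario == "sensing_only":
        return (0.0, eb * SENSING_SWEEP_CAP, 0.0)
    if scenario == "regulation_only":
        return (0.0, 0.0, eb * REGULATION_SWEEP_CAP)
    return A.at_porosity(porosity)


def evaluate_state_metrics(evolved: VesselState, targets: HomeostaticTargets,
                           wild_type_refs=None) -> MetricSet:
    """Diastolic metric set for an evolved (or baseline) systolic state."""
    diastolic = solve_elastic_state(evolved, P_DIASTOLIC_MMHG,
                                    perivascular_kPa=targets.perivascular_kPa)
    return compute_metrics(evolved, diastolic, wild_type_refs)


def porosity_sweep(porosities, A: InsultParams, scenario: str, gnr: GnRParams,
                   targets: HomeostaticTargets, params: WallParams,
                   n_increments: int = 10, wild_type_refs=None,
                   on_error: str = "raise") -> pd.DataFrame:
    """Metric table across a porosity grid for one insult scenario.

    Any nonzero insult is applied with the apex G&R parameter switch
    (eta=1, shear gain off); zero insult keeps the intact baseline gains.
    ``on_error='warn'`` drops failing porosities with a warning instead of
    raising.
    """
    rows = []
    for eps in porosities:
        ins = scenario_insults(eps, A, scenario)
        use = gnr.at_apex() if any(v > 0 for v in ins) else gnr
        try:
            evolved = solve_equilibrated(ins, use, targets, params,
                                         n_increments=n_increments)
            metrics = evaluate_state_metrics(evolved, targets, wild_type_refs)
        except RuntimeError as exc:
            if on_error == "warn":
                warnings.warn(f"porosity {eps:.3f}: {exc}")
                continue
            raise RuntimeError(f"porosity {eps:.3f}: {exc}") from exc
        rows.append({"porosity": eps, **metrics.as_dict(),
                     "theta_ce": ins[0], "theta_delta": ins[1],
                     "theta_gc": ins[2]})
    return pd.DataFrame(rows)
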