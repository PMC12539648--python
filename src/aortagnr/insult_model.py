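"""Porosity-to-insult mapping and axial insult profiles.

Elastin porosity (void fraction of the imaged elastic-fibre volume) is
the progression variable. Normalized porosity drives three insults: a
linear loss of elastic-fibre integrity, and saturating-exponential
losses of cellular mechanosensing (delta) and mechanoregulation
(fractional reduction of the collagen deposition stretch), whose
front-loading is set by the progression-rate constant g.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

#: experimental porosity range (pooled over both Marfan mouse groups)
POROSITY_LB = 0.115
POROSITY_UB = 0.699
#: maximal elastic-fibre integrity loss from the fold change in non-void space
ELASTIN_INSULT_MAX = (POROSITY_UB - POROSITY_LB) / (1.0 - POROSITY_LB)
#: single-contributor sweep caps for sensing / regulation scenarios
SENSING_SWEEP_CAP = 0.150
REGULATION_SWEEP_CAP = 0.012


@dataclass(frozen=True)
class InsultParams:
    """Optimizable insult triple plus fixed elastic-fibre ceiling."""

    theta_delta_max: float = 0.0
    theta_gc_max: float = 0.0
    g: float = 1.0
    theta_ce_max: float = ELASTIN_INSULT_MAX
    porosity_lb: float = POROSITY_LB
    porosity_ub: float = POROSITY_UB

    #: optimization box from prior in-silico stability ranges
    BOUNDS = ((0.0, 0.100), (0.0, 0.0150), (0.01, 10.0))

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_ce_max < 1.0:
            raise ValueError("elastic-fibre ceiling must lie in (0, 1)")
        if self.theta_delta_max < 0 or self.theta_gc_max < 0:
            raise ValueError("insult maxima must be non-negative")
        if self.g <= 0:
            raise ValueError("progression rate g must be positive")
        if self.porosity_ub <= self.porosity_lb:
            raise ValueError("porosity bounds must be ordered")

    def as_vector(self) -> tuple[float, float, float]:
        return (self.theta_delta_max, self.theta_gc_max, self.g)

    @classmethod
    def from_vector(cls, vec) -> "InsultParams":
        return cls(theta_delta_max=float(vec[0]), theta_gc_max=float(vec[1]),
                   g=float(vec[2]))

    def at_porosity(self, porosity: float) -> tuple[float, float, float]:
        """Apex insult triple (theta_ce, theta_delta, theta_gc) at a porosity."""
        eb = normalize_porosity(porosity, self.porosity_lb, self.porosity_ub)
        return (
            elastic_fibre_insult(eb, self.theta_ce_max),
            cell_insult(eb, self.g, self.theta_delta_max),
            cell_insult(eb, self.g, self.theta_gc_max),
        )


@dataclass(frozen=True)
class AxialProfileParams:
    """Gaussian-like axial insult profile centred at the segment midpoint."""

    lo_mm: float = 15.0
    zod_mm: float = 3.0
    vz: float = 2.0

    def __post_init__(self) -> None:
        if self.zod_mm <= 0:
            raise ValueError("zod must be positive")
        if self.vz < 1:
            raise ValueError("vz must be >= 1")
        if self.lo_mm <= 2 * self.zod_mm:
            raise ValueError("segment must be longer than twice the insult width")


def normalize_porosity(porosity: float, lb: float = POROSITY_LB,
                       ub: float = POROSITY_UB) -> float:
    """Normalized porosity (porosity - lb)/(ub - lb), clamped to [0, 1]."""
    if not math.isfinite(porosity):
        raise ValueError("porosity must be finite")
    return min(1.0, max(0.0, (porosity - lb) / (ub - lb)))


def elastic_fibre_insult(eps_bar: float,
                         theta_ce_max: float = ELASTIN_INSULT_MAX) -> float:
    """Elastic-fibre integrity loss, linear in normalized porosity."""
    return eps_bar * theta_ce_max


def cell_insult(eps_bar: float, g: float, theta_max: float) -> float:
    """Saturating-exponential cell-function insult.

    theta = theta_max (e^{-g eps_bar} - 1)/(e^{-g} - 1); zero at eps_bar=0,
    theta_max at eps_bar=1, concave increasing for g > 0 and approaching
    the linear ramp as g -> 0+.
    """
    if g <= 0:
        raise ValueError("progression rate g must be positive")
    return theta_max * math.expm1(-g * eps_bar) / math.expm1(-g)


def axial_profile(zo_mm: float, theta_apex: float,
                  profile: AxialProfileParams = AxialProfileParams()) -> float:
    """Insult magnitude at axial position ``zo`` for a given apex value."""
    if not 0.0 <= zo_mm <= profile.lo_mm:
        raise ValueError(f"zo={zo_mm} outside [0, {profile.lo_mm}] mm")
    arg = abs((zo_mm - profile.lo_mm / 2.0) / profile.zod_mm) ** profile.vz
    return theta_apex * math.exp(-arg)
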