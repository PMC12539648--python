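"""Parameter file handling and unit conventions.

Internal units are kPa and mm throughout; pressures cross the public
interfaces in mmHg and are converted here at 1 mmHg = 0.133322 kPa.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import yaml

MMHG_KPA = 0.133322
P_SYSTOLIC_MMHG = 120.0
P_DIASTOLIC_MMHG = 80.0


def mmhg_to_kpa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_KPA


def kpa_to_mmhg(p_kpa: float) -> float:
    return p_kpa / MMHG_KPA


@dataclass(frozen=True)
class WallParams:
    """Baseline wall geometry, composition, material and G&R parameters."""

    a0_mm: float = 0.809
    h0_mm: float = 0.041
    phi_e: float = 0.354
    phi_m: float = 0.345
    phi_c: float = 0.311
    beta_theta: float = 0.012
    beta_z: float = 0.012
    beta_d: float = 0.976
    ce_kPa: float = 42.03
    c1m_kPa: float = 1.26
    c2m: float = 30.0
    c1c_kPa: float = 665.6
    c2c: float = 2.14
    G_theta_e: float = 1.74
    G_z_e: float = 2.24
    Gm: float = 1.19
    Gc: float = 1.25
    alpha0_deg: float = 51.1
    delta: float = 0.0
    xi: float = 0.0
    eta: float = 0.9
    Ktauw_over_Ksigma: float = 0.9
    gamma: float = 0.2
    omega: float = 0.0
    neo_hookean_half: bool = True
    perivascular_kPa: float | None = None

    def __post_init__(self) -> None:
        if self.a0_mm <= 0 or self.h0_mm <= 0:
            raise ValueError("geometry must be positive")
        for name in ("phi_e", "phi_m", "phi_c", "beta_theta", "beta_z", "beta_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        # printed fractions may carry rounding; tolerate a small defect
        if abs(self.phi_e + self.phi_m + self.phi_c - 1.0) > 0.05:
            raise ValueError("constituent mass fractions must sum to ~1")
        if abs(self.beta_theta + self.beta_z + self.beta_d - 1.0) > 0.05:
            raise ValueError("collagen orientation fractions must sum to ~1")
        if self.c2m <= 0 or self.c2c <= 0:
            raise ValueError("Fung exponents must be positive")
        for name in ("G_theta_e", "G_z_e", "Gm", "Gc"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"deposition stretch {name} must exceed 1")
        if not 0.0 <= self.alpha0_deg <= 90.0:
            raise ValueError("alpha0_deg must lie in [0, 90]")
        for name in ("delta", "xi"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.eta <= 0 or self.gamma < 0 or self.Ktauw_over_Ksigma < 0:
            raise ValueError("invalid G&R parameters")

    @property
    def G_r_e(self) -> float:
        """Radial elastin deposition stretch from incompressible deposition."""
        return 1.0 / (self.G_theta_e * self.G_z_e)

    @property
    def phi_sum(self) -> float:
        return self.phi_e + self.phi_m + self.phi_c

    def with_(self, **kw) -> "WallParams":
        return replace(self, **kw)


_SECTION_KEYS = {
    "geometry": ("a0_mm", "h0_mm"),
    "mass_fractions": ("phi_e", "phi_m", "phi_c"),
    "collagen_orientation_fractions": ("beta_theta", "beta_z", "beta_d"),
    "material": ("ce_kPa", "c1m_kPa", "c2m", "c1c_kPa", "c2c"),
    "deposition_stretches": ("G_theta_e", "G_z_e", "Gm", "Gc"),
    "orientation": ("alpha0_deg",),
    "mechanosensing": ("delta", "xi"),
    "growth_remodelling": ("eta", "Ktauw_over_Ksigma", "gamma", "omega"),
    "options": ("neo_hookean_half", "perivascular_kPa"),
}


def load_params(path: str | Path | None = None) -> WallParams:
    """Load wall parameters from a YAML file (packaged defaults if ``None``)."""
    if path is None:
        text = resources.files("aortagnr.data").joinpath(
            "baseline_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    flat: dict = {}
    for section, keys in _SECTION_KEYS.items():
        block = raw.get(section, {})
        for key in keys:
            if key in block:
                flat[key] = block[key]
    # accept already-flat files as well
    for key in {k for keys in _SECTION_KEYS.values() for k in keys}:
        if key in raw:
            flat[key] = raw[key]
    return WallParams(**flat)
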