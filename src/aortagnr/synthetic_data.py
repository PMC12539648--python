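"""Synthetic porosity-metric observation sets.

Emulates the per-specimen structure of the experimental data: two
genotype-like groups whose elastin porosities occupy overlapping low
(C1041G-like) and high (mgR-like) ranges, with the six diastolic metrics
generated by the combined-insult forward model at a known insult triple
and perturbed by multiplicative lognormal noise. Wild-type normalizers
are the zero-insult baseline model metrics.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import WallParams, load_params
from .gnr_equilibrium import (GnRParams, evaluate_state_metrics,
                              init_homeostatic, solve_equilibrated)
from .insult_model import POROSITY_LB, POROSITY_UB, InsultParams

GROUP_RANGES = {
    "C1041G-like": (POROSITY_LB, 0.40),
    "mgR-like": (0.30, POROSITY_UB),
}

METRIC_COLUMNS = ("W_kPa", "c_tttt_MPa", "c_zzzz_MPa",
                  "distensibility_per_mmHg", "inner_diameter_mm",
                  "thickness_mm")

#: default multiplicative noise, biological-replicate scale
DEFAULT_NOISE_CV = 0.08


@dataclass(frozen=True)
class ObservationSet:
    """Per-specimen porosity-metric records with wild-type normalizers."""

    df: pd.DataFrame
    y_wt: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"specimen_id", "group", "porosity", *METRIC_COLUMNS}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"observation table missing columns {sorted(missing)}")
        por = self.df["porosity"]
        if ((por < 0) | (por > 1)).any():
            raise ValueError("porosity must lie in [0, 1]")
        for key in ("c_tttt_MPa", "W_kPa"):
            if self.y_wt.get(key, 0.0) <= 0:
                raise ValueError(f"missing wild-type normalizer for {key}")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        """Write the observation table plus a sidecar JSON of Y_WT/provenance."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = {"y_wt": self.y_wt, "provenance": self.provenance}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
        else:
            raise FileNotFoundError(f"sidecar {sidecar_path} with Y_WT not found")
        return cls(df=df, y_wt=sidecar["y_wt"],
                   provenance=sidecar.get("provenance", {}))


def generate_porosities(n_per_group: int, seed: int) -> pd.DataFrame:
    """Group-labelled porosity draws, uniform within each group's range."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for group, (lo, hi) in GROUP_RANGES.items():
        for eps in rng.uniform(lo, hi, size=n_per_group):
            rows.append({"group": group, "porosity": float(eps)})
    return pd.DataFrame(rows)


def generate_observations(A_true: InsultParams, noise_cv: float,
                          n_per_group: int, seed: int,
                          params: WallParams | None = None,
                          gnr: GnRParams | None = None,
                          n_increments: int = 10) -> ObservationSet:
    """Forward-model observation set at a known insult triple.

    Each metric is multiplied by a mean-one lognormal factor with
    coefficient of variation ``noise_cv``. Records whose forward solve
    fails are dropped with a warning.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    params = params or load_params()
    gnr = (gnr or GnRParams.from_params(params)).at_apex()
    _, targets = init_homeostatic(params)
    base = solve_equilibrated((0.0, 0.0, 0.0),
                              GnRParams.from_params(params), targets, params)
    wt = evaluate_state_metrics(base, targets).as_dict()

    table = generate_porosities(n_per_group, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    sig = float(np.sqrt(np.log1p(noise_cv ** 2)))
    rows = []
    start = None
    for i, rec in table.sort_values("porosity").iterrows():
        eps = float(rec["porosity"])
        try:
            ev = solve_equilibrated(A_true.at_porosity(eps), gnr, targets,
                                    params, n_increments=n_increments,
                                    start=start)
            start = (ev.lambda_theta, ev.composition.m_c, ev.composition.m_m)
            metrics = evaluate_state_metrics(ev, targets).as_dict()
        except RuntimeError as exc:
            warnings.warn(f"dropping porosity {eps:.3f}: {exc}")
            continue
        noisy = {k: metrics[k] * float(np.exp(sig * rng.standard_normal()
                                              - 0.5 * sig * sig))
                 for k in METRIC_COLUMNS}
        rows.append({"specimen_id": f"syn{i:03d}", "group": rec["group"],
                     "porosity": eps, **noisy})
    df = pd.DataFrame(rows).sort_values("specimen_id").reset_index(drop=True)
    provenance = {
        "A_true": dict(zip(("theta_delta_max", "theta_gc_max", "g"),
                           A_true.as_vector())),
        "theta_ce_max": A_true.theta_ce_max,
        "noise_cv": noise_cv,
        "seed": seed,
        "n_per_group": n_per_group,
        "dropped": 2 * n_per_group - len(rows),
    }
    y_wt = {k: wt[k] for k in METRIC_COLUMNS}
    return ObservationSet(df=df, y_wt=y_wt, provenance=provenance)
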