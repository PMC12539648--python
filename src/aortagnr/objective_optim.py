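"""Objective function and surrogate-management-framework optimizer.

The fit compares model-predicted diastolic circumferential stiffness and
stored energy against per-specimen observations over the experimental
porosity range, through wild-type-normalized mean squared errors
J_Y = (1/n) sum ((Y - Y_h)/Y_WT)^2 averaged over the two metrics,
Phi = (J_c + J_W)/2.

Minimization uses a surrogate management framework: a Latin-hypercube
initial design, a kriging (Gaussian-process) surrogate whose minimizer
drives SEARCH steps, and a positive-spanning coordinate POLL stencil
with mesh halving that guarantees convergence when the surrogate stops
helping.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .gnr_equilibrium import GnRParams, solve_equilibrated, evaluate_state_metrics
from .insult_model import InsultParams

OBJECTIVE_METRICS = ("c_tttt_MPa", "W_kPa")


@dataclass(frozen=True)
class ObjectiveSpec:
    """What enters the combined objective."""

    metric_keys: tuple[str, ...] = OBJECTIVE_METRICS
    y_wt: dict = field(default_factory=dict)
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("need at least one observation point")
        for key in self.metric_keys:
            if self.y_wt.get(key, 0.0) <= 0:
                raise ValueError(f"wild-type normalizer for {key} must be positive")


@dataclass(frozen=True)
class OptimResult:
    """Outcome of one optimizer trial."""

    A_star: tuple[float, float, float]
    phi: float
    n_evaluations: int
    seed: int
    converged_by: str  # mesh | budget
    history: tuple = ()

    def as_dict(self) -> dict:
        return {
            "theta_delta_max": self.A_star[0],
            "theta_gc_max": self.A_star[1],
            "g": self.A_star[2],
            "phi": self.phi,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "converged_by": self.converged_by,
        }


def normalized_mse(model_values: Sequence[float], target_values: Sequence[float],
                   y_wt: float, n: int | None = None) -> float:
    """Wild-type-normalized mean squared error of a metric curve."""
    model = np.asarray(model_values, dtype=float)
    target = np.asarray(target_values, dtype=float)
    if model.size == 0 or target.size == 0:
        raise ValueError("empty value lists")
    if model.shape != target.shape:
        raise ValueError("model and target lists must have equal length")
    if y_wt <= 0:
        raise ValueError("Y_WT must be positive")
    n = model.size if n is None else n
    return float(np.sum(((model - target) / y_wt) ** 2) / n)


def combined_objective(j_stiffness: float, j_energy: float) -> float:
    """Arithmetic mean of the stiffness and stored-energy errors."""
    if j_stiffness < 0 or j_energy < 0:
        raise ValueError("objective terms must be non-negative")
    return 0.5 * (j_stiffness + j_energy)


def lhs_sample(bounds: Sequence[tuple[float, float]], n_points: int,
               seed: int) -> np.ndarray:
    """Latin-hypercube design in a box: one point per stratum per dimension."""
    bounds = np.asarray(bounds, dtype=float)
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if np.any(bounds[:, 1] <= bounds[:, 0]):
        raise ValueError("degenerate bounds")
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    unit = sampler.random(n_points)
    return qmc.scale(unit, bounds[:, 0], bounds[:, 1])


class KrigingSurrogate:
    """Interpolating Gaussian-process surrogate on a box.

    Inputs are scaled to the unit box; hyperparameters are fit by maximum
    likelihood with a tiny fixed nugget for conditioning, so predictions
    at training points reproduce the training values.
    """

    def __init__(self, points: np.ndarray, values: np.ndarray,
                 bounds: Sequence[tuple[float, float]] | None = None,
                 nugget: float = 1e-10, seed: int = 0):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        values = np.asarray(values, dtype=float)
        if len(points) < 2:
            raise ValueError("need at least two training points")
        uniq, idx = np.unique(points.round(12), axis=0, return_index=True)
        if len(uniq) < len(points):
            keep = np.sort(idx)
            dup_vals = {}
            for i, p in enumerate(map(tuple, points.round(12))):
                dup_vals.setdefault(p, set()).add(round(float(values[i]), 9))
            if any(len(v) > 1 for v in dup_vals.values()):
                raise ValueError("duplicated points with conflicting values")
            points, values = points[keep], values[keep]
        if bounds is None:
            lo, hi = points.min(axis=0), points.max(axis=0)
            hi = np.where(hi > lo, hi, lo + 1.0)
        else:
            b = np.asarray(bounds, dtype=float)
            lo, hi = b[:, 0], b[:, 1]
        self._lo, self._span = lo, hi - lo
        kernel = ConstantKernel(1.0, (1e-4, 1e6)) * RBF(
            np.full(points.shape[1], 0.3), (1e-3, 1e3))
        self._gp = GaussianProcessRegressor(
            kernel=kernel, alpha=nugget, normalize_y=True,
            n_restarts_optimizer=2, random_state=seed)
        with warnings.catch_warnings():
            # surrogate quality is judged by its interpolation property,
            # not by full ML convergence of the length scales
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._gp.fit(self._scale(points), values)

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self._lo) / self._span

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = self._gp.predict(self._scale(np.asarray(x, dtype=float)))
        return np.asarray(out, dtype=float)

    def __call__(self, x: np.ndarray) -> float:
        return float(self.predict(np.atleast_2d(x))[0])


def kriging_surrogate(points, values, **kw) -> KrigingSurrogate:
    """Fit an interpolating kriging predictor to evaluated points."""
    return KrigingSurrogate(np.asarray(points), np.asarray(values), **kw)


def _surrogate_minimum(surr: KrigingSurrogate, bounds: np.ndarray,
                       starts: np.ndarray) -> np.ndarray:
    best_x, best_f = None, math.inf
    for x0 in starts:
        r = minimize(lambda x: surr(x), x0, method="L-BFGS-B", bounds=bounds)
        if r.fun < best_f:
            best_x, best_f = r.x, r.fun
    return np.clip(best_x, bounds[:, 0], bounds[:, 1])


def smf_optimize(objective: Callable[[np.ndarray], float],
                 bounds: Sequence[tuple[float, float]], seed: int,
                 budget: int = 300, n_init: int | None = None,
                 delta_min: float = 1e-3, delta0: float = 0.25,
                 poll: str = "coordinate") -> OptimResult:
    """Surrogate management framework minimization over a box.

    SEARCH evaluates the kriging-surrogate minimizer while it improves;
    otherwise a positive-spanning POLL stencil of relative size ``delta``
    around the incumbent is evaluated, halving ``delta`` on failure.
    Terminates at ``delta < delta_min`` (mesh) or the evaluation budget.
    Objective failures count as +inf and the incumbent sequence is
    non-increasing.
    """
    bounds = np.asarray(bounds, dtype=float)
    dim = len(bounds)
    span = bounds[:, 1] - bounds[:, 0]
    if np.any(span <= 0):
        raise ValueError("degenerate bounds")
    n_init = 10 * dim if n_init is None else n_init
    if budget < n_init:
        raise ValueError("budget must cover the initial design")
    rng = np.random.default_rng(seed)

    X: list[np.ndarray] = []
    F: list[float] = []

    def run(x: np.ndarray) -> float:
        x = np.clip(x, bounds[:, 0], bounds[:, 1])
        for xi, fi in zip(X, F):
            if np.all(np.abs(xi - x) <= 1e-12 * np.maximum(span, 1.0)):
                return fi
        try:
            f = float(objective(x))
            if not math.isfinite(f):
                f = math.inf
        except Exception:
            f = math.inf
        X.append(x.copy())
        F.append(f)
        return f

    for x in lhs_sample(bounds, n_init, seed):
        run(x)
    inc = int(np.argmin(F))
    x_inc, f_inc = X[inc].copy(), F[inc]

    delta = delta0
    reason = "budget"
    while len(F) < budget:
        if delta < delta_min:
            reason = "mesh"
            break
        # SEARCH on the surrogate while it keeps improving
        improved = True
        while improved and len(F) < budget:
            improved = False
            ok = [i for i, f in enumerate(F) if math.isfinite(f)]
            if len(ok) >= 2 * dim:
                try:
                    surr = kriging_surrogate(
                        np.array([X[i] for i in ok]),
                        np.array([F[i] for i in ok]),
                        bounds=bounds, seed=int(rng.integers(2**31 - 1)))
                    starts = np.vstack([
                        [X[i] for i in np.argsort(F)[:3]],
                        qmc.scale(qmc.LatinHypercube(
                            dim, seed=int(rng.integers(2**31 - 1))).random(4),
                            bounds[:, 0], bounds[:, 1]),
                    ])
                    cand = _surrogate_minimum(surr, bounds, starts)
                except Exception:
                    cand = None
                if cand is not None:
                    f = run(cand)
                    if f < f_inc - 1e-15:
                        x_inc, f_inc = cand.copy(), f
                        improved = True
        if len(F) >= budget:
            break
        # POLL with a positive-spanning coordinate stencil
        if poll == "random":
            Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
            dirs = np.vstack([Q, -Q])
        else:
            eye = np.eye(dim)
            dirs = np.vstack([eye, -eye])
        poll_hit = False
        for d in dirs:
            if len(F) >= budget:
                break
            f = run(x_inc + delta * span * d)
            if f < f_inc - 1e-15:
                x_inc, f_inc = np.clip(x_inc + delta * span * d,
                                       bounds[:, 0], bounds[:, 1]), f
                poll_hit = True
                break
        if not poll_hit:
            delta *= 0.5

    return OptimResult(A_star=tuple(float(v) for v in x_inc), phi=float(f_inc),
                       n_evaluations=len(F), seed=seed, converged_by=reason,
                       history=tuple(zip(map(tuple, X), F)))


# ---------------------------------------------------------------------------
# model-vs-observations objective


def metric_curves(porosities: Sequence[float], A: InsultParams, targets,
                  params, gnr: GnRParams | None = None,
                  n_increments: int = 10) -> dict[str, np.ndarray]:
    """Model metric curves at given porosities under the combined insult.

    Porosities are solved in ascending order with warm starts; results
    are returned in input order.
    """
    gnr = (gnr or GnRParams()).at_apex()
    order = np.argsort(porosities)
    out = {k: np.empty(len(porosities)) for k in
           ("W_kPa", "c_tttt_MPa", "c_zzzz_MPa", "distensibility_per_mmHg",
            "inner_diameter_mm", "thickness_mm")}
    start = None
    for idx in order:
        ins = A.at_porosity(float(porosities[idx]))
        ev = solve_equilibrated(ins, gnr, targets, params,
                                n_increments=n_increments, start=start)
        start = (ev.lambda_theta, ev.composition.m_c, ev.composition.m_m)
        m = evaluate_state_metrics(ev, targets)
        d = m.as_dict()
        for k in out:
            out[k][idx] = d[k]
    return out


def phi_objective(observations, targets, params,
                  gnr: GnRParams | None = None,
                  n_increments: int = 10) -> Callable[[np.ndarray], float]:
    """Phi(A) against an observation set, for use with ``smf_optimize``.

    The model curve is evaluated at each observation's porosity; the
    first continuation is full-depth and subsequent evaluations reuse the
    neighbouring solution.
    """
    df = observations.df
    porosities = df["porosity"].to_numpy(dtype=float)
    y_wt = observations.y_wt

    def phi(vec: np.ndarray) -> float:
        A = InsultParams.from_vector(vec)
        curves = metric_curves(porosities, A, targets, params, gnr,
                               n_increments=n_increments)
        js = [normalized_mse(curves[k], df[k].to_numpy(dtype=float), y_wt[k])
              for k in OBJECTIVE_METRICS]
        return combined_objective(*js)

    return phi
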