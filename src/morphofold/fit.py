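"""Bayesian calibration of the growth simulator against target fold networks.

The objective couples the mechanical solver and the fold-network metric: a
candidate parameter vector is simulated to steady state, its epidermis
surface reduced to a fold network, and the normalized two-component metric
compared (Euclidean distance) with the target. A Gaussian-process surrogate
with expected-improvement acquisition minimizes this black-box objective.

Fitting follows a two-stage protocol: a five-parameter fit (epidermis
modulus with dermis modulus fixed at 1, both Poisson ratios, both tangential
growths) against the control-sample target, then a three-parameter fit of
the epidermis parameters alone against the treated-sample target, with the
dermis parameters carried over unchanged from stage one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm as normal_dist
from scipy.stats import qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from morphofold import foldnet, mech
from morphofold.mesh import DERMIS, EPIDERMIS, LayeredTetMesh

__all__ = [
    "ParamSpace",
    "StoppingRule",
    "OptResult",
    "control_space",
    "treated_space",
    "params_to_model",
    "simulate_and_score",
    "bayes_optimize",
    "staged_fit",
]

log = logging.getLogger(__name__)

#: Default bounds bracketing the plausible layer parameters with margin while
#: respecting model validity (nu capped below the locking regime).
DEFAULT_BOUNDS = {
    "E_epidermis": (0.5, 10.0),
    "nu_epidermis": (0.05, 0.45),
    "nu_dermis": (0.05, 0.45),
    "lambda_T_epidermis": (0.5, 3.0),
    "lambda_T_dermis": (0.5, 3.0),
}


@dataclass(frozen=True)
class ParamSpace:
    """Free parameters with bounds plus fixed parameter values."""

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.names) & set(self.fixed):
            raise ValueError("free and fixed parameter sets overlap")
        for n, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValueError(f"bad bounds for {n}: ({lo}, {hi})")
        for key in ("nu_epidermis", "nu_dermis"):
            if key in self.names:
                hi = dict(zip(self.names, self.bounds))[key][1]
                if hi > mech.NU_SOLVER_CAP:
                    raise ValueError(
                        f"{key} upper bound {hi} exceeds the solver cap "
                        f"{mech.NU_SOLVER_CAP}"
                    )

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_dict(self, x: np.ndarray) -> dict[str, float]:
        d = dict(self.fixed)
        d.update({n: float(v) for n, v in zip(self.names, x)})
        return d

    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


def control_space(bounds: dict | None = None) -> ParamSpace:
    """Five-dimensional stage-1 space (dermis modulus fixed at 1)."""
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    names = (
        "E_epidermis",
        "nu_epidermis",
        "nu_dermis",
        "lambda_T_epidermis",
        "lambda_T_dermis",
    )
    return ParamSpace(
        names=names,
        bounds=tuple(b[n] for n in names),
        fixed={"E_dermis": 1.0},
    )


def treated_space(dermis_params: dict, bounds: dict | None = None) -> ParamSpace:
    """Three-dimensional stage-2 space; dermis values fixed from stage 1."""
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    names = ("E_epidermis", "nu_epidermis", "lambda_T_epidermis")
    return ParamSpace(
        names=names,
        bounds=tuple(b[n] for n in names),
        fixed={
            "E_dermis": 1.0,
            "nu_dermis": float(dermis_params["nu_dermis"]),
            "lambda_T_dermis": float(dermis_params["lambda_T_dermis"]),
        },
    )


def params_to_model(params: dict):
    """Parameter dict -> per-layer (materials, growth) for the solver."""
    materials = {
        EPIDERMIS: mech.ElasticConstants(
            E=params["E_epidermis"], nu=params["nu_epidermis"]
        ),
        DERMIS: mech.ElasticConstants(
            E=params.get("E_dermis", 1.0), nu=params["nu_dermis"]
        ),
    }
    growth = {
        EPIDERMIS: mech.GrowthLaw(
            lambda_N=params.get("lambda_N_epidermis", 0.0),
            lambda_T=params["lambda_T_epidermis"],
        ),
        DERMIS: mech.GrowthLaw(
            lambda_N=params.get("lambda_N_dermis", 0.0),
            lambda_T=params["lambda_T_dermis"],
        ),
    }
    return materials, growth


def simulate_and_score(
    params: dict,
    mesh: LayeredTetMesh,
    target: foldnet.MetricVector,
    norm: foldnet.Normalizer,
    config: mech.SolverConfig | None = None,
    seed: int = 0,
    quantile: float = 0.3,
    spur_fraction: float = 0.02,
    projection_axis: int = 2,
) -> float:
    """Objective: normalized metric distance between simulation and target.

    Deterministic for a given seed. Simulation failures (non-convergence or
    element inversion) return NaN, which :func:`bayes_optimize` converts to
    a finite penalty so the surrogate learns to avoid that region.
    """
    materials, growth = params_to_model(params)
    try:
        state = mech.relax_to_steady_state(mesh, materials, growth, config, seed=seed)
    except (mech.ConvergenceError, mech.ElementInversionError) as exc:
        log.warning("simulation failed for %s: %s", params, exc)
        return float("nan")
    surface = foldnet.epidermis_surface(mesh, state.positions)
    net = foldnet.extract_fold_network(
        surface,
        quantile=quantile,
        spur_fraction=spur_fraction,
        projection_axis=projection_axis,
    )
    mv = foldnet.compute_metrics(net)
    return foldnet.network_distance(mv, target, norm)


@dataclass(frozen=True)
class StoppingRule:
    """Stop after ``patience`` iterations without improvement, or at the cap."""

    patience: int = 500
    max_iterations: int = 3000

    def __post_init__(self):
        if not 0 < self.patience <= self.max_iterations:
            raise ValueError("need 0 < patience <= max_iterations")


@dataclass
class OptResult:
    """Best parameters and full evaluation history of one optimization."""

    best_params: dict
    best_objective: float
    history_x: np.ndarray  # (n, d) evaluated points
    history_y: np.ndarray  # (n,) raw objectives (NaN = failed simulation)
    seed: int
    stopping_reason: str

    @property
    def best_curve(self) -> np.ndarray:
        """Best-so-far objective after each evaluation (non-increasing)."""
        y = np.where(np.isnan(self.history_y), np.inf, self.history_y)
        return np.minimum.accumulate(y)


def _expected_improvement(mu, sd, y_best, xi):
    sd = np.maximum(sd, 1e-12)
    z = (y_best - xi - mu) / sd
    return (y_best - xi - mu) * normal_dist.cdf(z) + sd * normal_dist.pdf(z)


def bayes_optimize(
    space: ParamSpace,
    objective,
    stop: StoppingRule | None = None,
    seed: int = 0,
    n_initial: int | None = None,
) -> OptResult:
    """Seeded global minimization with a GP surrogate and expected improvement.

    ``objective`` maps a parameter dict to a scalar (NaN for a failed
    evaluation; replaced internally by ten times the worst successful value).
    Fully deterministic for a given seed.
    """
    if stop is None:
        stop = StoppingRule()
    rng = np.random.default_rng(seed)
    d = space.dim
    lo, hi = space.lower(), space.upper()
    n_init = n_initial if n_initial is not None else max(8, 2 * d + 2)
    n_init = min(n_init, stop.max_iterations)

    sampler = qmc.LatinHypercube(d=d, seed=int(rng.integers(2**31)))
    X = sampler.random(n_init) * (hi - lo) + lo
    ys = [float(objective(space.to_dict(x))) for x in X]
    X = list(X)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.3), length_scale_bounds=(5e-2, 5.0), nu=2.5
    ) + WhiteKernel(1e-6, (1e-9, 1e-1))

    best_i = int(np.nanargmin(ys)) if np.any(np.isfinite(ys)) else None
    no_improve = 0
    reason = "max_iterations"
    while len(ys) < stop.max_iterations:
        y_arr = np.asarray(ys, dtype=float)
        finite = np.isfinite(y_arr)
        if not finite.any():
            if len(ys) >= 3 * n_init:
                raise RuntimeError("all objective evaluations failed")
            x_next = rng.uniform(lo, hi)
        else:
            worst = float(y_arr[finite].max())
            y_fit = np.where(finite, y_arr, 10.0 * max(worst, 1e-3))
            Xn = (np.asarray(X) - lo) / (hi - lo)
            gp = GaussianProcessRegressor(
                kernel=kernel,
                normalize_y=True,
                n_restarts_optimizer=1,
                random_state=int(rng.integers(2**31)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(Xn, y_fit)
            y_best = float(y_fit.min())
            cand = rng.random((1024, d))
            x_loc = Xn[int(np.argmin(y_fit))]
            local = np.clip(
                x_loc + 0.05 * rng.standard_normal((256, d)), 0.0, 1.0
            )
            cand = np.vstack([cand, local])
            mu, sd = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu, sd, y_best, xi=0.01 * max(y_fit.std(), 1e-9))
            x_next = cand[int(np.argmax(ei))] * (hi - lo) + lo
        y_next = float(objective(space.to_dict(x_next)))
        X.append(x_next)
        ys.append(y_next)
        improved = np.isfinite(y_next) and (
            best_i is None or y_next < ys[best_i] - 1e-12
        )
        if improved:
            best_i = len(ys) - 1
            no_improve = 0
        else:
            no_improve += 1
        if no_improve >= stop.patience:
            reason = "patience"
            break
    if best_i is None:
        raise RuntimeError("all objective evaluations failed")
    return OptResult(
        best_params=space.to_dict(np.asarray(X[best_i])),
        best_objective=float(ys[best_i]),
        history_x=np.asarray(X),
        history_y=np.asarray(ys),
        seed=seed,
        stopping_reason=reason,
    )


def staged_fit(
    control_target: foldnet.MetricVector,
    treated_target: foldnet.MetricVector,
    mesh: LayeredTetMesh,
    norm: foldnet.Normalizer,
    config: mech.SolverConfig | None = None,
    stop: StoppingRule | None = None,
    seed: int = 0,
    sim_seed: int = 0,
    bounds: dict | None = None,
) -> tuple[OptResult, OptResult]:
    """Two-stage calibration: 5-parameter control fit, then 3-parameter treated fit.

    Stage two keeps the dermis Poisson ratio and tangential growth at the
    stage-one optima and refits only the epidermis parameters.
    """

    def make_objective(target):
        def obj(params):
            return simulate_and_score(
                params, mesh, target, norm, config=config, seed=sim_seed
            )

        return obj

    stage1 = bayes_optimize(
        control_space(bounds), make_objective(control_target), stop, seed=seed
    )
    space2 = treated_space(stage1.best_params, bounds)
    stage2 = bayes_optimize(
        space2, make_objective(treated_target), stop, seed=seed + 1
    )
    return stage1, stage2
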