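"""Particle-swarm hyperparameter search with adaptive inertia weight.

The improved PSO (IPSO) maximizes a fitness function over a box-bounded
search space.  Two modifications to the canonical swarm update target
premature convergence:

* **subgroup-adaptive inertia** — particles fitter than the swarm average
  get the small terminal weight ``omega_e`` (exploit), while the rest
  interpolate between ``omega_s`` and ``omega_e`` according to how far their
  fitness sits below the current maximum (explore);
* **dynamic learning factors** — the cognitive factor c1 decays linearly
  from ``c_max`` to ~0 and the social factor c2 grows linearly from
  ``c_min`` to ~2*c_min over the run, shifting particles from self-guided
  to swarm-guided search.

For SVM tuning the 3-D position encodes (log2 C, log2 g, gamma); fitness is
mean stratified 5-fold cross-validation accuracy on the training split.
Setting ``inertia`` to a constant (or "linear") and ``factors`` to a fixed
(c1, c2) pair recovers standard PSO, which serves as the comparison
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .mkl_svm import KernelParams

__all__ = [
    "PsoConfig",
    "OptimizeResult",
    "adaptive_inertia",
    "dynamic_factors",
    "update_particle",
    "optimize",
    "decode_position",
    "encode_params",
    "make_cv_fitness",
    "SVM_BOUNDS",
]

#: search box for (log2 C, log2 g, gamma)
SVM_BOUNDS = (np.array([-9.0, -7.0, 0.0]), np.array([9.0, 7.0, 1.0]))


def adaptive_inertia(f_i: float, f_avg: float, f_max: float,
                     omega_s: float = 0.9, omega_e: float = 0.4) -> float:
    """Subgroup-adaptive inertia weight.

    Particles with above-average fitness get ``omega_e``; the rest get
    ``omega_s - (f_i - f_max)(omega_s - omega_e)/(f_avg - f_max)``, clipped
    to [omega_e, omega_s].  The degenerate swarm (f_avg == f_max) maps to
    ``omega_e`` for continuity with the upper branch.
    """
    if f_i > f_avg or f_avg == f_max:
        return omega_e
    w = omega_s - (f_i - f_max) * (omega_s - omega_e) / (f_avg - f_max)
    return float(np.clip(w, omega_e, omega_s))


def dynamic_factors(t: int, big_t: int, c_max: float = 2.5,
                    c_min: float = 0.5) -> tuple[float, float]:
    """Linearly scheduled learning factors at iteration ``t`` of ``big_t``.

    c1 = c_max - (t-1)/T * c_max decays; c2 = c_min + (t-1)/T * c_min grows.
    """
    if not 1 <= t <= big_t:
        raise ValueError(f"iteration t={t} outside [1, {big_t}]")
    frac = (t - 1) / big_t
    return c_max - frac * c_max, c_min + frac * c_min


def update_particle(x: np.ndarray, v: np.ndarray, p_best: np.ndarray,
                    g_best: np.ndarray, omega: float, c1: float, c2: float,
                    lower: np.ndarray, upper: np.ndarray, v_max: np.ndarray,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One velocity/position update with per-dimension r1, r2 ~ U[0,1].

    Velocity is clipped to [-v_max, v_max] and position to the search box.
    """
    r1 = rng.uniform(size=x.shape)
    r2 = rng.uniform(size=x.shape)
    v_new = omega * v + c1 * r1 * (p_best - x) + c2 * r2 * (g_best - x)
    v_new = np.clip(v_new, -v_max, v_max)
    x_new = np.clip(x + v_new, lower, upper)
    return x_new, v_new


@dataclass
class PsoConfig:
    """Swarm configuration.

    ``inertia`` selects the strategy: "adaptive" (IPSO), "linear"
    (omega_s -> omega_e over the run) or a float constant.  ``factors`` is
    "dynamic" (IPSO schedule) or a fixed (c1, c2) pair for baseline PSO.
    """

    n_particles: int = 20
    n_iterations: int = 200
    lower: np.ndarray = field(default_factory=lambda: SVM_BOUNDS[0].copy())
    upper: np.ndarray = field(default_factory=lambda: SVM_BOUNDS[1].copy())
    omega_s: float = 0.9
    omega_e: float = 0.4
    c_max: float = 2.5
    c_min: float = 0.5
    v_max_fraction: float = 0.2
    inertia: str | float = "adaptive"
    factors: str | tuple[float, float] = "dynamic"
    seed: int = 0
    early_stop_fitness: float | None = None

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if self.lower.shape != self.upper.shape or np.any(self.lower >= self.upper):
            raise ValueError("invalid search bounds")
        if self.n_particles < 2 or self.n_iterations < 1:
            raise ValueError("need at least 2 particles and 1 iteration")


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray               # per-iteration global-best fitness
    n_evaluations: int
    positions: np.ndarray           # final particle positions


def _safe_fitness(fn: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    val = float(fn(x))
    if not np.isfinite(val):
        warnings.warn(f"non-finite fitness at {x}; treating as -inf", RuntimeWarning)
        return -np.inf
    return val


def optimize(fitness: Callable[[np.ndarray], float], config: PsoConfig) -> OptimizeResult:
    """Run the swarm for ``n_iterations`` (maximization); reproducible by seed.

    The returned trace holds the global-best fitness after initialization
    and after each iteration, so it is monotone non-decreasing by
    construction.  An optional ``early_stop_fitness`` halts the search as
    soon as the global best reaches it.
    """
    rng = np.random.default_rng(config.seed)
    dim = config.lower.shape[0]
    span = config.upper - config.lower
    v_max = config.v_max_fraction * span

    x = config.lower + span * rng.uniform(size=(config.n_particles, dim))
    v = rng.uniform(-1.0, 1.0, size=(config.n_particles, dim)) * v_max
    fit = np.array([_safe_fitness(fitness, xi) for xi in x])
    n_evals = config.n_particles
    p_best, p_fit = x.copy(), fit.copy()
    g_idx = int(np.argmax(p_fit))
    g_best, g_fit = p_best[g_idx].copy(), float(p_fit[g_idx])
    trace = [g_fit]

    for t in range(1, config.n_iterations + 1):
        if config.early_stop_fitness is not None and g_fit >= config.early_stop_fitness:
            break
        if config.factors == "dynamic":
            c1, c2 = dynamic_factors(t, config.n_iterations, config.c_max, config.c_min)
        else:
            c1, c2 = config.factors
        finite = fit[np.isfinite(fit)]
        f_avg = float(finite.mean()) if finite.size else 0.0
        f_max = float(finite.max()) if finite.size else 0.0

        for i in range(config.n_particles):
            if config.inertia == "adaptive":
                omega = adaptive_inertia(fit[i], f_avg, f_max, config.omega_s, config.omega_e)
            elif config.inertia == "linear":
                frac = (t - 1) / max(config.n_iterations - 1, 1)
                omega = config.omega_s - frac * (config.omega_s - config.omega_e)
            else:
                omega = float(config.inertia)
            x[i], v[i] = update_particle(x[i], v[i], p_best[i], g_best, omega,
                                         c1, c2, config.lower, config.upper, v_max, rng)
            fit[i] = _safe_fitness(fitness, x[i])
            n_evals += 1
            if fit[i] > p_fit[i]:
                p_best[i], p_fit[i] = x[i].copy(), fit[i]
                if fit[i] > g_fit:
                    g_best, g_fit = x[i].copy(), float(fit[i])
        trace.append(g_fit)

    return OptimizeResult(best_position=g_best, best_fitness=g_fit,
                          trace=np.asarray(trace), n_evaluations=n_evals,
                          positions=x)


def decode_position(x: Sequence[float], d: int = 3) -> KernelParams:
    """Map a swarm position (log2 C, log2 g, gamma) to kernel parameters."""
    x = np.asarray(x, float)
    lo, hi = SVM_BOUNDS
    if x.shape != lo.shape or np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
        raise ValueError(f"position {x} outside the SVM search bounds")
    return KernelParams(C=float(2.0 ** x[0]), g=float(2.0 ** x[1]),
                        gamma=float(np.clip(x[2], 0.0, 1.0)), d=d)


def encode_params(params: KernelParams) -> np.ndarray:
    """Inverse of :func:`decode_position`."""
    return np.array([np.log2(params.C), np.log2(params.g), params.gamma])


def make_cv_fitness(x, y, n_folds: int = 5, fold_seed: int = 0,
                    tol: float = 1e-4, d: int = 3,
                    max_iter: int = 20_000) -> Callable[[np.ndarray], float]:
    """Stratified k-fold CV accuracy of the mixed-kernel SVM as a fitness.

    The polynomial part (X X' + 1)^d and the pairwise squared distances are
    precomputed once; each call assembles the mixed Gram for the decoded
    (C, g, gamma) and averages fold accuracies.  Folds are fixed by
    ``fold_seed`` so the fitness is deterministic.  ``max_iter`` bounds the
    solver effort per fold: hyperparameter corners where the SMO solver
    crawls (huge C on an ill-scaled kernel) simply score what their
    truncated solution earns, which keeps every swarm evaluation cheap
    without biasing the search toward them.
    """
    from .fusion import FeatureBlock
    if isinstance(x, FeatureBlock):
        x = x.matrix
    x = np.asarray(x, float)
    y = np.asarray(y)
    poly_base = x @ x.T + 1.0
    sq = np.sum(x * x, axis=1)
    dist2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    poly_pow = poly_base ** d
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    folds = list(skf.split(x, y))

    def fitness(position: np.ndarray) -> float:
        params = decode_position(position, d=d)
        k = params.gamma * poly_pow + (1 - params.gamma) * np.exp(-dist2 / (2 * params.g**2))
        accs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for tr, te in folds:
                clf = SVC(C=params.C, kernel="precomputed", tol=tol, max_iter=max_iter)
                clf.fit(k[np.ix_(tr, tr)], y[tr])
                accs.append(float(np.mean(clf.predict(k[np.ix_(te, tr)]) == y[te])))
        return float(np.mean(accs))

    return fitness
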