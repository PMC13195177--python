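"""Inner fluence optimization over nonnegative per-beamlet intensities.

One call runs a fixed iteration budget (40 by default — the per-loop budget
the outer controller paces itself with) on the composite objective.  Two
backends are provided:

* ``lbfgs`` (default): bound-constrained L-BFGS-B, which gets each inner
  problem close to its optimum within the budget the way a treatment
  planning system's quasi-Newton optimizer does;
* ``pgd``: projected gradient descent with Armijo backtracking, the
  simplest method with an explicit monotone-descent certificate.

Both backends keep the fluence nonnegative at every iterate and return a
nonincreasing per-iteration objective history; the outer loop warm-starts
each call from the previous solution so the trajectory over loops is
continuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as sciopt

from .dose import (ObjectiveReport, ObjectiveSpec, evaluate_objectives,
                   total_objective_and_gradient)
from .phantom import InfluenceMatrix


@dataclass(frozen=True)
class OptimizerConfig:
    inner_iterations: int = 40
    tolerance: float = 1e-9       # relative objective-change convergence floor
    backend: str = "lbfgs"        # "lbfgs" | "pgd"
    initial_step: float = 1.0
    backtrack_factor: float = 0.5
    max_backtracks: int = 40
    armijo_c: float = 1e-4

    def __post_init__(self):
        if self.inner_iterations < 0:
            raise ValueError("inner_iterations must be >= 0")
        if self.backend not in ("lbfgs", "pgd"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class OptimizeResult:
    fluence: np.ndarray
    report: ObjectiveReport
    objective_history: list[float]


def initial_fluence(influence: InfluenceMatrix, ptv_mask: np.ndarray,
                    prescription: float) -> np.ndarray:
    """Uniform positive fluence scaled so the mean PTV dose is ~ D_p."""
    ones = np.ones(influence.n_beamlets)
    dose = influence.matrix.T @ ones
    mean_ptv = float(dose[np.asarray(ptv_mask, bool).ravel()].mean())
    if mean_ptv <= 0:
        raise ValueError("unit fluence deposits no dose in the PTV")
    return ones * (prescription / mean_ptv)


def _check_finite(f: float, g: np.ndarray) -> None:
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite objective or gradient")


def _run_lbfgs(fun, x0: np.ndarray, config: OptimizerConfig) -> tuple[np.ndarray, list[float]]:
    history = [fun(x0)[0]]

    def objective(x):
        f, g = fun(x)
        _check_finite(f, g)
        return f, g

    def callback(xk):
        fk, _ = fun(xk)
        # L-BFGS-B line searches enforce sufficient decrease, but guard the
        # recorded history so it is nonincreasing by construction.
        history.append(min(fk, history[-1]))

    res = sciopt.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * x0.size, callback=callback,
        options={"maxiter": config.inner_iterations,
                 "ftol": config.tolerance, "gtol": 1e-12})
    x = np.maximum(0.0, res.x)
    f_final = fun(x)[0]
    if f_final <= history[0]:
        return x, history
    return x0, [history[0]]  # solver failed to descend; keep the start


def _run_pgd(fun, x0: np.ndarray, config: OptimizerConfig) -> tuple[np.ndarray, list[float]]:
    x = x0.copy()
    f, g = fun(x)
    _check_finite(f, g)
    history = [f]
    step = config.initial_step
    for _ in range(config.inner_iterations):
        accepted = False
        for _ in range(config.max_backtracks):
            x_new = np.maximum(0.0, x - step * g)
            f_new, g_new = fun(x_new)
            _check_finite(f_new, g_new)
            decrease = float(g @ (x - x_new))
            if f_new <= f - config.armijo_c * decrease and f_new <= f:
                accepted = True
                break
            step *= config.backtrack_factor
        if not accepted:
            break
        converged = f > 0 and (f - f_new) / max(f, 1e-300) < config.tolerance
        x, f, g = x_new, f_new, g_new
        history.append(f)
        step /= config.backtrack_factor  # gentle growth for the next iterate
        if converged:
            break
    return x, history


def optimize_fluence(influence: InfluenceMatrix,
                     objectives: list[ObjectiveSpec],
                     masks: dict[str, np.ndarray],
                     prescription: float,
                     start: np.ndarray,
                     config: OptimizerConfig = OptimizerConfig()) -> OptimizeResult:
    """Minimize the composite objective over nonnegative fluence.

    Runs up to ``config.inner_iterations`` iterations of the configured
    backend.  The total objective at return never exceeds the value at
    ``start``, and the returned history is nonincreasing.
    """
    x0 = np.asarray(start, dtype=float).copy()
    if x0.shape != (influence.n_beamlets,):
        raise ValueError("start fluence has wrong length")
    if np.any(x0 < 0):
        raise ValueError("start fluence must be nonnegative")

    def fun(x):
        return total_objective_and_gradient(objectives, influence, x, masks,
                                            prescription)

    if config.inner_iterations == 0:
        f0, g0 = fun(x0)
        _check_finite(f0, g0)
        x, history = x0, [f0]
    elif config.backend == "lbfgs":
        x, history = _run_lbfgs(fun, x0, config)
    else:
        x, history = _run_pgd(fun, x0, config)

    dose = influence.matrix.T @ x
    report = evaluate_objectives(objectives, dose, masks, prescription)
    return OptimizeResult(x, report, history)
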