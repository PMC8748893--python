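"""Mini-batch optimizer engines for condition-decomposable ODE objectives.

The update rule is

    theta^(r+1) = theta^(r) + eta_r * delta_r,

where ``delta_r`` is the algorithm's proposed direction computed from the
mini-batch gradient estimate sum_{e in S_r} grad J_e(theta^(r)), and
``eta_r`` follows a prescheduled learning-rate trajectory.  Four algorithms
are provided — SGD, SGD with momentum, RMSProp, and Adam in a *standard*
(rho1, rho2) = (0.9, 0.999) and a *balanced* (0.9, 0.9) variant.

Two reliability layers distinguish this from plain deep-learning loops:

* a *rescue interceptor* that reacts to objective evaluation failures
  (un-integrable ODEs) by undoing the previous update and shrinking the step
  length like a one-dimensional trust region, with gradual recovery; and
* an optional mini-batch *line search* that re-evaluates the objective
  (without gradient) on the same mini-batch at backtracked step sizes before
  accepting an update.

Everything operates on the log10 parameter scale inside a box, with
element-wise clipping after each update.
"""

from __future__ import annotations

import json
import math
import time as _time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .objective import ObjectiveValue, ParameterSpace

__all__ = [
    "LearningRateSchedule",
    "MiniBatchOptimizer",
    "SGD",
    "Momentum",
    "RMSProp",
    "Adam",
    "make_optimizer",
    "make_epoch_batches",
    "OptimizationHistory",
    "MultiStartResult",
    "run_minibatch",
    "run_fullbatch_reference",
    "run_multistart",
    "suggest_learning_rate",
]

TERM_COMPLETED = "completed"
TERM_RESCUE_EXHAUSTED = "rescue_exhausted"
TERM_INITIAL_FAILURE = "initial_failure"
TERM_WALL_TIME = "wall_time"

MAX_RESCUE_ATTEMPTS = 10
MAX_LINE_SEARCH_TRIALS = 3
RESCUE_REDUCTION = 0.5
RESCUE_RECOVERY = 2.0


# ----------------------------------------------------------------------
# learning-rate schedules


@dataclass
class LearningRateSchedule:
    """Prescheduled learning-rate trajectory.

    ``log_decreasing`` interpolates geometrically from ``eta_start`` at step
    0 to ``eta_end`` at the final step; ``constant`` keeps ``eta_start``.
    The four named presets cover three logarithmically decreasing ranges
    (1e0->1e-3, 1e-1->1e-4, 1e-2->1e-5) and one constant rate (1e-3).
    """

    mode: str = "log_decreasing"
    eta_start: float = 1e-1
    eta_end: float = 1e-4

    def __post_init__(self) -> None:
        if self.mode not in ("log_decreasing", "constant"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.eta_start <= 0 or (self.mode == "log_decreasing" and self.eta_end <= 0):
            raise ValueError("learning rates must be positive")

    def eta(self, step: int, total_steps: int) -> float:
        if self.mode == "constant":
            return self.eta_start
        if total_steps < 2:
            return self.eta_start
        frac = step / (total_steps - 1)
        return self.eta_start * (self.eta_end / self.eta_start) ** frac

    # named presets -----------------------------------------------------
    @classmethod
    def schedule_1(cls) -> "LearningRateSchedule":
        """High, logarithmically decreasing from 1e0 to 1e-3."""
        return cls("log_decreasing", 1e0, 1e-3)

    @classmethod
    def schedule_2(cls) -> "LearningRateSchedule":
        """Medium, logarithmically decreasing from 1e-1 to 1e-4."""
        return cls("log_decreasing", 1e-1, 1e-4)

    @classmethod
    def schedule_3(cls) -> "LearningRateSchedule":
        """Low, logarithmically decreasing from 1e-2 to 1e-5."""
        return cls("log_decreasing", 1e-2, 1e-5)

    @classmethod
    def schedule_4(cls) -> "LearningRateSchedule":
        """Constant, fixed to 1e-3."""
        return cls("constant", 1e-3, 1e-3)

    @classmethod
    def from_string(cls, spec: str) -> "LearningRateSchedule":
        """Parse ``log:START:END`` or ``const:VALUE`` (or ``schedule_N``)."""
        presets = {f"schedule_{i}": getattr(cls, f"schedule_{i}") for i in (1, 2, 3, 4)}
        if spec in presets:
            return presets[spec]()
        kind, _, rest = spec.partition(":")
        if kind == "log":
            a, _, b = rest.partition(":")
            return cls("log_decreasing", float(a), float(b))
        if kind == "const":
            return cls("constant", float(rest), float(rest))
        raise ValueError(f"cannot parse schedule spec {spec!r}")


def suggest_learning_rate(n_theta: int, kappa: float = 0.05) -> LearningRateSchedule:
    """Heuristic schedule targeting an initial step size of kappa*sqrt(n_theta).

    For the adaptive algorithms (RMSProp, Adam) the proposed update has norm
    close to sqrt(n_theta), so the learning rate that realizes a step of
    kappa*sqrt(n_theta) is simply eta_start = kappa, with kappa in
    [0.01, 0.1] a reasonable first choice.  The end rate mirrors the
    three-decade decay of the preset schedules.
    """
    if not (0 < kappa):
        raise ValueError("kappa must be positive")
    return LearningRateSchedule("log_decreasing", kappa, kappa * 1e-3)


# ----------------------------------------------------------------------
# step directions


class MiniBatchOptimizer:
    """Base class: maps a gradient estimate to a proposed update delta."""

    name = "base"

    def __init__(self) -> None:
        self._n: int | None = None

    def reset(self, n_theta: int) -> None:
        self._n = n_theta

    def direction(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def accumulators(self) -> dict[str, np.ndarray]:
        return {}


class SGD(MiniBatchOptimizer):
    """Plain stochastic gradient descent: delta = -g."""

    name = "sgd"

    def direction(self, g: np.ndarray) -> np.ndarray:
        return -np.asarray(g, float)


class Momentum(MiniBatchOptimizer):
    """SGD with momentum: a decaying average of gradients as direction."""

    name = "momentum"

    def __init__(self, rho: float = 0.9) -> None:
        super().__init__()
        self.rho = rho

    def reset(self, n_theta: int) -> None:
        super().reset(n_theta)
        self.v = np.zeros(n_theta)

    def direction(self, g: np.ndarray) -> np.ndarray:
        self.v = self.rho * self.v + np.asarray(g, float)
        return -self.v

    def accumulators(self):
        return {"v": self.v}


class RMSProp(MiniBatchOptimizer):
    """Adaptive preconditioning by a decaying average of squared gradients."""

    name = "rmsprop"

    def __init__(self, rho: float = 0.9, eps: float = 1e-8) -> None:
        super().__init__()
        self.rho = rho
        self.eps = eps

    def reset(self, n_theta: int) -> None:
        super().reset(n_theta)
        self.a = np.zeros(n_theta)

    def direction(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, float)
        self.a = self.rho * self.a + (1.0 - self.rho) * g * g
        return -g / (np.sqrt(self.a) + self.eps)

    def accumulators(self):
        return {"a": self.a}


class Adam(MiniBatchOptimizer):
    """Adam with bias correction.

    ``standard`` uses (rho1, rho2) = (0.9, 0.999) as in the original
    publication; ``balanced`` sets both decay rates to 0.9, which empirically
    improves calibration of ODE models.
    """

    name = "adam"

    def __init__(self, rho1: float = 0.9, rho2: float = 0.999, eps: float = 1e-8) -> None:
        super().__init__()
        self.rho1 = rho1
        self.rho2 = rho2
        self.eps = eps

    @classmethod
    def balanced(cls) -> "Adam":
        opt = cls(rho1=0.9, rho2=0.9)
        opt.name = "adam-balanced"
        return opt

    def reset(self, n_theta: int) -> None:
        super().reset(n_theta)
        self.m = np.zeros(n_theta)
        self.v = np.zeros(n_theta)
        self.t = 0

    def direction(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, float)
        self.t += 1
        self.m = self.rho1 * self.m + (1.0 - self.rho1) * g
        self.v = self.rho2 * self.v + (1.0 - self.rho2) * g * g
        m_hat = self.m / (1.0 - self.rho1 ** self.t)
        v_hat = self.v / (1.0 - self.rho2 ** self.t)
        return -m_hat / (np.sqrt(v_hat) + self.eps)

    def accumulators(self):
        return {"m": self.m, "v": self.v}


def make_optimizer(name: str) -> MiniBatchOptimizer:
    """Factory for the algorithm tags used by the CLI and run configs."""
    name = name.lower().replace("_", "-")
    if name == "sgd":
        return SGD()
    if name == "momentum":
        return Momentum()
    if name == "rmsprop":
        return RMSProp()
    if name == "adam":
        return Adam()
    if name in ("adam-balanced", "adam-b"):
        return Adam.balanced()
    raise ValueError(f"unknown optimizer {name!r}")


def apply_update(
    theta: np.ndarray,
    delta: np.ndarray,
    eta: float,
    bounds: ParameterSpace,
    step_scale: float = 1.0,
) -> np.ndarray:
    """theta + step_scale * eta * delta, clipped element-wise to the box."""
    return bounds.clip(np.asarray(theta, float) + step_scale * eta * np.asarray(delta, float))


# ----------------------------------------------------------------------
# epoch mini-batching


def make_epoch_batches(
    condition_ids: Sequence[str],
    batch_size: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Random disjoint mini-batches covering all conditions exactly once.

    The id list is shuffled and split into ceil(M / batch_size) consecutive
    chunks; the last chunk may be smaller but is kept, so every condition is
    used once per epoch.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    ids = list(condition_ids)
    if batch_size > len(ids):
        import warnings

        warnings.warn("batch_size exceeds the number of conditions; using one full batch")
        batch_size = len(ids)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return [perm[i:i + batch_size] for i in range(0, len(perm), batch_size)]


# ----------------------------------------------------------------------
# histories


@dataclass
class OptimizationHistory:
    """Per-step record of one local optimization run.

    ``theta_trace[r]`` is the point at which step r's gradient was evaluated;
    ``j_trace[r]`` the mini-batch objective there.  ``final_theta`` is the
    last accepted point.  ``events`` collects rescue / line-search incidents
    as (step, kind, detail) tuples.  ``n_condition_sims`` is the cumulative
    count of condition simulations — the hardware-independent cost proxy.
    """

    start_id: int = 0
    algorithm: str = ""
    steps: list[int] = field(default_factory=list)
    epochs: list[int] = field(default_factory=list)
    theta_trace: list[np.ndarray] = field(default_factory=list)
    j_trace: list[float] = field(default_factory=list)
    eta_trace: list[float] = field(default_factory=list)
    step_scale_trace: list[float] = field(default_factory=list)
    sim_count_trace: list[int] = field(default_factory=list)
    events: list[tuple] = field(default_factory=list)
    full_j_per_epoch: list[float] = field(default_factory=list)
    final_theta: np.ndarray | None = None
    termination: str = TERM_COMPLETED
    n_condition_sims: int = 0
    n_grad_evals: int = 0
    n_obj_evals: int = 0
    final_metrics: dict | None = None
    steps_per_epoch: int = 1
    wall_time_s: float = 0.0

    def record(self, step, epoch, theta, j, eta, step_scale):
        self.steps.append(int(step))
        self.epochs.append(int(epoch))
        self.theta_trace.append(np.array(theta, dtype=float))
        self.j_trace.append(float(j))
        self.eta_trace.append(float(eta))
        self.step_scale_trace.append(float(step_scale))
        self.sim_count_trace.append(int(self.n_condition_sims))

    def thetas(self) -> np.ndarray:
        return np.array(self.theta_trace)

    @property
    def final_J(self) -> float:
        if self.final_metrics and "J_full" in self.final_metrics:
            return self.final_metrics["J_full"]
        return self.j_trace[-1] if self.j_trace else np.nan


@dataclass
class MultiStartResult:
    """Histories and start points of one multi-start experiment."""

    histories: list[OptimizationHistory]
    starts: np.ndarray  # (n_starts, n_theta), log10 scale

    @property
    def final_values(self) -> np.ndarray:
        return np.array([h.final_J for h in self.histories])

    def best(self) -> OptimizationHistory:
        finals = self.final_values
        finite = np.where(np.isfinite(finals), finals, np.inf)
        return self.histories[int(np.argmin(finite))]


# ----------------------------------------------------------------------
# the mini-batch loop


def _quadratic_backtrack(alpha_prev: float, j0: float, dphi0: float, j_trial: float) -> float:
    """One safeguarded quadratic-interpolation backtracking step.

    Fits a quadratic to phi(0)=j0, phi'(0)=dphi0 and phi(alpha_prev)=j_trial
    and returns its minimizer, safeguarded to [0.1, 0.5] * alpha_prev.
    """
    denom = 2.0 * (j_trial - j0 - dphi0 * alpha_prev)
    if denom <= 0 or not np.isfinite(denom):
        alpha = 0.5 * alpha_prev
    else:
        alpha = -dphi0 * alpha_prev ** 2 / denom
    return float(np.clip(alpha, 0.1 * alpha_prev, 0.5 * alpha_prev))


def run_minibatch(
    objective,
    bounds: ParameterSpace,
    theta0: np.ndarray,
    algorithm: str | MiniBatchOptimizer = "adam-balanced",
    schedule: LearningRateSchedule | str = "schedule_2",
    batch_size: int = 30,
    epochs: int = 50,
    seed: int | np.random.Generator = 0,
    rescue: bool = True,
    line_search: bool = False,
    start_id: int = 0,
    full_eval_every_epoch: bool = False,
    compute_final_metrics: bool = True,
    wall_time_limit_s: float | None = None,
) -> OptimizationHistory:
    """One local mini-batch optimization run.

    ``objective`` must expose ``condition_ids`` and
    ``evaluate(theta_log10, subset, with_gradient) -> ObjectiveValue``.
    Each epoch shuffles the conditions into disjoint mini-batches; each step
    evaluates the batch objective and gradient, proposes an update via the
    chosen algorithm, optionally line-searches it on the same batch, and
    applies it with element-wise clipping to the box.

    Evaluation failures trigger the rescue interceptor: the previous update
    is undone, the step length shrunk by half, and the step retried on the
    same batch — at most 10 times, after which the run terminates with
    ``termination="rescue_exhausted"``.  A failure at the initial point
    cannot be recovered (``"initial_failure"``).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    opt = make_optimizer(algorithm) if isinstance(algorithm, str) else algorithm
    sched = LearningRateSchedule.from_string(schedule) if isinstance(schedule, str) else schedule

    theta = bounds.clip(np.asarray(theta0, dtype=float))
    n_theta = theta.size
    opt.reset(n_theta)

    cids = list(objective.condition_ids)
    steps_per_epoch = math.ceil(len(cids) / min(batch_size, len(cids)))
    total_steps = epochs * steps_per_epoch

    hist = OptimizationHistory(start_id=start_id, algorithm=opt.name,
                               steps_per_epoch=steps_per_epoch)
    t_start = _time.perf_counter()

    def evaluate(th, batch, with_gradient):
        val = objective.evaluate(th, batch, with_gradient=with_gradient)
        hist.n_condition_sims += getattr(val, "n_sims", len(batch))
        if with_gradient:
            hist.n_grad_evals += 1
        else:
            hist.n_obj_evals += 1
        return val

    step_scale = 1.0
    in_recovery = False
    theta_prev = None
    delta_prev = None
    eta_prev = None
    r = 0

    for epoch in range(epochs):
        batches = make_epoch_batches(cids, batch_size, rng)
        for batch in batches:
            if wall_time_limit_s is not None and _time.perf_counter() - t_start > wall_time_limit_s:
                hist.termination = TERM_WALL_TIME
                break

            val = evaluate(theta, batch, True)

            # ---- rescue interceptor -----------------------------------
            if not val.ok:
                if theta_prev is None:
                    hist.termination = TERM_INITIAL_FAILURE
                    hist.events.append((r, "initial_failure", ""))
                    break
                if not rescue:
                    hist.termination = TERM_RESCUE_EXHAUSTED
                    hist.events.append((r, "failure_no_rescue", ""))
                    break
                recovered = False
                for attempt in range(1, MAX_RESCUE_ATTEMPTS + 1):
                    step_scale *= RESCUE_REDUCTION
                    theta = apply_update(theta_prev, delta_prev, eta_prev, bounds, step_scale)
                    val = evaluate(theta, batch, True)
                    hist.events.append((r, "rescue_attempt", f"{attempt}:{step_scale:g}"))
                    if val.ok:
                        recovered = True
                        in_recovery = True
                        break
                if not recovered:
                    hist.termination = TERM_RESCUE_EXHAUSTED
                    hist.events.append((r, "rescue_exhausted", ""))
                    break
            elif in_recovery:
                # gradual restoration of the unmodified step length
                step_scale = min(1.0, step_scale * RESCUE_RECOVERY)
                if step_scale >= 1.0:
                    in_recovery = False

            eta = sched.eta(r, total_steps)
            delta = opt.direction(val.gradient)
            hist.record(r, epoch, theta, val.J, eta, step_scale)

            # ---- step proposal / line search --------------------------
            if not line_search:
                theta_next = apply_update(theta, delta, eta, bounds, step_scale)
            else:
                theta_next = _line_search_step(
                    objective=objective, evaluate=evaluate, bounds=bounds,
                    theta=theta, delta=delta, eta=eta * step_scale,
                    batch=batch, j0=val.J, g=val.gradient, hist=hist, r=r,
                )
                if theta_next is None:  # all trials failed evaluation
                    if theta_prev is None:
                        hist.termination = TERM_INITIAL_FAILURE
                        break
                    if not rescue:
                        hist.termination = TERM_RESCUE_EXHAUSTED
                        break
                    # treat like a failed step: shrink and retry around theta
                    recovered = False
                    for attempt in range(1, MAX_RESCUE_ATTEMPTS + 1):
                        step_scale *= RESCUE_REDUCTION
                        theta_next = _line_search_step(
                            objective=objective, evaluate=evaluate, bounds=bounds,
                            theta=theta, delta=delta, eta=eta * step_scale,
                            batch=batch, j0=val.J, g=val.gradient, hist=hist, r=r,
                        )
                        hist.events.append((r, "rescue_attempt", f"ls:{attempt}:{step_scale:g}"))
                        if theta_next is not None:
                            recovered = True
                            in_recovery = True
                            break
                    if not recovered:
                        hist.termination = TERM_RESCUE_EXHAUSTED
                        hist.events.append((r, "rescue_exhausted", ""))
                        break

            theta_prev = theta
            delta_prev = delta
            eta_prev = eta
            theta = theta_next
            r += 1
        else:
            if full_eval_every_epoch:
                full = objective.evaluate(theta, None, with_gradient=False)
                hist.n_condition_sims += getattr(full, "n_sims", len(cids))
                hist.full_j_per_epoch.append(full.J if full.ok else np.nan)
            continue
        break  # inner loop broke -> terminate run

    hist.final_theta = np.array(theta)
    if hist.termination == TERM_COMPLETED and r < total_steps:
        pass  # wall-time terminations already labelled
    if compute_final_metrics and hist.termination in (TERM_COMPLETED, TERM_WALL_TIME):
        from .objective import NLLObjective, full_dataset_metrics

        if isinstance(objective, NLLObjective):
            metrics = full_dataset_metrics(objective, theta)
            hist.n_condition_sims += metrics.pop("n_sims", 0)
            hist.final_metrics = metrics
        else:
            full = objective.evaluate(theta, None, with_gradient=False)
            hist.n_condition_sims += getattr(full, "n_sims", len(cids))
            hist.final_metrics = {"J_full": full.J if full.ok else np.nan,
                                  "valid": bool(full.ok)}
    hist.wall_time_s = _time.perf_counter() - t_start
    return hist


def _line_search_step(
    *, objective, evaluate, bounds, theta, delta, eta, batch, j0, g, hist, r
):
    """Backtracking line search on the same mini-batch.

    Trials the full step first; on non-decrease, backtracks by safeguarded
    quadratic interpolation, up to 3 trials.  If no trial improves, the
    smallest-step trial point is accepted anyway (the stochastic setting
    always progresses).  Returns None iff every trial failed evaluation.
    """
    dphi0 = float(np.dot(g, eta * delta))  # directional derivative wrt alpha
    alpha = 1.0
    last_point = None
    for trial in range(1, MAX_LINE_SEARCH_TRIALS + 1):
        cand = apply_update(theta, delta, eta, bounds, alpha)
        val = evaluate(cand, batch, False)
        if val.ok:
            last_point = cand
            if val.J < j0:
                if trial > 1:
                    hist.events.append((r, "line_search", f"accepted:{trial}:{alpha:g}"))
                return cand
            alpha = _quadratic_backtrack(alpha, j0, dphi0, val.J)
        else:
            hist.events.append((r, "line_search_failure", f"{trial}:{alpha:g}"))
            alpha = 0.5 * alpha
    if last_point is None:
        return None
    hist.events.append((r, "line_search", f"exhausted:{alpha:g}"))
    return last_point


# ----------------------------------------------------------------------
# full-batch reference


def run_fullbatch_reference(
    objective,
    bounds: ParameterSpace,
    theta0: np.ndarray,
    max_iterations: int = 100,
    start_id: int = 0,
    compute_final_metrics: bool = True,
) -> OptimizationHistory:
    """Bounded quasi-Newton (L-BFGS-B) minimization of the full objective.

    Serves as the full-batch comparator for benchmarking the mini-batch
    engines; its history uses the same schema.  Evaluation failures are
    mapped to a large finite penalty so the optimizer can retreat.
    """
    theta0 = bounds.clip(np.asarray(theta0, dtype=float))
    hist = OptimizationHistory(start_id=start_id, algorithm="lbfgsb", steps_per_epoch=1)
    t_start = _time.perf_counter()
    penalty = 1e100

    def fun(th):
        val = objective.evaluate(th, None, with_gradient=True)
        hist.n_condition_sims += getattr(val, "n_sims", len(objective.condition_ids))
        hist.n_grad_evals += 1
        if not val.ok:
            return penalty, np.zeros_like(th)
        return val.J, val.gradient

    it = {"k": 0}

    def cb(th):
        val = objective.evaluate(th, None, with_gradient=False)
        hist.n_condition_sims += getattr(val, "n_sims", len(objective.condition_ids))
        hist.record(it["k"], it["k"], th, val.J if val.ok else np.nan, np.nan, 1.0)
        it["k"] += 1

    res = minimize(
        fun, theta0, jac=True, method="L-BFGS-B",
        bounds=list(zip(bounds.lower, bounds.upper)),
        callback=cb, options={"maxiter": max_iterations},
    )
    hist.final_theta = bounds.clip(res.x)
    hist.termination = TERM_COMPLETED if res.success or res.status == 1 else f"optimizer:{res.message}"
    if compute_final_metrics:
        from .objective import NLLObjective, full_dataset_metrics

        if isinstance(objective, NLLObjective):
            metrics = full_dataset_metrics(objective, hist.final_theta)
            hist.n_condition_sims += metrics.pop("n_sims", 0)
            hist.final_metrics = metrics
        else:
            val = objective.evaluate(hist.final_theta, None, with_gradient=False)
            hist.final_metrics = {"J_full": val.J if val.ok else np.nan, "valid": bool(val.ok)}
    hist.wall_time_s = _time.perf_counter() - t_start
    return hist


# ----------------------------------------------------------------------
# multi-start orchestration


def run_multistart(
    objective,
    bounds: ParameterSpace,
    n_starts: int = 100,
    seed: int = 0,
    runner: Callable[..., OptimizationHistory] = run_minibatch,
    starts: np.ndarray | None = None,
    **runner_kwargs,
) -> MultiStartResult:
    """Multi-start local optimization from uniform random points in the box.

    The start set depends only on ``seed`` (and the bounds), so different
    optimizer settings launched with the same seed are paired start-for-start
    — the basis of rank-based optimizer comparisons.  Pass ``starts``
    explicitly to reuse a precomputed set.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if starts is None:
        sample_rng = np.random.default_rng(seed)
        starts = bounds.sample(n_starts, sample_rng)
    starts = np.asarray(starts, dtype=float)
    histories = []
    for i, th0 in enumerate(starts):
        kwargs = dict(runner_kwargs)
        if runner is run_minibatch:
            # each start gets its own batch-shuffling stream, derived from
            # the experiment seed and the start index
            kwargs.setdefault("seed", np.random.default_rng([seed, i]))
        h = runner(objective, bounds, th0, start_id=i, **kwargs)
        histories.append(h)
    return MultiStartResult(histories=histories, starts=starts)
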