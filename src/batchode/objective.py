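"""Per-condition decomposable negative-log-likelihood objective.

For a Gaussian noise model with known per-record standard deviations, the
negative log-likelihood (up to an additive constant) is the weighted
least-squares cost

    J(theta) = sum_e J_e(theta),
    J_e(theta) = 1/2 sum_i ((ybar_{e,i} - y_{e,i}(theta)) / sigma_{e,i})^2,

which decomposes over experimental conditions ``e``.  Mini-batch optimizers
exploit this sum structure: the gradient of a random condition subset is an
unbiased (up to the |S|/M factor) estimate of the direction of the full
gradient.  ``evaluate`` therefore takes an arbitrary condition subset and
returns the *unnormalized sum* over that subset, both for the value and the
gradient.

All optimization-facing parameter vectors and gradients are on the log10
scale; model evaluation converts to the linear scale internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    Condition,
    ODEModel,
    STATUS_OK,
    compute_output_sensitivities,
    simulate_condition,
    simulate_steady_state,
    steady_state_sensitivities,
    STEADY_STATE_TIME,
)

__all__ = [
    "ParameterSpace",
    "CalibrationProblem",
    "ObjectiveValue",
    "NLLObjective",
    "analytic_scaling_factors",
    "full_dataset_metrics",
    "MEASUREMENT_COLUMNS",
]

#: PEtab-flavoured measurement table columns
MEASUREMENT_COLUMNS = [
    "observableId",
    "simulationConditionId",
    "time",
    "measurement",
    "noiseParameters",
]

STATUS_EVAL_FAILURE = "evaluation_failure"


class ConfigurationError(ValueError):
    """Raised for malformed problems, subsets, or tables."""


@dataclass
class ParameterSpace:
    """Box-bounded parameter space on the log10 scale.

    The default box is [-5, 3] per parameter, i.e. [1e-5, 1e3] on the linear
    scale, a biologically plausible range for mass-action rate constants.
    """

    names: list[str]
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        self.lower = np.full(n, -5.0) if self.lower is None else np.asarray(self.lower, float)
        self.upper = np.full(n, 3.0) if self.upper is None else np.asarray(self.upper, float)
        if not np.all(self.lower < self.upper):
            raise ConfigurationError("parameter bounds must satisfy lower < upper")

    @property
    def n_theta(self) -> int:
        return len(self.names)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform start points in the log10 box, shape (n, n_theta)."""
        return rng.uniform(self.lower, self.upper, size=(n, self.n_theta))

    def clip(self, theta_log10: np.ndarray) -> np.ndarray:
        return np.clip(theta_log10, self.lower, self.upper)

    def contains(self, theta_log10: np.ndarray) -> bool:
        return bool(np.all(theta_log10 >= self.lower) and np.all(theta_log10 <= self.upper))


@dataclass
class _CondRecords:
    """Pre-indexed measurement records for one condition."""

    times: np.ndarray          # unique, sorted, finite simulation times
    time_idx: np.ndarray       # per record, index into times (time-course only)
    obs_idx: np.ndarray        # per record, observable index
    y: np.ndarray              # measurements
    sigma: np.ndarray          # noise SDs
    is_steady_state: bool


@dataclass
class CalibrationProblem:
    """A full calibration problem bundle.

    Fields
    ------
    model, conditions, measurements, parameter_space
        The ODE model, condition map (id -> :class:`Condition`), the
        PEtab-flavoured measurement table, and the log10 parameter box.
    theta_true
        Optional ground-truth parameters (linear scale) for synthetic
        problems.
    scaled_observables
        Observables modelled as ``y = s * yhat`` with a free multiplicative
        scale per observable, computed analytically (one group per id).
    """

    model: ODEModel
    conditions: dict[str, Condition]
    measurements: pd.DataFrame
    parameter_space: ParameterSpace
    theta_true: np.ndarray | None = None
    scaled_observables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.measurements
        missing = [c for c in MEASUREMENT_COLUMNS if c not in m.columns]
        if missing:
            raise ConfigurationError(f"measurement table missing columns: {missing}")
        sigma = m["noiseParameters"].to_numpy(dtype=float)
        if np.any(~(sigma > 0)):
            bad = np.flatnonzero(~(sigma > 0))
            raise ConfigurationError(f"noiseParameters must be > 0; offending rows: {bad[:10].tolist()}")
        unknown_cond = set(m["simulationConditionId"]) - set(self.conditions)
        if unknown_cond:
            rows = m.index[m["simulationConditionId"].isin(unknown_cond)][:10].tolist()
            raise ConfigurationError(
                f"measurements reference undefined conditions {sorted(unknown_cond)[:5]} (rows {rows})")
        unknown_obs = set(m["observableId"]) - set(self.model.observable_names)
        if unknown_obs:
            raise ConfigurationError(f"unknown observable ids: {sorted(unknown_obs)}")

    @property
    def condition_ids(self) -> list[str]:
        return sorted(self.conditions)

    @property
    def n_records(self) -> int:
        return len(self.measurements)

    def theta_true_log10(self) -> np.ndarray | None:
        return None if self.theta_true is None else np.log10(self.theta_true)


@dataclass
class ObjectiveValue:
    """Result of one objective evaluation over a condition subset.

    ``J`` is the half-sum of squared weighted residuals; ``J_full_nll`` adds
    the theta-independent Gaussian normalization sum(log(2 pi sigma^2))/2 for
    the evaluated records.  On any condition's integration failure or
    steady-state non-convergence, ``status`` is ``"evaluation_failure"`` and
    J is undefined (NaN).
    """

    J: float
    J_full_nll: float
    per_condition: dict[str, float]
    gradient: np.ndarray | None = None
    status: str = STATUS_OK
    n_sims: int = 0
    scalings: dict[str, float] | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


class NLLObjective:
    """Condition-decomposable negative-log-likelihood objective.

    Exposes the interface mini-batch optimizers consume: ``condition_ids``
    and ``evaluate(theta_log10, subset, with_gradient)``.  Summation order is
    fixed (sorted condition id, record order within a condition) so repeat
    evaluations are bit-identical.
    """

    def __init__(
        self,
        problem: CalibrationProblem,
        rtol: float = 1e-6,
        atol: float = 1e-12,
        apply_scalings: bool = False,
    ) -> None:
        self.problem = problem
        self.model = problem.model
        self.rtol = rtol
        self.atol = atol
        if apply_scalings and not problem.scaled_observables:
            raise ConfigurationError("apply_scalings requires problem.scaled_observables")
        self.apply_scalings = apply_scalings
        self._index_measurements()

    # -- indexing -------------------------------------------------------
    def _index_measurements(self) -> None:
        obs_pos = {name: i for i, name in enumerate(self.model.observable_names)}
        self._records: dict[str, _CondRecords] = {}
        for cid, grp in self.problem.measurements.groupby("simulationConditionId", sort=True):
            cond = self.problem.conditions[cid]
            t = grp["time"].to_numpy(dtype=float)
            if cond.is_steady_state or np.all(np.isinf(t)):
                if not np.all(np.isinf(t)):
                    raise ConfigurationError(
                        f"steady-state condition {cid!r} has finite measurement times")
                self._records[cid] = _CondRecords(
                    times=np.array([]),
                    time_idx=np.zeros(len(grp), dtype=int),
                    obs_idx=np.array([obs_pos[o] for o in grp["observableId"]]),
                    y=grp["measurement"].to_numpy(dtype=float),
                    sigma=grp["noiseParameters"].to_numpy(dtype=float),
                    is_steady_state=True,
                )
            else:
                times = np.unique(t)
                self._records[cid] = _CondRecords(
                    times=times,
                    time_idx=np.searchsorted(times, t),
                    obs_idx=np.array([obs_pos[o] for o in grp["observableId"]]),
                    y=grp["measurement"].to_numpy(dtype=float),
                    sigma=grp["noiseParameters"].to_numpy(dtype=float),
                    is_steady_state=False,
                )

    @property
    def condition_ids(self) -> list[str]:
        return sorted(self._records)

    def n_records(self, subset: Iterable[str] | None = None) -> int:
        cids = self._resolve_subset(subset)
        return int(sum(len(self._records[c].y) for c in cids))

    def _resolve_subset(self, subset: Iterable[str] | None) -> list[str]:
        if subset is None:
            return self.condition_ids
        subset = list(subset)
        if not subset:
            raise ConfigurationError("subset must be non-empty")
        unknown = set(subset) - set(self._records)
        if unknown:
            raise ConfigurationError(f"unknown condition ids in subset: {sorted(unknown)}")
        return sorted(subset)

    # -- simulation of one condition's records --------------------------
    def _simulate(self, cid: str, theta_lin: np.ndarray, with_gradient: bool):
        """Return (yhat_records, dyhat_records or None, ok)."""
        rec = self._records[cid]
        cond = self.problem.conditions[cid]
        if rec.is_steady_state:
            x_ss, y, status = simulate_steady_state(
                self.model, theta_lin, cond, rtol=self.rtol, atol=self.atol)
            if status != STATUS_OK:
                return None, None, False
            yhat = y[rec.obs_idx]
            if not with_gradient:
                return yhat, None, True
            dy = steady_state_sensitivities(self.model, theta_lin, cond, x_ss)
            if dy is None:
                # singular Jacobian (conservation laws): fall back to
                # integrating the variational system out to the horizon
                sens = compute_output_sensitivities(
                    self.model, theta_lin, cond, [STEADY_STATE_TIME],
                    rtol=self.rtol, atol=self.atol, max_steps=10 * 10_000)
                if not sens.ok:
                    return None, None, False
                dy = sens.dy_dtheta[0]
            return yhat, dy[rec.obs_idx, :], True
        if with_gradient:
            sens = compute_output_sensitivities(
                self.model, theta_lin, cond, rec.times, rtol=self.rtol, atol=self.atol)
            if not sens.ok:
                return None, None, False
            yhat = sens.trajectory.observables[rec.time_idx, rec.obs_idx]
            dy = sens.dy_dtheta[rec.time_idx, rec.obs_idx, :]
            return yhat, dy, True
        traj = simulate_condition(
            self.model, theta_lin, cond, rec.times, rtol=self.rtol, atol=self.atol)
        if not traj.ok:
            return None, None, False
        return traj.observables[rec.time_idx, rec.obs_idx], None, True

    # -- evaluation ------------------------------------------------------
    def evaluate(
        self,
        theta_log10: np.ndarray,
        subset: Iterable[str] | None = None,
        with_gradient: bool = False,
    ) -> ObjectiveValue:
        """Objective (and optionally its gradient) over a condition subset.

        The value is the plain sum of per-condition contributions J_e; the
        gradient is the unnormalized sum of per-condition gradients on the
        log10 scale.  A single failing condition fails the whole evaluation.
        """
        cids = self._resolve_subset(subset)
        theta_log10 = np.asarray(theta_log10, dtype=float)
        theta_lin = 10.0 ** theta_log10
        n_th = self.model.n_theta

        scalings = None
        if self.apply_scalings:
            return self._evaluate_scaled(theta_lin, cids, with_gradient)

        J = 0.0
        const = 0.0
        per_condition: dict[str, float] = {}
        grad = np.zeros(n_th) if with_gradient else None
        n_sims = 0
        for cid in cids:
            rec = self._records[cid]
            yhat, dy, ok = self._simulate(cid, theta_lin, with_gradient)
            n_sims += 1
            if not ok:
                return ObjectiveValue(np.nan, np.nan, {}, None, STATUS_EVAL_FAILURE, n_sims)
            r = (rec.y - yhat) / rec.sigma
            J_e = 0.5 * float(r @ r)
            per_condition[cid] = J_e
            J += J_e
            const += float(np.sum(np.log(2.0 * np.pi * rec.sigma ** 2)))
            if with_gradient:
                grad += ((yhat - rec.y) / rec.sigma ** 2) @ dy
        return ObjectiveValue(J, J + 0.5 * const, per_condition, grad,
                              STATUS_OK, n_sims, scalings)

    def _evaluate_scaled(self, theta_lin, cids, with_gradient) -> ObjectiveValue:
        """Evaluation with analytic per-observable scaling factors applied.

        Scales are profiled out per evaluation (on the evaluated subset); by
        the envelope theorem the gradient of the profiled objective equals
        the partial gradient at the optimal scales, so no extra terms arise.
        """
        sims: dict[str, tuple] = {}
        n_sims = 0
        for cid in cids:
            yhat, dy, ok = self._simulate(cid, theta_lin, with_gradient)
            n_sims += 1
            if not ok:
                return ObjectiveValue(np.nan, np.nan, {}, None, STATUS_EVAL_FAILURE, n_sims)
            sims[cid] = (yhat, dy)

        scaled = set(self.problem.scaled_observables)
        obs_names = self.model.observable_names
        num = {o: 0.0 for o in scaled}
        den = {o: 0.0 for o in scaled}
        for cid in cids:
            rec = self._records[cid]
            yhat = sims[cid][0]
            for o in scaled:
                mask = np.array([obs_names[i] == o for i in rec.obs_idx])
                if mask.any():
                    w = rec.sigma[mask] ** 2
                    num[o] += float(np.sum(rec.y[mask] * yhat[mask] / w))
                    den[o] += float(np.sum(yhat[mask] ** 2 / w))
        scalings = {o: (num[o] / den[o] if den[o] > 0 else 1.0) for o in scaled}

        J = 0.0
        const = 0.0
        per_condition: dict[str, float] = {}
        grad = np.zeros(self.model.n_theta) if with_gradient else None
        for cid in cids:
            rec = self._records[cid]
            yhat, dy = sims[cid]
            s = np.array([scalings.get(obs_names[i], 1.0) for i in rec.obs_idx])
            r = (rec.y - s * yhat) / rec.sigma
            J_e = 0.5 * float(r @ r)
            per_condition[cid] = J_e
            J += J_e
            const += float(np.sum(np.log(2.0 * np.pi * rec.sigma ** 2)))
            if with_gradient:
                grad += ((s * yhat - rec.y) * s / rec.sigma ** 2) @ dy
        return ObjectiveValue(J, J + 0.5 * const, per_condition, grad,
                              STATUS_OK, n_sims, scalings)


def analytic_scaling_factors(
    measurements: np.ndarray,
    simulations: np.ndarray,
    sigmas: np.ndarray,
    groups: Sequence,
) -> dict:
    """J-minimizing multiplicative scales for observables modelled y = s*yhat.

    For each group g, s*_g = (sum ybar*yhat/sigma^2) / (sum yhat^2/sigma^2)
    over the group's records — the closed-form minimizer of the weighted
    least-squares cost in s.  Groups with sum yhat^2/sigma^2 = 0 get s*=1
    with a warning.
    """
    measurements = np.asarray(measurements, float)
    simulations = np.asarray(simulations, float)
    sigmas = np.asarray(sigmas, float)
    groups = np.asarray(groups)
    if not (len(measurements) == len(simulations) == len(sigmas) == len(groups)):
        raise ConfigurationError("scaling inputs must have equal length")
    if len(groups) == 0:
        raise ConfigurationError("empty scaling input")
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ConfigurationError(f"empty scaling group {g!r}")
        w = sigmas[mask] ** 2
        den = float(np.sum(simulations[mask] ** 2 / w))
        if den == 0.0:
            import warnings

            warnings.warn(f"scaling group {g!r} has all-zero simulations; s*=1")
            out[g] = 1.0
        else:
            out[g] = float(np.sum(measurements[mask] * simulations[mask] / w)) / den
    return out


def full_dataset_metrics(
    objective: NLLObjective,
    theta_log10: np.ndarray,
) -> dict:
    """Whole-dataset summary at one parameter vector.

    Evaluates every condition, applies analytic scaling factors for the
    problem's configured scaled observables, and returns the objective
    ``J_full``, the Pearson correlation between all measurements and
    simulations, and the (unweighted) RMSE.  On evaluation failure the
    metrics are NaN with ``valid=False``.
    """
    problem = objective.problem
    theta_lin = 10.0 ** np.asarray(theta_log10, dtype=float)
    cids = objective.condition_ids
    ybar_all, yhat_all, sigma_all, group_all = [], [], [], []
    obs_names = problem.model.observable_names
    n_sims = 0
    for cid in cids:
        rec = objective._records[cid]
        yhat, _, ok = objective._simulate(cid, theta_lin, False)
        n_sims += 1
        if not ok:
            return {"J_full": np.nan, "pearson_r": np.nan, "rmse": np.nan,
                    "valid": False, "n_sims": n_sims}
        ybar_all.append(rec.y)
        yhat_all.append(yhat)
        sigma_all.append(rec.sigma)
        group_all.append([obs_names[i] for i in rec.obs_idx])
    ybar = np.concatenate(ybar_all)
    yhat = np.concatenate(yhat_all)
    sigma = np.concatenate(sigma_all)
    group = np.concatenate(group_all)

    if problem.scaled_observables:
        in_scaled = np.isin(group, problem.scaled_observables)
        if in_scaled.any():
            s_map = analytic_scaling_factors(
                ybar[in_scaled], yhat[in_scaled], sigma[in_scaled], group[in_scaled])
            scale = np.array([s_map.get(g, 1.0) for g in group])
            yhat = yhat * scale

    resid = ybar - yhat
    J_full = 0.5 * float(np.sum((resid / sigma) ** 2))
    if np.std(ybar) == 0 or np.std(yhat) == 0:
        pearson = np.nan
    else:
        pearson = float(stats.pearsonr(ybar, yhat).statistic)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return {"J_full": J_full, "pearson_r": pearson, "rmse": rmse,
            "valid": True, "n_sims": n_sims}
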