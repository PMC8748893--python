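"""Condition-parameterized ODE models with trajectory, steady-state and
sensitivity computations.

A model is a vector field ``dx/dt = f(x, theta, u)`` with initial state
``x(0) = x0(theta, u)`` and observables ``y = h(x, theta)``.  ``theta`` holds
the estimated kinetic parameters (optimized on a log10 scale elsewhere in the
package), while ``u`` is a vector of known input parameters encoding one
experimental condition — a dose, expression scalings, drug potencies.  One
condition is one initial value problem; a calibration dataset is a collection
of many such conditions.

Models are usually built symbolically (:meth:`ODEModel.from_symbolic`), which
gives analytic Jacobians for stiff integration and exact forward sensitivity
equations.  Plain-callable models are supported for testing and prototyping,
with finite-difference Jacobians filled in automatically.

Integration failures are *values*, not exceptions: every simulation routine
returns a status flag so that optimization-level recovery logic (the rescue
interceptor) can decide what to do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import odeint

__all__ = [
    "ODEModel",
    "Condition",
    "Trajectory",
    "SensitivityResult",
    "simulate_condition",
    "simulate_steady_state",
    "compute_output_sensitivities",
    "STATUS_OK",
    "STATUS_FAILURE",
    "STATUS_NOT_CONVERGED",
]

LN10 = np.log(10.0)

STATUS_OK = "ok"
STATUS_FAILURE = "integration_failure"
STATUS_NOT_CONVERGED = "not_converged"

#: default per-step integration error tolerances
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-16
DEFAULT_MAX_STEPS = 10_000

#: horizon and acceptance tolerances for steady-state computation
STEADY_STATE_TIME = 1e8
STEADY_STATE_RTOL = 1e-8
STEADY_STATE_ATOL = 1e-16

_ODEINT_OK = "Integration successful."


@dataclass
class Condition:
    """One experimental condition: a vector of known input parameters.

    ``is_steady_state`` marks conditions whose readout is the equilibrium
    output of the model (one data point per condition) rather than a
    time course.
    """

    condition_id: str
    u: np.ndarray
    is_steady_state: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if not np.all(np.isfinite(self.u)):
            raise ValueError(f"condition {self.condition_id!r}: u must be finite")


@dataclass
class Trajectory:
    """Numerical solution at requested time points plus observables."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_x)
    observables: np.ndarray  # (n_times, n_obs)
    status: str = STATUS_OK

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@dataclass
class SensitivityResult:
    """Observable sensitivities d y / d theta-hat on the log10 parameter scale.

    ``dy_dtheta`` has shape (n_times, n_obs, n_theta).  The chain rule
    d theta / d theta-hat = theta * ln(10) is already applied, so these feed
    directly into gradients of objectives defined over log10 parameters.
    """

    dy_dtheta: np.ndarray
    trajectory: Trajectory
    status: str = STATUS_OK

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def _fd_jacobian(fun: Callable, x: np.ndarray, *args, rel_step: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of ``fun`` w.r.t. its first argument."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(fun(x, *args), dtype=float)
    jac = np.empty((f0.size, x.size))
    for j in range(x.size):
        h = rel_step * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += h
        xm[j] -= h
        jac[:, j] = (np.asarray(fun(xp, *args)) - np.asarray(fun(xm, *args))) / (2 * h)
    return jac


class ODEModel:
    """A condition-parameterized ODE model.

    Attributes
    ----------
    n_x, n_theta, n_u, n_obs
        State, estimated-parameter, input-parameter and observable counts.
    rhs, init, obs
        Callables ``rhs(t, x, theta, u) -> dx/dt``, ``init(theta, u) -> x0``,
        ``obs(x, theta) -> y``.
    """

    def __init__(
        self,
        *,
        state_names: Sequence[str],
        parameter_names: Sequence[str],
        input_names: Sequence[str],
        observable_names: Sequence[str],
        rhs: Callable,
        init: Callable,
        obs: Callable,
        rhs_jac_x: Callable | None = None,
        rhs_jac_theta: Callable | None = None,
        init_jac_theta: Callable | None = None,
        obs_jac_x: Callable | None = None,
        obs_jac_theta: Callable | None = None,
    ) -> None:
        if len(set(parameter_names)) != len(parameter_names):
            raise ValueError("duplicate parameter names")
        self.state_names = list(state_names)
        self.parameter_names = list(parameter_names)
        self.input_names = list(input_names)
        self.observable_names = list(observable_names)
        self.n_x = len(self.state_names)
        self.n_theta = len(self.parameter_names)
        self.n_u = len(self.input_names)
        self.n_obs = len(self.observable_names)
        self.rhs = rhs
        self.init = init
        self.obs = obs
        # Jacobians: analytic when built symbolically, FD fallback otherwise.
        self.rhs_jac_x = rhs_jac_x or (
            lambda t, x, th, u: _fd_jacobian(lambda xx: rhs(t, xx, th, u), x)
        )
        self.rhs_jac_theta = rhs_jac_theta or (
            lambda t, x, th, u: _fd_jacobian(lambda tt: rhs(t, x, tt, u), th)
        )
        self.init_jac_theta = init_jac_theta or (
            lambda th, u: _fd_jacobian(lambda tt: init(tt, u), th)
        )
        self.obs_jac_x = obs_jac_x or (
            lambda x, th: _fd_jacobian(lambda xx: obs(xx, th), x)
        )
        self.obs_jac_theta = obs_jac_theta or (
            lambda x, th: _fd_jacobian(lambda tt: obs(x, tt), th)
        )
        self.symbolic_spec: dict | None = None  # set by from_symbolic
        self._sym: dict | None = None
        self._aug_cache: tuple | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_symbolic(
        cls,
        *,
        states: dict[str, str],
        parameters: Sequence[str],
        inputs: Sequence[str],
        rates: dict[str, str],
        observables: dict[str, str],
    ) -> "ODEModel":
        """Build a model from arithmetic expression strings.

        Parameters
        ----------
        states
            Mapping state name -> initial-value expression (in parameters and
            inputs, or a number).
        rates
            Mapping state name -> d/dt expression (in states, parameters,
            inputs, and ``t``).
        observables
            Mapping observable name -> expression (in states and parameters).
        """
        state_names = list(states)
        parameter_names = list(parameters)
        input_names = list(inputs)
        observable_names = list(observables)
        missing = set(rates) ^ set(states)
        if missing:
            raise ValueError(f"states and rates must use the same names, mismatch: {missing}")

        t_sym = sp.Symbol("t")
        x_syms = sp.symbols([f"__x{i}" for i in range(len(state_names))])
        th_syms = sp.symbols([f"__p{i}" for i in range(len(parameter_names))]) if parameter_names else []
        u_syms = sp.symbols([f"__u{i}" for i in range(len(input_names))]) if input_names else []
        if len(state_names) == 1:
            x_syms = [x_syms] if not isinstance(x_syms, (list, tuple)) else list(x_syms)
        x_syms = list(np.atleast_1d(x_syms))
        th_syms = list(np.atleast_1d(th_syms))
        u_syms = list(np.atleast_1d(u_syms))

        local = {"t": t_sym}
        local.update(dict(zip(state_names, x_syms)))
        local.update(dict(zip(parameter_names, th_syms)))
        local.update(dict(zip(input_names, u_syms)))

        def parse(expr: str):
            return sp.sympify(expr, locals=local)

        f_exprs = sp.Matrix([parse(rates[name]) for name in state_names])
        x0_exprs = sp.Matrix([parse(str(states[name])) for name in state_names])
        h_exprs = sp.Matrix([parse(observables[name]) for name in observable_names])

        jx = f_exprs.jacobian(x_syms)
        jth = f_exprs.jacobian(th_syms) if th_syms else sp.zeros(len(state_names), 0)
        x0_jth = x0_exprs.jacobian(th_syms) if th_syms else sp.zeros(len(state_names), 0)
        hx = h_exprs.jacobian(x_syms)
        hth = h_exprs.jacobian(th_syms) if th_syms else sp.zeros(len(observable_names), 0)

        args = (t_sym, x_syms, th_syms, u_syms)
        f_l = sp.lambdify(args, list(f_exprs), "numpy")
        jx_l = sp.lambdify(args, jx, "numpy")
        jth_l = sp.lambdify(args, jth, "numpy")
        xu_args = (th_syms, u_syms)
        x0_l = sp.lambdify(xu_args, list(x0_exprs), "numpy")
        x0_jth_l = sp.lambdify(xu_args, x0_jth, "numpy")
        h_args = (x_syms, th_syms)
        h_l = sp.lambdify(h_args, list(h_exprs), "numpy")
        hx_l = sp.lambdify(h_args, hx, "numpy")
        hth_l = sp.lambdify(h_args, hth, "numpy")

        model = cls(
            state_names=state_names,
            parameter_names=parameter_names,
            input_names=input_names,
            observable_names=observable_names,
            rhs=lambda t, x, th, u: np.asarray(f_l(t, x, th, u), dtype=float),
            init=lambda th, u: np.asarray(x0_l(th, u), dtype=float),
            obs=lambda x, th: np.asarray(h_l(x, th), dtype=float),
            rhs_jac_x=lambda t, x, th, u: np.asarray(jx_l(t, x, th, u), dtype=float),
            rhs_jac_theta=lambda t, x, th, u: np.asarray(jth_l(t, x, th, u), dtype=float),
            init_jac_theta=lambda th, u: np.asarray(x0_jth_l(th, u), dtype=float),
            obs_jac_x=lambda x, th: np.asarray(hx_l(x, th), dtype=float),
            obs_jac_theta=lambda x, th: np.asarray(hth_l(x, th), dtype=float),
        )
        model.symbolic_spec = {
            "states": {k: str(v) for k, v in states.items()},
            "parameters": parameter_names,
            "inputs": input_names,
            "rates": dict(rates),
            "observables": dict(observables),
        }
        model._sym = {
            "t": t_sym, "x": x_syms, "theta": th_syms, "u": u_syms,
            "f": f_exprs, "jx": jx, "jth": jth,
        }
        return model

    # ------------------------------------------------------------------
    def _augmented_symbolic(self):
        """Lambdified forward-variational system, built once per model.

        The augmented state is z = [x, S[:,0], S[:,1], ...] with
        S = dx/dtheta stored column-major by parameter.  Generating the full
        right-hand side symbolically collapses each solver callback into a
        single compiled-expression call, which matters: the integrator
        evaluates it hundreds of times per solve.
        """
        if getattr(self, "_aug_cache", None) is not None:
            return self._aug_cache
        if getattr(self, "_sym", None) is None:
            return None
        sym = self._sym
        n_x, n_th = self.n_x, self.n_theta
        s_syms = list(sp.symbols([f"__s{j}_{i}" for j in range(n_th) for i in range(n_x)]))
        S = sp.Matrix(n_x, n_th, lambda i, j: s_syms[j * n_x + i])
        dS = sym["jx"] * S + sym["jth"]
        aug_exprs = list(sym["f"]) + [dS[i, j] for j in range(n_th) for i in range(n_x)]
        z_syms = list(sym["x"]) + s_syms
        args = (sym["t"], z_syms, sym["theta"], sym["u"])
        aug_rhs_l = sp.lambdify(args, aug_exprs, "numpy", cse=True)
        jx_l = sp.lambdify((sym["t"], sym["x"], sym["theta"], sym["u"]), sym["jx"], "numpy", cse=True)
        self._aug_cache = (aug_rhs_l, jx_l)
        return self._aug_cache

    def observe_trajectory(self, states: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return np.stack([self.obs(x, theta) for x in np.atleast_2d(states)])


# ----------------------------------------------------------------------
# simulation


def _integrate(rhs, jac, x0, times, rtol, atol, max_steps):
    """odeint wrapper returning (values_at_times, ok_flag).

    ``times`` must start at 0 (the model's initial time).  Failures of the
    adaptive integrator (step-limit, repeated error-test failure, non-finite
    output) are reported via the flag.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with np.errstate(all="ignore"):
                out, info = odeint(
                    rhs,
                    x0,
                    times,
                    Dfun=jac,
                    rtol=rtol,
                    atol=atol,
                    mxstep=max_steps,
                    full_output=True,
                    printmessg=False,
                    tfirst=True,
                )
    except Exception:
        return None, False
    if info.get("message") != _ODEINT_OK or not np.all(np.isfinite(out)):
        return out, False
    return out, True


def simulate_condition(
    model: ODEModel,
    theta: np.ndarray,
    condition: Condition,
    times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Trajectory:
    """Integrate one condition and evaluate observables at ``times``.

    ``theta`` is on the linear (model) scale.  Integration always starts at
    t=0 from ``model.init(theta, u)``; ``times`` must be non-empty and
    strictly increasing.  On solver failure the returned trajectory carries
    ``status="integration_failure"`` — no exception is raised.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    theta = np.asarray(theta, dtype=float)
    u = condition.u

    try:
        x0 = np.asarray(model.init(theta, u), dtype=float)
    except Exception:
        return Trajectory(times, np.full((times.size, model.n_x), np.nan),
                          np.full((times.size, model.n_obs), np.nan), STATUS_FAILURE)

    prepend = times[0] > 0.0
    tgrid = np.concatenate([[0.0], times]) if prepend else times
    out, ok = _integrate(
        lambda t, x: model.rhs(t, x, theta, u),
        lambda t, x: model.rhs_jac_x(t, x, theta, u),
        x0, tgrid, rtol, atol, max_steps,
    )
    if not ok or out is None:
        return Trajectory(times, np.full((times.size, model.n_x), np.nan),
                          np.full((times.size, model.n_obs), np.nan), STATUS_FAILURE)
    states = out[1:] if prepend else out
    try:
        with np.errstate(all="ignore"):
            observables = np.stack([model.obs(x, theta) for x in states])
    except Exception:
        return Trajectory(times, states, np.full((times.size, model.n_obs), np.nan), STATUS_FAILURE)
    if not np.all(np.isfinite(observables)):
        return Trajectory(times, states, observables, STATUS_FAILURE)
    return Trajectory(times, states, observables, STATUS_OK)


def steady_state_residual_norm(
    model: ODEModel,
    x: np.ndarray,
    theta: np.ndarray,
    u: np.ndarray,
    rtol: float = STEADY_STATE_RTOL,
    atol: float = STEADY_STATE_ATOL,
) -> float:
    """Tolerance-weighted RMS norm of the vector field at ``x``.

    sqrt(mean_i (f_i / (atol + rtol*|x_i|))^2); values <= 1 count as
    equilibrated, mirroring the weighted error norms of adaptive solvers.
    """
    f = np.asarray(model.rhs(0.0, x, theta, u), dtype=float)
    w = atol + rtol * np.abs(x)
    return float(np.sqrt(np.mean((f / w) ** 2)))


def simulate_steady_state(
    model: ODEModel,
    theta: np.ndarray,
    condition: Condition,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_steps: int = 10 * DEFAULT_MAX_STEPS,
    t_max: float = STEADY_STATE_TIME,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Equilibrate one condition by integrating to ``t_max`` (default 1e8).

    Returns ``(state, observables, status)``.  Convergence is accepted iff
    the tolerance-weighted RMS norm of the vector field is <= 1 both at the
    final state and at the half-horizon state; otherwise status is
    ``"not_converged"``.  The half-horizon check rejects the degenerate
    linear-drift ray x = f*t, for which the weighted norm at the full
    horizon sits exactly on the acceptance boundary.  Integration failures
    give ``"integration_failure"``.
    """
    theta = np.asarray(theta, dtype=float)
    u = condition.u
    try:
        x0 = np.asarray(model.init(theta, u), dtype=float)
    except Exception:
        nan_x = np.full(model.n_x, np.nan)
        return nan_x, np.full(model.n_obs, np.nan), STATUS_FAILURE
    out, ok = _integrate(
        lambda t, x: model.rhs(t, x, theta, u),
        lambda t, x: model.rhs_jac_x(t, x, theta, u),
        x0, np.array([0.0, t_max / 2, t_max]), rtol, atol, max_steps,
    )
    if not ok or out is None:
        nan_x = np.full(model.n_x, np.nan)
        return nan_x, np.full(model.n_obs, np.nan), STATUS_FAILURE
    x_ss = out[-1]
    if (steady_state_residual_norm(model, x_ss, theta, u) > 1.0
            or steady_state_residual_norm(model, out[-2], theta, u) > 1.0):
        return x_ss, np.full(model.n_obs, np.nan), STATUS_NOT_CONVERGED
    try:
        y = np.asarray(model.obs(x_ss, theta), dtype=float)
    except Exception:
        return x_ss, np.full(model.n_obs, np.nan), STATUS_FAILURE
    if not np.all(np.isfinite(y)):
        return x_ss, y, STATUS_FAILURE
    return x_ss, y, STATUS_OK


# ----------------------------------------------------------------------
# forward sensitivities


def _augmented_system(model: ODEModel, theta: np.ndarray, u: np.ndarray):
    """Forward variational system: states + state sensitivities S = dx/dtheta.

    The augmented state is z = [x, S[:,0], S[:,1], ...]; dS/dt = Jx S + Jth.
    The supplied Jacobian is the exact block-lower-triangular structure's
    diagonal, kron(I, Jx), which is what the implicit solver needs for stable
    Newton iterations.
    """
    n_x, n_th = model.n_x, model.n_theta
    n_aug = n_x * (1 + n_th)

    aug = model._augmented_symbolic() if hasattr(model, "_augmented_symbolic") else None
    if aug is not None:
        aug_rhs_l, jx_l = aug
        jac_buf = np.zeros((n_aug, n_aug))

        def rhs(t, z):
            return np.asarray(aug_rhs_l(t, z, theta, u), dtype=float)

        def jac(t, z):
            jx = np.asarray(jx_l(t, z[:n_x], theta, u), dtype=float)
            for b in range(1 + n_th):
                jac_buf[b * n_x:(b + 1) * n_x, b * n_x:(b + 1) * n_x] = jx
            return jac_buf

        return rhs, jac

    def rhs(t, z):
        x = z[:n_x]
        S = z[n_x:].reshape(n_th, n_x).T
        f = model.rhs(t, x, theta, u)
        jx = model.rhs_jac_x(t, x, theta, u)
        jth = model.rhs_jac_theta(t, x, theta, u)
        dS = jx @ S + jth
        out = np.empty(n_aug)
        out[:n_x] = f
        out[n_x:] = dS.T.ravel()
        return out

    jac_buf = np.zeros((n_aug, n_aug))

    def jac(t, z):
        jx = model.rhs_jac_x(t, z[:n_x], theta, u)
        for b in range(1 + n_th):
            jac_buf[b * n_x:(b + 1) * n_x, b * n_x:(b + 1) * n_x] = jx
        return jac_buf

    return rhs, jac


def compute_output_sensitivities(
    model: ODEModel,
    theta: np.ndarray,
    condition: Condition,
    times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> SensitivityResult:
    """Observable sensitivities on the log10 parameter scale, via the forward
    variational system (an augmented ODE integrated alongside the states).

    ``theta`` is linear-scale; the returned derivatives are w.r.t.
    theta-hat = log10(theta), i.e. chain-ruled by theta * ln(10).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)) or np.any(theta <= 0):
        raise ValueError("theta must be finite and positive for log10-scale sensitivities")
    u = condition.u
    n_x, n_th, n_obs = model.n_x, model.n_theta, model.n_obs

    def _fail():
        traj = Trajectory(times, np.full((times.size, n_x), np.nan),
                          np.full((times.size, n_obs), np.nan), STATUS_FAILURE)
        return SensitivityResult(np.full((times.size, n_obs, n_th), np.nan), traj, STATUS_FAILURE)

    try:
        x0 = np.asarray(model.init(theta, u), dtype=float)
        S0 = np.asarray(model.init_jac_theta(theta, u), dtype=float)
    except Exception:
        return _fail()

    z0 = np.concatenate([x0, S0.T.ravel()])
    rhs, jac = _augmented_system(model, theta, u)
    prepend = times[0] > 0.0
    tgrid = np.concatenate([[0.0], times]) if prepend else times
    out, ok = _integrate(rhs, jac, z0, tgrid, rtol, atol, max_steps)
    if not ok or out is None:
        return _fail()
    z = out[1:] if prepend else out
    states = z[:, :n_x]

    observables = np.empty((times.size, n_obs))
    dy = np.empty((times.size, n_obs, n_th))
    chain = theta * LN10  # d theta / d log10(theta)
    try:
        with np.errstate(all="ignore"):
            for k in range(times.size):
                x = states[k]
                S = z[k, n_x:].reshape(n_th, n_x).T
                observables[k] = model.obs(x, theta)
                hx = model.obs_jac_x(x, theta)
                hth = model.obs_jac_theta(x, theta)
                dy[k] = (hx @ S + hth) * chain
    except Exception:
        return _fail()
    if not (np.all(np.isfinite(observables)) and np.all(np.isfinite(dy))):
        return _fail()
    traj = Trajectory(times, states, observables, STATUS_OK)
    return SensitivityResult(dy, traj, STATUS_OK)


def steady_state_sensitivities(
    model: ODEModel,
    theta: np.ndarray,
    condition: Condition,
    x_ss: np.ndarray,
) -> np.ndarray | None:
    """Observable sensitivities at a steady state, on the log10 scale.

    Uses the implicit-function theorem: dx*/dtheta = -Jx^{-1} Jth, which is
    exact for a locally unique equilibrium.  Returns None when Jx is singular
    (e.g. models with conservation laws).
    """
    theta = np.asarray(theta, dtype=float)
    u = condition.u
    jx = model.rhs_jac_x(0.0, x_ss, theta, u)
    jth = model.rhs_jac_theta(0.0, x_ss, theta, u)
    try:
        S = np.linalg.solve(jx, -jth)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(S)):
        return None
    hx = model.obs_jac_x(x_ss, theta)
    hth = model.obs_jac_theta(x_ss, theta)
    return (hx @ S + hth) * (theta * LN10)
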