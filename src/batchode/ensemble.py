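"""Parameter ensembles harvested from optimization histories.

Mini-batch optimization visits many near-optimal parameter vectors on its
way; collecting them yields an inexpensive ensemble for prediction spread
and parameter-space characterization.  The construction runs in four
stages: (1) smooth each run's noisy mini-batch objective trace by a
centered one-epoch moving average; (2) set a cutoff at the best smoothed
RMSE times 1.10; (3) admit every visited parameter vector whose smoothed
value beats the cutoff; (4) thin to at most 50 members per (run, epoch).

The RMSE <-> objective conversion uses the weighted residual RMS
RMSE = sqrt(2 J / N) with N the total record count, which reduces to the
plain RMSE under a shared unit noise SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import compute_output_sensitivities, simulate_condition, simulate_steady_state

__all__ = [
    "ParameterEnsemble",
    "smooth_history",
    "build_ensemble",
    "ensemble_predict",
    "top_k_ensemble",
    "covariance_spectrum",
    "output_sensitivity_svd",
]

DEFAULT_CUTOFF_TOLERANCE = 0.10
DEFAULT_THINNING_CAP = 50


@dataclass
class ParameterEnsemble:
    """Cutoff-filtered, thinned parameter vectors with provenance.

    ``members`` is (n_members x n_theta) on the log10 scale; ``provenance``
    holds (start_id, step) per member.
    """

    members: np.ndarray
    provenance: list[tuple[int, int]]
    cutoff: float
    thinning_cap: int
    smoothing_window: int
    smoothed_values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.members)


def smooth_history(j_trace: np.ndarray, steps_per_epoch: int) -> np.ndarray:
    """Centered moving average over up to one epoch of steps.

    For each step the window extends half an epoch before and after, where
    possible; at the trace ends it is truncated.  A constant trace is
    returned unchanged; a single-step trace is its own smoothing.
    """
    j = np.asarray(j_trace, dtype=float)
    if j.size == 0:
        return j
    half = max(steps_per_epoch // 2, 0)
    csum = np.concatenate([[0.0], np.cumsum(j)])
    out = np.empty_like(j)
    for i in range(j.size):
        lo = max(0, i - half)
        hi = min(j.size, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def build_ensemble(
    histories,
    n_records: int,
    cutoff_tolerance: float = DEFAULT_CUTOFF_TOLERANCE,
    thinning_cap: int | None = DEFAULT_THINNING_CAP,
    cutoff: float | None = None,
) -> ParameterEnsemble:
    """Build a parameter ensemble from mini-batch optimization histories.

    The per-step mini-batch objective is converted to a full-dataset
    equivalent by multiplying with (n_records / batch records); since
    batches are drawn uniformly this is the natural unbiased rescaling.
    With ``cutoff=None`` the cutoff is the best smoothed RMSE across all
    histories times (1 + cutoff_tolerance).  ``thinning_cap=None`` disables
    thinning.
    """
    smoothed_all = []
    for h in histories:
        spe = max(h.steps_per_epoch, 1)
        j = np.asarray(h.j_trace, dtype=float)
        # scale the mini-batch objective to a full-dataset equivalent:
        # batches are uniform (up to the remainder), so J_full ~= J_batch * spe
        j_full_equiv = j * spe
        smoothed_all.append(smooth_history(j_full_equiv, spe))

    rmse_all = [np.sqrt(2.0 * np.maximum(s, 0.0) / n_records) for s in smoothed_all]
    finite_best = [np.nanmin(r) for r in rmse_all if r.size and np.any(np.isfinite(r))]
    if cutoff is None:
        if not finite_best:
            warnings.warn("no finite smoothed values; ensemble is empty")
            return ParameterEnsemble(np.empty((0, 0)), [], np.nan,
                                     thinning_cap or 0, 0)
        cutoff = float(min(finite_best) * (1.0 + cutoff_tolerance))

    members, prov, vals = [], [], []
    for h, rmse in zip(histories, rmse_all):
        if not rmse.size:
            continue
        spe = max(h.steps_per_epoch, 1)
        admitted = np.flatnonzero(rmse <= cutoff)
        if admitted.size == 0:
            continue
        epochs = np.asarray(h.epochs, dtype=int)[admitted]
        for ep in np.unique(epochs):
            idx = admitted[epochs == ep]
            if thinning_cap is not None and idx.size > thinning_cap:
                # uniform stride down to the cap
                sel = idx[np.linspace(0, idx.size - 1, thinning_cap).round().astype(int)]
            else:
                sel = idx
            for i in sel:
                members.append(h.theta_trace[i])
                prov.append((h.start_id, int(h.steps[i])))
                vals.append(rmse[i])

    if not members:
        warnings.warn("ensemble admission is empty")
        return ParameterEnsemble(np.empty((0, 0)), [], float(cutoff),
                                 thinning_cap or 0, 0)
    spe0 = max(histories[0].steps_per_epoch, 1)
    return ParameterEnsemble(np.array(members), prov, float(cutoff),
                             thinning_cap if thinning_cap is not None else -1,
                             spe0, np.array(vals))


def top_k_ensemble(histories, k: int = 10) -> np.ndarray:
    """Final parameter vectors of the k best runs (log10 scale)."""
    finals = np.array([h.final_J for h in histories], dtype=float)
    finals = np.where(np.isfinite(finals), finals, np.inf)
    order = np.argsort(finals, kind="stable")[:k]
    return np.array([histories[i].final_theta for i in order])


def ensemble_predict(
    problem,
    thetas_log10: np.ndarray,
    condition_ids=None,
    times=None,
) -> dict:
    """Per-condition mean and SD of model outputs across ensemble members.

    Simulates every member for the requested conditions (time-course on
    ``times`` or the problem's measurement grid; steady-state conditions at
    equilibrium) and returns element-wise mean and SD over members, computed
    over the members as listed (duplicates count).  Members that fail to
    simulate are excluded and counted in ``n_failed``.
    """
    thetas_log10 = np.atleast_2d(np.asarray(thetas_log10, dtype=float))
    if thetas_log10.shape[0] < 1:
        raise ValueError("ensemble must be non-empty")
    if condition_ids is None:
        condition_ids = sorted(problem.conditions)
    outputs = {cid: [] for cid in condition_ids}
    n_failed = 0
    for theta in thetas_log10:
        theta_lin = 10.0 ** theta
        ok = True
        member_out = {}
        for cid in condition_ids:
            cond = problem.conditions[cid]
            if cond.is_steady_state:
                _, y, status = simulate_steady_state(problem.model, theta_lin, cond,
                                                     rtol=1e-6, atol=1e-12)
                if status != "ok":
                    ok = False
                    break
                member_out[cid] = np.asarray(y)
            else:
                tt = times
                if tt is None:
                    m = problem.measurements
                    tt = np.unique(m.loc[m["simulationConditionId"] == cid, "time"].to_numpy(float))
                traj = simulate_condition(problem.model, theta_lin, cond, tt,
                                          rtol=1e-6, atol=1e-12)
                if not traj.ok:
                    ok = False
                    break
                member_out[cid] = traj.observables
        if ok:
            for cid, y in member_out.items():
                outputs[cid].append(y)
        else:
            n_failed += 1

    result = {"n_failed": n_failed, "n_members": thetas_log10.shape[0], "mean": {}, "sd": {}}
    for cid in condition_ids:
        if outputs[cid]:
            stack = np.stack(outputs[cid])
            result["mean"][cid] = stack.mean(axis=0)
            result["sd"][cid] = stack.std(axis=0)
    return result


def covariance_spectrum(members: np.ndarray) -> dict:
    """Eigen-decomposition of the ensemble covariance matrix.

    Returns eigenvalues in descending order, explained-variance fractions
    and their cumulative curve.  The eigenvalue sum equals the total
    variance (trace identity).
    """
    members = np.asarray(members, dtype=float)
    if members.ndim != 2 or members.shape[0] < 2:
        raise ValueError("need at least two ensemble members")
    cov = np.cov(members, rowvar=False)
    cov = np.atleast_2d(cov)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.maximum(eigvals, 0.0)
    total = eigvals.sum()
    frac = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return {
        "eigenvalues": eigvals,
        "explained_variance": frac,
        "cumulative_explained_variance": np.cumsum(frac),
        "total_variance": float(total),
    }


def output_sensitivity_svd(
    problem,
    thetas_log10: np.ndarray,
    condition_ids=None,
    rtol: float = 1e-6,
    atol: float = 1e-12,
    rank_rtol: float | None = None,
) -> dict:
    """SVD of the stacked output-sensitivity matrix at a set of parameters.

    For each parameter vector (typically the top-k finals) and condition,
    the observable sensitivities d y / d log10(theta) at the measurement
    times are stacked into one matrix of shape
    (sum of outputs x n_theta); its singular values measure how many
    parameter-space directions the outputs are informative about.  The
    numerical rank counts singular values above
    max(matrix dims) * eps * largest SV by default; since the entries are
    themselves only accurate to the integration tolerance, pass
    ``rank_rtol`` (e.g. the integration rtol) to count the rank at the
    accuracy of the computed sensitivities instead.  Parameter vectors
    whose simulation fails are excluded and reported.
    """
    thetas_log10 = np.atleast_2d(np.asarray(thetas_log10, dtype=float))
    if condition_ids is None:
        condition_ids = sorted(problem.conditions)
    m = problem.measurements
    blocks = []
    n_failed = 0
    for theta in thetas_log10:
        theta_lin = 10.0 ** theta
        ok = True
        theta_blocks = []
        for cid in condition_ids:
            cond = problem.conditions[cid]
            tt = np.unique(m.loc[m["simulationConditionId"] == cid, "time"].to_numpy(float))
            tt = tt[np.isfinite(tt)]
            if cond.is_steady_state or tt.size == 0:
                from .models import STEADY_STATE_TIME

                tt = np.array([STEADY_STATE_TIME])
            sens = compute_output_sensitivities(problem.model, theta_lin, cond, tt,
                                                rtol=rtol, atol=atol)
            if not sens.ok:
                ok = False
                break
            theta_blocks.append(sens.dy_dtheta.reshape(-1, problem.model.n_theta))
        if ok:
            blocks.extend(theta_blocks)
        else:
            n_failed += 1
    if not blocks:
        raise RuntimeError("no parameter vector could be simulated")
    matrix = np.vstack(blocks)
    sv = np.linalg.svd(matrix, compute_uv=False)
    rel = rank_rtol if rank_rtol is not None else max(matrix.shape) * np.finfo(float).eps
    tol = rel * (sv[0] if sv.size else 0.0)
    return {
        "singular_values": sv,
        "numerical_rank": int(np.sum(sv > tol)),
        "rank_tolerance": float(tol),
        "matrix_shape": matrix.shape,
        "n_failed": n_failed,
    }
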