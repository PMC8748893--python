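"""Problem and results I/O.

Problems are exchanged as a directory of PEtab-flavoured TSV tables plus a
YAML model definition and an index file:

    problem.yaml       index: file names, scaled observables
    model.yaml         states / parameters / inputs / rates / observables
    conditions.tsv     conditionId, steadyState, one column per input
    measurements.tsv   observableId, simulationConditionId, time,
                       measurement, noiseParameters
    parameters.tsv     parameterId, lowerBound, upperBound, parameterScale,
                       nominalValue, estimate
    ground_truth.json  optional true parameters for synthetic problems

Optimization results go to an HDF5 store (one group per start with the
parameter / objective / learning-rate traces and the event log) plus a TSV
summary of final metrics, one row per start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .models import Condition, ODEModel
from .objective import (
    CalibrationProblem,
    ConfigurationError,
    MEASUREMENT_COLUMNS,
    ParameterSpace,
)
from .optimizers import MultiStartResult, OptimizationHistory

__all__ = [
    "RunConfig",
    "load_problem",
    "save_problem",
    "write_results",
    "read_results",
]


@dataclass
class RunConfig:
    """Run configuration for the `optimize` command."""

    problem_dir: str
    algorithm: str = "adam-balanced"
    schedule: str = "schedule_2"
    batch_size: int = 30
    epochs: int = 50
    n_starts: int = 100
    seed: int = 0
    rescue: bool = True
    line_search: bool = False
    output_dir: str = "results"
    wall_time_limit_s: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)


def save_problem(problem: CalibrationProblem, out_dir: str | Path) -> Path:
    """Write a problem bundle as TSV/YAML/JSON files; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = problem.model
    if model.symbolic_spec is None:
        raise ConfigurationError("only symbolically defined models can be serialized")
    with open(out / "model.yaml", "w") as fh:
        yaml.safe_dump(model.symbolic_spec, fh, sort_keys=False)

    cond_rows = []
    for cid in sorted(problem.conditions):
        c = problem.conditions[cid]
        row = {"conditionId": cid, "steadyState": int(c.is_steady_state)}
        row.update({name: c.u[i] for i, name in enumerate(model.input_names)})
        cond_rows.append(row)
    pd.DataFrame(cond_rows).to_csv(out / "conditions.tsv", sep="\t", index=False)

    problem.measurements.to_csv(out / "measurements.tsv", sep="\t", index=False)

    space = problem.parameter_space
    pd.DataFrame({
        "parameterId": space.names,
        "lowerBound": 10.0 ** space.lower,
        "upperBound": 10.0 ** space.upper,
        "parameterScale": "log10",
        "nominalValue": (problem.theta_true if problem.theta_true is not None
                         else 10.0 ** ((space.lower + space.upper) / 2)),
        "estimate": 1,
    }).to_csv(out / "parameters.tsv", sep="\t", index=False)

    if problem.theta_true is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump({"theta_true": list(map(float, problem.theta_true)),
                       "parameter_names": space.names}, fh, indent=1)

    index = {
        "model": "model.yaml",
        "conditions": "conditions.tsv",
        "measurements": "measurements.tsv",
        "parameters": "parameters.tsv",
        "scaled_observables": problem.scaled_observables,
    }
    with open(out / "problem.yaml", "w") as fh:
        yaml.safe_dump(index, fh, sort_keys=False)
    return out


def load_problem(path: str | Path) -> CalibrationProblem:
    """Load a problem bundle from a directory (or its problem.yaml)."""
    path = Path(path)
    if path.is_file():
        path = path.parent
    index_file = path / "problem.yaml"
    if not index_file.exists():
        raise ConfigurationError(f"no problem.yaml under {path}")
    with open(index_file) as fh:
        index = yaml.safe_load(fh)

    with open(path / index["model"]) as fh:
        spec = yaml.safe_load(fh)
    model = ODEModel.from_symbolic(
        states=spec["states"], parameters=spec["parameters"],
        inputs=spec["inputs"], rates=spec["rates"],
        observables=spec["observables"])

    cond_df = pd.read_csv(path / index["conditions"], sep="\t",
                          float_precision="round_trip")
    if "conditionId" not in cond_df.columns:
        raise ConfigurationError("conditions.tsv must have a conditionId column")
    missing_inputs = [n for n in model.input_names if n not in cond_df.columns]
    if missing_inputs:
        raise ConfigurationError(f"conditions.tsv missing input columns: {missing_inputs}")
    conditions = {}
    for _, row in cond_df.iterrows():
        cid = str(row["conditionId"])
        u = np.array([float(row[n]) for n in model.input_names])
        conditions[cid] = Condition(cid, u, bool(row.get("steadyState", 0)))

    measurements = pd.read_csv(path / index["measurements"], sep="\t",
                               float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ConfigurationError(f"measurements.tsv missing columns: {missing}")

    par_df = pd.read_csv(path / index["parameters"], sep="\t")
    order = {p: i for i, p in enumerate(model.parameter_names)}
    unknown = set(par_df["parameterId"]) - set(order)
    if unknown:
        raise ConfigurationError(f"parameters.tsv has unknown parameters: {sorted(unknown)}")
    par_df = par_df.sort_values("parameterId", key=lambda s: s.map(order))
    space = ParameterSpace(
        names=list(par_df["parameterId"]),
        lower=np.log10(par_df["lowerBound"].to_numpy(float)),
        upper=np.log10(par_df["upperBound"].to_numpy(float)),
    )

    theta_true = None
    gt = path / "ground_truth.json"
    if gt.exists():
        with open(gt) as fh:
            theta_true = np.array(json.load(fh)["theta_true"], dtype=float)

    return CalibrationProblem(
        model=model, conditions=conditions, measurements=measurements,
        parameter_space=space, theta_true=theta_true,
        scaled_observables=list(index.get("scaled_observables", [])))


# ----------------------------------------------------------------------
# results store


def write_results(result: MultiStartResult, out_dir: str | Path) -> tuple[Path, Path]:
    """Persist a multi-start result: HDF5 history store + TSV summary.

    Returns (store path, summary path).  The summary has one row per start
    with the final objective, correlation, termination reason and the
    simulation-count cost proxy.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store_path = out / "histories.h5"
    with h5py.File(store_path, "w") as fh:
        fh.attrs["n_starts"] = len(result.histories)
        fh.create_dataset("starts", data=result.starts)
        for h in result.histories:
            g = fh.create_group(f"start_{h.start_id:04d}")
            g.attrs["algorithm"] = h.algorithm
            g.attrs["termination"] = h.termination
            g.attrs["n_condition_sims"] = h.n_condition_sims
            g.attrs["steps_per_epoch"] = h.steps_per_epoch
            g.attrs["start_id"] = h.start_id
            g.attrs["wall_time_s"] = h.wall_time_s
            g.create_dataset("theta_trace", data=np.array(h.theta_trace))
            g.create_dataset("j_trace", data=np.array(h.j_trace))
            g.create_dataset("eta_trace", data=np.array(h.eta_trace))
            g.create_dataset("step_scale_trace", data=np.array(h.step_scale_trace))
            g.create_dataset("sim_count_trace", data=np.array(h.sim_count_trace))
            g.create_dataset("steps", data=np.array(h.steps, dtype=int))
            g.create_dataset("epochs", data=np.array(h.epochs, dtype=int))
            if h.full_j_per_epoch:
                g.create_dataset("full_j_per_epoch", data=np.array(h.full_j_per_epoch))
            if h.final_theta is not None:
                g.create_dataset("final_theta", data=h.final_theta)
            g.attrs["events"] = json.dumps([list(e) for e in h.events])
            if h.final_metrics is not None:
                g.attrs["final_metrics"] = json.dumps(
                    {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                     for k, v in h.final_metrics.items()})

    rows = []
    for h in result.histories:
        fm = h.final_metrics or {}
        rows.append({
            "start": h.start_id,
            "final_J": fm.get("J_full", np.nan),
            "pearson_r": fm.get("pearson_r", np.nan),
            "rmse": fm.get("rmse", np.nan),
            "termination": h.termination,
            "n_condition_sims": h.n_condition_sims,
        })
    summary_path = out / "summary.tsv"
    pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False,
                              float_format="%.10g")
    return store_path, summary_path


def read_results(store_path: str | Path) -> MultiStartResult:
    """Reconstruct histories from an HDF5 store written by write_results."""
    histories = []
    with h5py.File(store_path, "r") as fh:
        starts = fh["starts"][()]
        for key in sorted(k for k in fh.keys() if k.startswith("start_")):
            g = fh[key]
            h = OptimizationHistory(
                start_id=int(g.attrs["start_id"]),
                algorithm=str(g.attrs["algorithm"]),
                termination=str(g.attrs["termination"]),
                steps_per_epoch=int(g.attrs["steps_per_epoch"]),
            )
            h.n_condition_sims = int(g.attrs["n_condition_sims"])
            h.wall_time_s = float(g.attrs.get("wall_time_s", 0.0))
            h.theta_trace = [np.array(t) for t in g["theta_trace"][()]]
            h.j_trace = list(map(float, g["j_trace"][()]))
            h.eta_trace = list(map(float, g["eta_trace"][()]))
            h.step_scale_trace = list(map(float, g["step_scale_trace"][()]))
            h.sim_count_trace = list(map(int, g["sim_count_trace"][()]))
            h.steps = list(map(int, g["steps"][()]))
            h.epochs = list(map(int, g["epochs"][()]))
            if "full_j_per_epoch" in g:
                h.full_j_per_epoch = list(map(float, g["full_j_per_epoch"][()]))
            if "final_theta" in g:
                h.final_theta = g["final_theta"][()]
            h.events = [tuple(e) for e in json.loads(g.attrs["events"])]
            if "final_metrics" in g.attrs:
                fm = json.loads(g.attrs["final_metrics"])
                h.final_metrics = {k: (np.nan if v is None else v) for k, v in fm.items()}
            histories.append(h)
    return MultiStartResult(histories=histories, starts=starts)
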