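"""Synthetic calibration problems with known ground truth.

The generator emulates the structure of published many-condition calibration
benchmarks: a signaling cascade of phosphorylation cycles simulated under
hundreds to thousands of experimental conditions that differ only in their
input parameters (stimulus dose and per-layer protein expression scalings),
observed as noisy time courses.  Three presets mirror the benchmark scales

    fujita_like     600 conditions x 1 observable x 10 time points =  6000 records
    bachmann_like  1200 conditions x 1 observable x 10 time points = 12000 records
    lucarelli_like 1500 conditions x 4 observables x 10 time points = 60000 records

and a fourth (``viability_like``) emulates a steady-state dose-response
application: cell line x drug x dose conditions with a single equilibrium
"viability" readout per condition and binary responder labels (viability
reduced by more than 50% relative to the untreated cell line).

Additive Gaussian noise uses a per-observable SD of 10% of that observable's
dynamic range across the noise-free dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import Condition, ODEModel, simulate_condition, simulate_steady_state
from .objective import CalibrationProblem, ParameterSpace

__all__ = [
    "CascadeSpec",
    "GeneratorPreset",
    "PRESETS",
    "get_preset",
    "build_cascade_model",
    "sample_conditions",
    "generate_dataset",
    "generate_viability_dataset",
    "default_theta_true",
]

#: basal stimulus driving layer 1 even at dose 0
BASAL_STIMULUS = 0.1
#: noise SD as a fraction of each observable's dynamic range
NOISE_FRACTION = 0.10

_KACT_TRUE = [1.5, 0.8, 1.2, 0.6, 1.0, 0.9]
_KDEACT_TRUE = [0.6, 0.4, 0.5, 0.3, 0.45, 0.35]


@dataclass
class CascadeSpec:
    """Structure of the phosphorylation-cascade fixture model.

    Each layer is a cycle between an inactive and an active form; layer 1 is
    activated by the stimulus dose (plus a small basal drive), downstream
    layers by the active species of the layer above.  ``with_turnover`` adds
    basal synthesis and degradation so the system has no conservation laws
    and a unique, parameter-sensitive steady state (used by the viability
    preset).
    """

    n_layers: int = 2
    with_turnover: bool = False
    with_drug: bool = False
    k_syn: float = 0.5
    k_deg: float = 0.2

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


def build_cascade_model(spec: CascadeSpec) -> ODEModel:
    """Build the cascade ODE model from a :class:`CascadeSpec`.

    States: (inactive_l, active_l) per layer.  Estimated parameters: the
    activation and deactivation rate constants k_act_l, k_deact_l.  Inputs:
    the stimulus dose, optionally per-layer drug potencies, and per-layer
    expression scalings (total protein per layer).
    """
    L = spec.n_layers
    states: dict[str, str] = {}
    rates: dict[str, str] = {}
    params: list[str] = []
    inputs = ["dose"]
    if spec.with_drug:
        inputs += [f"pot_{l}" for l in range(1, L + 1)]
    inputs += [f"s_{l}" for l in range(1, L + 1)]

    for l in range(1, L + 1):
        ka, kd = f"k_act_{l}", f"k_deact_{l}"
        params += [ka, kd]
        I, A = f"inact_{l}", f"act_{l}"
        if l == 1:
            # time-course presets: "dose" is the stimulus; drug presets: a
            # constant growth signal drives the cascade and "dose" is the
            # drug concentration, acting only through the inhibition terms
            drive = "1.0" if spec.with_drug else f"(dose + {BASAL_STIMULUS})"
        else:
            drive = f"act_{l - 1}"
        act = f"{ka} * {drive} * {I}"
        if spec.with_drug:
            act = f"({act}) / (1 + pot_{l} * dose)"
        deact = f"{kd} * {A}"
        if spec.with_turnover:
            states[I] = f"s_{l} * {spec.k_syn} / {spec.k_deg}"
            states[A] = "0"
            rates[I] = f"{spec.k_syn} * s_{l} - {spec.k_deg} * {I} - ({act}) + {deact}"
            rates[A] = f"({act}) - {deact} - {spec.k_deg} * {A}"
        else:
            states[I] = f"s_{l}"
            states[A] = "0"
            rates[I] = f"-({act}) + {deact}"
            rates[A] = f"({act}) - {deact}"

    observables = {f"obs_act_{l}": f"act_{l}" for l in range(1, L + 1)}
    return ODEModel.from_symbolic(
        states=states, parameters=params, inputs=inputs,
        rates=rates, observables=observables,
    )


@dataclass
class GeneratorPreset:
    """A named benchmark-problem recipe."""

    name: str
    n_layers: int
    n_conditions: int
    observed_layers: list[int]
    # log-spaced grid covering the fast rise phase and the plateau: early
    # samples separate activation from deactivation rates (identifiability)
    times: np.ndarray = field(default_factory=lambda: np.geomspace(0.2, 15.0, 10))
    noise_fraction: float = NOISE_FRACTION
    dose_grid: np.ndarray = field(default_factory=lambda: np.logspace(-1.0, 1.0, 12))
    scaling_range: tuple[float, float] = (0.2, 5.0)
    seed: int = 0

    @property
    def n_records(self) -> int:
        return self.n_conditions * len(self.observed_layers) * len(self.times)


PRESETS: dict[str, GeneratorPreset] = {
    "fujita_like": GeneratorPreset("fujita_like", n_layers=2, n_conditions=600,
                                   observed_layers=[2]),
    "bachmann_like": GeneratorPreset("bachmann_like", n_layers=3, n_conditions=1200,
                                     observed_layers=[3]),
    "lucarelli_like": GeneratorPreset("lucarelli_like", n_layers=4, n_conditions=1500,
                                      observed_layers=[1, 2, 3, 4]),
}


def get_preset(name: str, n_conditions: int | None = None, seed: int | None = None) -> GeneratorPreset:
    """Look up a preset, optionally at reduced scale / different seed."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)} or viability_like")
    p = PRESETS[name]
    changes = {}
    if n_conditions is not None:
        changes["n_conditions"] = n_conditions
    if seed is not None:
        changes["seed"] = seed
    return replace(p, **changes) if changes else p


def default_theta_true(n_layers: int) -> np.ndarray:
    """Ground-truth rate constants (linear scale): alternating k_act, k_deact."""
    out = []
    for l in range(n_layers):
        out += [_KACT_TRUE[l], _KDEACT_TRUE[l]]
    return np.array(out)


def sample_conditions(preset: GeneratorPreset, rng: np.random.Generator) -> list[Condition]:
    """Draw the preset's condition table: dose from the log-spaced grid
    (cycled) combined with per-layer expression scalings drawn log-uniformly
    from the scaling range.  Deterministic under the generator's state."""
    lo, hi = np.log(preset.scaling_range[0]), np.log(preset.scaling_range[1])
    width = len(str(preset.n_conditions - 1))
    conditions = []
    for e in range(preset.n_conditions):
        dose = preset.dose_grid[e % len(preset.dose_grid)]
        scalings = np.exp(rng.uniform(lo, hi, size=preset.n_layers))
        conditions.append(Condition(f"c{e:0{width}d}", np.concatenate([[dose], scalings])))
    return conditions


def generate_dataset(
    preset: GeneratorPreset | str,
    theta_true: np.ndarray | None = None,
    seed: int | None = None,
    noise: bool = True,
) -> CalibrationProblem:
    """Simulate the preset's conditions at the true parameters and emit a
    calibration problem with a noisy measurement table.

    Noise is additive Gaussian with a per-observable SD of
    ``preset.noise_fraction`` times that observable's dynamic range over the
    noise-free dataset; with ``noise=False`` the measurements equal the
    simulations exactly (so J(theta_true) = 0).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if seed is None:
        seed = preset.seed
    rng = np.random.default_rng(seed)

    model = build_cascade_model(CascadeSpec(n_layers=preset.n_layers))
    theta_true = default_theta_true(preset.n_layers) if theta_true is None else np.asarray(theta_true, float)
    space = ParameterSpace(list(model.parameter_names))
    if not space.contains(np.log10(theta_true)):
        raise ValueError("theta_true outside the parameter box")

    conditions = sample_conditions(preset, rng)
    obs_names = [f"obs_act_{l}" for l in preset.observed_layers]
    obs_idx = [model.observable_names.index(o) for o in obs_names]

    sims = np.empty((len(conditions), len(preset.times), len(obs_idx)))
    for k, cond in enumerate(conditions):
        traj = simulate_condition(model, theta_true, cond, preset.times)
        if not traj.ok:
            raise RuntimeError(f"simulation failed at theta_true for condition {cond.condition_id}")
        sims[k] = traj.observables[:, obs_idx]

    # per-observable noise SD from the dynamic range of the clean data
    rng_per_obs = sims.max(axis=(0, 1)) - sims.min(axis=(0, 1))
    sigma = np.maximum(preset.noise_fraction * rng_per_obs, 1e-12)

    rows = []
    for k, cond in enumerate(conditions):
        for j, oname in enumerate(obs_names):
            for i, t in enumerate(preset.times):
                y = sims[k, i, j]
                if noise:
                    y = y + rng.normal(0.0, sigma[j])
                rows.append((oname, cond.condition_id, float(t), float(y), float(sigma[j])))
    measurements = pd.DataFrame(
        rows, columns=["observableId", "simulationConditionId", "time",
                       "measurement", "noiseParameters"])

    return CalibrationProblem(
        model=model,
        conditions={c.condition_id: c for c in conditions},
        measurements=measurements,
        parameter_space=space,
        theta_true=theta_true,
    )


def generate_viability_dataset(
    n_cell_lines: int = 12,
    n_drugs: int = 3,
    n_doses: int = 5,
    seed: int = 0,
    n_layers: int = 2,
    noise_fraction: float = NOISE_FRACTION,
) -> tuple[CalibrationProblem, pd.DataFrame]:
    """Steady-state dose-response problem with binary responder labels.

    Conditions are cell line x drug x dose combinations plus one untreated
    condition per cell line (``n_cell_lines * (n_drugs * n_doses + 1)`` in
    total).  Cell lines differ in their per-layer expression scalings; each
    drug inhibits the activation of one cascade layer with a drawn potency.
    The readout is the equilibrium activity of the last layer ("viability"),
    one record per condition.  A condition's ground-truth label is
    *responsive* iff its noise-free viability is below 50% of the untreated
    viability of the same cell line (strictly).

    Returns the calibration problem and a label table with per-condition
    fold changes and labels.
    """
    if min(n_cell_lines, n_drugs, n_doses) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    spec = CascadeSpec(n_layers=n_layers, with_turnover=True, with_drug=True)
    model = build_cascade_model(spec)
    theta_true = default_theta_true(n_layers)
    space = ParameterSpace(list(model.parameter_names))

    # cell lines: expression scalings; drugs: target layer + potency
    scalings = np.exp(rng.uniform(np.log(0.3), np.log(3.0), size=(n_cell_lines, n_layers)))
    drug_target = rng.integers(0, n_layers, size=n_drugs)
    drug_potency = 10 ** rng.uniform(-0.5, 1.0, size=n_drugs)
    doses = np.logspace(-1.0, 1.0, n_doses)

    conditions: dict[str, Condition] = {}
    meta = []

    def make_u(cl: int, drug: int | None, dose: float) -> np.ndarray:
        pot = np.zeros(n_layers)
        if drug is not None:
            pot[drug_target[drug]] = drug_potency[drug]
        return np.concatenate([[dose], pot, scalings[cl]])

    for cl in range(n_cell_lines):
        cid = f"cl{cl:03d}_untreated"
        conditions[cid] = Condition(cid, make_u(cl, None, 0.0), is_steady_state=True)
        meta.append((cid, cl, "none", 0.0))
        for d in range(n_drugs):
            for k, dose in enumerate(doses):
                cid = f"cl{cl:03d}_d{d}_x{k}"
                conditions[cid] = Condition(cid, make_u(cl, d, dose), is_steady_state=True)
                meta.append((cid, cl, f"drug{d}", float(dose)))

    viability = {}
    for cid, cond in conditions.items():
        _, y, status = simulate_steady_state(model, theta_true, cond)
        if status != "ok":
            raise RuntimeError(f"steady state did not converge at theta_true for {cid}")
        viability[cid] = float(y[n_layers - 1])  # last layer's activity

    untreated = {cl: viability[f"cl{cl:03d}_untreated"] for cl in range(n_cell_lines)}
    values = np.array([viability[cid] for cid, *_ in meta])
    sigma = max(noise_fraction * (values.max() - values.min()), 1e-12)

    obs_name = model.observable_names[n_layers - 1]
    rows, label_rows = [], []
    for cid, cl, drug, dose in meta:
        clean = viability[cid]
        noisy = clean + rng.normal(0.0, sigma)
        rows.append((obs_name, cid, np.inf, float(noisy), float(sigma)))
        fold = clean / untreated[cl]
        label_rows.append((cid, cl, drug, dose, clean, float(noisy), fold, bool(fold < 0.5)))

    measurements = pd.DataFrame(
        rows, columns=["observableId", "simulationConditionId", "time",
                       "measurement", "noiseParameters"])
    labels = pd.DataFrame(
        label_rows, columns=["conditionId", "cell_line", "drug", "dose",
                             "viability_true", "viability_measured",
                             "fold_change", "responsive"])

    problem = CalibrationProblem(
        model=model, conditions=conditions, measurements=measurements,
        parameter_space=space, theta_true=theta_true)
    return problem, labels
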