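# Methods

This note records the modelling assumptions, numerical choices and design
decisions behind `batchode`, and what the synthetic benchmarks do and do
not establish.

## Model class and objective

Models are autonomous ODE systems `dx/dt = f(x, θ, u)` with initial state
`x0(θ, u)` and observables `y = h(x, θ)`.  θ holds the estimated kinetic
parameters; u is a per-condition vector of known inputs (dose, expression
scalings, drug potencies).  One condition is one initial value problem.
Measurements carry a known Gaussian noise SD per record, so the negative
log-likelihood reduces (up to the constant `½ Σ log 2πσ²`, which
`ObjectiveValue.J_full_nll` adds back) to the weighted least-squares cost
`J(θ) = Σ_e J_e(θ)`.  Estimating σ is out of scope; only multiplicative
observable scalings are profiled analytically, using the closed-form
minimizer `s* = (Σ ȳŷ/σ²)/(Σ ŷ²/σ²)` per observable group.  When scalings
are applied inside the objective, the gradient is the partial gradient at
the optimal scales (envelope theorem), so no extra terms arise.

All optimization happens on the log10 parameter scale in a box, by default
Ω′ = [−5, 3] per parameter (1e−5 to 1e3 on the linear scale, a plausible
range for mass-action rate constants).  Gradients are chain-ruled by
θ·ln 10 so that model evaluation stays on the linear scale.

## Numerical integration

The default solver is LSODA (via `scipy.integrate.odeint`): an adaptive,
variable-order implicit multistep method that switches between
Adams–Moulton and BDF and therefore handles the stiff regimes these models
enter for extreme parameter draws.  Its compiled stepping loop is roughly
an order of magnitude faster than the pure-Python alternatives, which is
what makes many-condition mini-batch studies feasible on one CPU.
Default per-step tolerances are rtol 1e−8, atol 1e−16, at most 1e4 steps.
The optimization-facing objective uses rtol 1e−6, atol 1e−12 by default — a
desk-scale accuracy choice; both are constructor parameters.  Symbolically
defined models (the YAML schema and all generator fixtures) get analytic
Jacobians via sympy; plain-callable models fall back to central finite
differences.

Integration failures (step-limit, repeated error-test failure, non-finite
output, exceptions in the right-hand side) are *statuses*, never
exceptions: `Trajectory.status` / `ObjectiveValue.status` propagate them to
the optimizer, whose rescue interceptor owns the recovery policy.  No
`status="ok"` result ever contains NaN or Inf.

## Gradients: forward sensitivity equations

Gradients use the forward variational system: the augmented state
`[x, dx/dθ]` obeys `dS/dt = (∂f/∂x) S + ∂f/∂θ`, `S(0) = ∂x0/∂θ`.  For
symbolic models the full augmented right-hand side is generated
symbolically (common-subexpression-eliminated), so each solver callback is
a single compiled-expression call; the supplied Jacobian is the
block-diagonal `I ⊗ ∂f/∂x`, the exact diagonal of the block-triangular
augmented Jacobian.  At the package's scale (tens of parameters) forward
sensitivities are as exact as and simpler than an adjoint computation; the
gradient contract (same signature, log10 scale) leaves room for an adjoint
backend.  Steady-state sensitivities use the implicit-function theorem
`dx*/dθ = −(∂f/∂x)⁻¹ ∂f/∂θ` when the Jacobian is regular, falling back to
integrating the variational system to the steady-state horizon for models
with conservation laws.

## Steady states

Steady-state conditions are simulated to t = 1e8 time units.  Convergence
is accepted when the tolerance-weighted RMS norm of the vector field,
`sqrt(mean((f_i/(atol + rtol·|x_i|))²))` with atol 1e−16 and rtol 1e−8, is
≤ 1 — the weighting convention of adaptive solvers' error norms.  The norm
is required to hold at both the full horizon and the half horizon: a pure
drift `x = f·t` satisfies the full-horizon check exactly on its boundary
(because rtol·t_max = 1), and the half-horizon requirement rejects that
degenerate ray while leaving genuine equilibria (time constants far below
t_max/2) unaffected.

## Mini-batch optimization

Per epoch the condition ids are shuffled and split into
`ceil(M/batch_size)` disjoint batches; the remainder batch is kept so every
condition is used exactly once per epoch.  The gradient estimate is the
*unnormalized sum* of per-condition gradients over the batch — consequence:
the effective SGD step grows with batch size, while the adaptive
algorithms' preconditioning removes that scale.  Update rules follow the
original publications (momentum and RMSProp decay 0.9, Adam with bias
correction, ε = 1e−8).  Under a persistent gradient, Adam's bias-corrected
update tends to unit magnitude per coordinate, so its step norm approaches
η·√n_θ; the schedule-suggestion helper uses this to map a target initial
step κ·√n_θ (κ ∈ [0.01, 0.1] is a reasonable first choice) to η_start = κ.

Learning-rate schedules interpolate geometrically between endpoints over
the run (or stay constant).  Four presets span three decades of decay each:
1e0→1e−3, 1e−1→1e−4, 1e−2→1e−5, and constant 1e−3.

Updates are clipped element-wise to the box; accumulators are *not* reset
on clipping.  Runs are deterministic given a seed: start sampling, batch
shuffling and generator noise flow from seeded `numpy` generators
(per-start streams are derived from the experiment seed and the start
index, so optimizer settings sharing a seed get paired starts *and* paired
batch sequences).

### Rescue interceptor

Triggered when a batch objective/gradient evaluation fails.  The previous
update is undone, the persistent `step_scale` multiplier (∈ (0,1]) is
halved, the update is re-applied at the reduced length, and the evaluation
retried on the same mini-batch — at most 10 times, after which the run
terminates (`rescue_exhausted`).  After a successful recovery the scale
doubles per successful step until it reaches 1.  The ×0.5 / ×2 factors are
a symmetric trust-region-style choice; the paper-level behaviour (dip and
gradual restoration, hard cap of 10) does not depend on them.  A failure at
the initial point has nothing to undo and terminates immediately
(`initial_failure`).

### Mini-batch line search

When enabled, each proposed step is evaluated objective-only on the same
mini-batch before acceptance: first the full step; on non-decrease, the
step factor is backtracked by safeguarded quadratic interpolation (the
minimizer of the quadratic fitted to φ(0), φ′(0), φ(α), clamped to
[0.1, 0.5]·α), at most 3 trials.  If no trial decreases the objective, the
smallest evaluable trial point is accepted anyway — in the stochastic
setting rejecting the step would stall progress, and the recorded event
flags the exhaustion.  Trial evaluation failures count as non-improvement
and halve the factor; if every trial fails, the step is handed to the
rescue logic.  The line search rescales the current step only; the
schedule itself is untouched.

## Benchmarking metrics

Optimizer settings are compared on paired multi-starts: per start, settings
are ranked ascending by final full-dataset objective (ties averaged; failed
runs rank worst, tied), then ranks are averaged over starts.  Final
objectives and correlations are always computed on the *whole* dataset,
with analytic scalings where configured, regardless of how the optimizer
was run.  The convergence threshold ("value-to-reach") is the mean plus one
sample SD (ddof = 1 — with ten values the distinction is minor) of a
reference optimizer's ten best finals; a run converges when its full-
dataset objective first drops below it, with cost accounted in condition
simulations — a hardware-independent proxy — and wall time recorded
secondarily.

Responder classification labels a condition responsive iff its readout is
*strictly* below 50% of the untreated reference of its group.  ROC analysis
sweeps the unique score values; AUC is trapezoidal (equal to the
normalized Mann–Whitney U statistic); the classification threshold is the
discrete slope-1 tangency point, operationalized as the maximizer of
TPR − FPR (Youden), with ties broken toward smaller FPR.  Thresholds
derived on one dataset can be reused on independent data.

## Ensembles from optimization histories

The history ensemble is built in four stages: (1) each run's mini-batch
objective trace is rescaled to a full-dataset equivalent (×steps/epoch;
batches are uniform draws) and smoothed by a centered moving average of up
to one epoch (half before, half after, truncated at the ends); (2) the
cutoff is the best smoothed weighted RMSE times 1.10, where
RMSE = sqrt(2J/N) converts the half-sum-of-squares objective to a residual
RMS under the σ-weighting (the smoothed best is used rather than the raw
best, for robustness; an explicit cutoff can be passed); (3) every visited
θ with smoothed value under the cutoff is admitted; (4) the admitted
members are thinned by uniform stride to at most 50 per (run, epoch).
Ensemble predictions are member-wise simulation means and SDs (members
counted as listed).  Parameter-space characterization uses the covariance
eigenspectrum (explained-variance fractions summing to 1) and the SVD of
the stacked output-sensitivity matrix; the default numerical-rank threshold
`max(dims)·eps·σ₁` assumes exact entries, so for ODE-integrated
sensitivities a `rank_rtol` at the integration tolerance gives the honest
rank.

## Synthetic benchmark generator

The generator emulates many-condition calibration studies with a
phosphorylation cascade: per layer an inactive/active cycle, layer 1
driven by the stimulus (dose + a basal drive of 0.1), downstream layers by
the upstream active species; per-layer expression scalings set the total
protein.  Estimated parameters are the activation/deactivation rate
constants (2 per layer).  Three presets fix the benchmark scales —
600 × 1 × 10 = 6000, 1200 × 1 × 10 = 12,000 and 1500 × 4 × 10 = 60,000
records.  Conditions combine a dose from a 12-point log grid (0.1–10,
cycled) with scalings drawn log-uniformly from [0.2, 5].  The default
ground truth places rates within one decade of 1.  Observation times are
log-spaced over 0.2–15 time units: sampling the fast rise phase is what
makes both rate constants of each layer identifiable; an evenly spaced
late grid leaves a sloppy ridge along which activation and deactivation
trade off.  Noise is additive Gaussian with a per-observable SD of 10% of
that observable's dynamic range over the clean dataset — a typical
signal-to-noise for quantitative immunoblot/proteomics readouts; with
noise disabled the generator is self-consistent (J(θ_true) = 0).

The viability preset adds basal turnover (synthesis/degradation, so the
steady state is unique and the Jacobian regular) and drug inhibition
(activation divided by 1 + potency·dose; each drug targets one layer with
a drawn potency).  Conditions are cell line × drug × dose plus one
untreated condition per cell line; the readout is the equilibrium activity
of the last layer, one record per condition; ground-truth responder labels
use the strict 50% fold-change rule on the noise-free readouts.

What these fixtures do not emulate: model-mismatch (the fitted model class
always contains the truth), non-Gaussian or heteroscedastic-beyond-design
noise, condition-specific observables or missing data, and the sheer
parameter dimension of genome-scale models.  Passing tests therefore
establish the correctness and behaviour of the machinery, not performance
claims on any real dataset.

## Study sizes used in tests and the acceptance script

Stochastic-behaviour studies run at desk scale, chosen so the full suite
executes on a single CPU: the line-search ablation uses a 100-condition
problem, high learning-rate preset, batch 25, 3 epochs, paired starts over
5 seeded repetitions; the parameter-recovery study uses 100 conditions,
balanced Adam, medium schedule, batch 10, 30 epochs, 20 starts, with the
chi-square criterion `best J ≤ J(θ_true) + 3·sqrt(N/2)`.  The full-scale
presets are exercised for their record-count contracts and generation
only.

## Known limitations

* No SBML/PEtab import; problems enter via the YAML + TSV schema or the
  generator.  The table layout follows PEtab conventions so export is
  mechanical.
* No adjoint gradients; cost grows linearly with n_θ, fine for tens of
  parameters, prohibitive for thousands.
* Analytic scaling factors only; offset and noise parameters are not
  profiled.
* The full-batch reference is L-BFGS-B with a large-penalty fallback on
  evaluation failure, which can stall it in failure regions rather than
  retreating along a line search.
* `run_minibatch` records full-dataset objectives at epoch boundaries only
  when `full_eval_every_epoch=True` (it doubles the per-epoch cost);
  convergence metrics need either that flag or explicit traces.
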