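"""Generate a small synthetic calibration problem and fit it full-batch.

Builds a 40-condition signaling-cascade dataset with known true rate
constants, fits it with the bounded quasi-Newton reference optimizer from
five random starts, and compares the recovered parameters with the truth.
"""

import numpy as np

import batchode as b

problem = b.generate_dataset(b.get_preset("fujita_like", n_conditions=40), seed=1)
objective = b.NLLObjective(problem)

print(f"{len(problem.conditions)} conditions, {problem.n_records} measurements")

result = b.run_multistart(objective, problem.parameter_space, n_starts=5, seed=2,
                          runner=b.run_fullbatch_reference, max_iterations=150)
best = result.best()

J_true = b.full_dataset_metrics(objective, problem.theta_true_log10())["J_full"]
print(f"final J of best start: {best.final_metrics['J_full']:.1f} "
      f"(J at true parameters: {J_true:.1f}; expectation is ~N/2 = "
      f"{problem.n_records / 2:.0f} under the generating noise)")
for name, est, true in zip(problem.parameter_space.names, best.final_theta,
                           problem.theta_true_log10()):
    print(f"  {name:10s} log10 estimate {est:+.3f}   truth {true:+.3f}")
print("Estimates within ~0.1 log10 of the truth mean the rate constant is "
      "identified to ~25%.")
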