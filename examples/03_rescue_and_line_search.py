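"""Failure recovery and the mini-batch line search at a high learning rate.

Parameter vectors far from the optimum can make the ODE unintegrable; the
rescue interceptor undoes the offending update and shrinks the step like a
one-dimensional trust region.  Separately, at a deliberately high learning
rate the backtracking line search (objective-only re-evaluations on the
same mini-batch) stabilizes the optimization.
"""

import numpy as np

import batchode as b

problem = b.generate_dataset(b.get_preset("fujita_like", n_conditions=60), seed=21)
objective = b.NLLObjective(problem)
space = problem.parameter_space

starts = space.sample(6, np.random.default_rng(0))
for line_search in (False, True):
    finals = []
    for i, th0 in enumerate(starts):
        hist = b.run_minibatch(objective, space, th0, algorithm="adam",
                               schedule="schedule_1",  # high learning rate
                               batch_size=15, epochs=4,
                               seed=np.random.default_rng([5, i]),
                               line_search=line_search)
        finals.append(hist.final_J)
    tag = "with line search   " if line_search else "without line search"
    print(f"{tag}: median final J = {np.nanmedian(finals):8.1f} over paired starts")

print("\nAt an overly aggressive learning rate the line search rejects the "
      "overshooting trial steps, so its median final objective is lower.")
print(f"(J at the true parameters is "
      f"{b.full_dataset_metrics(objective, problem.theta_true_log10())['J_full']:.1f}.)")
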