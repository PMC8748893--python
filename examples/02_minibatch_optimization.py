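"""Mini-batch calibration and rank-based comparison of optimizer settings.

Runs two mini-batch optimizers (balanced Adam and RMSProp, both with the
medium logarithmically decreasing learning-rate schedule) from the same
random starts, ranks them start-by-start on their final full-dataset
objective, and prints the waterfall of final values.
"""

import numpy as np

import batchode as b

problem = b.generate_dataset(b.get_preset("fujita_like", n_conditions=60), seed=3)
objective = b.NLLObjective(problem)
space = problem.parameter_space

settings = {"adam-balanced": {}, "rmsprop": {}}
finals = {}
for algo in settings:
    res = b.run_multistart(objective, space, n_starts=8, seed=7,  # paired starts
                           algorithm=algo, schedule="schedule_2",
                           batch_size=10, epochs=15)
    finals[algo] = res.final_values
    sorted_vals, order = b.waterfall(res.final_values)
    print(f"{algo}: waterfall of final J over starts:")
    print("  " + "  ".join(f"{v:.1f}" for v in sorted_vals))

table = b.rank_settings(np.array(list(finals.values())), list(finals))
print("\nMean rank per setting (lower is better, ties averaged):")
for name, mean_rank in table.ordered():
    print(f"  {name:15s} {mean_rank:.2f}")
print("A mean rank near 1 means that setting won on most of the paired starts.")
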