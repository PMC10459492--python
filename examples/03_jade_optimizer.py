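"""Minimize a test function with JADE and watch the self-adaptation.

JADE mutates each candidate toward a random member of the current elite
("current-to-pbest"), recycles replaced parents through an archive, and
adapts the mutation factor F and crossover rate CR from the values that
produced successful offspring.
"""

import numpy as np

from evostack import Bounds, JadeConfig, optimize_jade


def rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1 - x[:-1]) ** 2))


bounds = Bounds(np.full(4, -2.0), np.full(4, 2.0))
config = JadeConfig(pop_size=40, generations=300, seed=0)
result = optimize_jade(rosenbrock, bounds, config)

print(f"best f = {result.best.fitness:.3e} at x = {np.round(result.best.position, 4)}")
print(f"objective evaluations: {result.evaluations}")
for g in (0, 50, 150, 300):
    rec = result.trace[g]
    print(f"  gen {rec['generation']:>3}: best {rec['best_fitness']:.3e}  "
          f"mu_F {rec['mu_F']:.3f}  mu_CR {rec['mu_CR']:.3f}  "
          f"archive {rec['archive_size']}")
# The optimum of the Rosenbrock function is 0 at x = (1, 1, 1, 1); mu_F and
# mu_CR drift toward values that keep producing improvements.
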