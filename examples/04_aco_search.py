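"""Ant-colony architecture search (surrogate fitness, desk scale).

Runs the ant-colony-system search with a deterministic architecture-only
fitness so the mechanics are visible in seconds; swap in a
TrainingEvaluator to drive it with real validation accuracy.
"""

from swarmnas import desk_space
from swarmnas.aco import ACOConfig, run_aco_search
from swarmnas.evaluation import SurrogateEvaluator

config = ACOConfig(n_ants=4, depth=6, rng_seed=0)
evaluator = SurrogateEvaluator(seed=0)
best, history = run_aco_search(evaluator, config, desk_space(),
                               input_shape=(32, 32, 3))

print(f"models evaluated: {evaluator.n_calls}")  # ants x depth = 24
print(f"best architecture: {best.notation()}")
print(f"best fitness: {history.best_fitness[-1]:.3f}")

# The best-so-far curve is non-decreasing: each entry is the best fitness
# seen after one more candidate evaluation.
curve = history.best_fitness
print("best-so-far:", " ".join(f"{f:.2f}" for f in curve[::4]))
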