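"""Particle-swarm search with real training on synthetic images.

The full loop at desk scale: generate a separable 5-class dataset, run a
1-run/3-iteration/5-particle swarm with 1-epoch fitness evaluations, then
retrain the global best for 5 epochs and report its metrics.  Takes a few
minutes on one CPU.
"""

from swarmnas import desk_space
from swarmnas.evaluation import TrainerSpec, TrainingEvaluator
from swarmnas.pso import PSOConfig, run_pso_search
from swarmnas.synth import easy_profile, generate_dataset

seed = 1
ds = generate_dataset(easy_profile(n_total=600, image_size=32,
                                   noise_sigma=0.02, seed=seed))
evaluator = TrainingEvaluator(ds.images, ds.labels,
                              TrainerSpec(epochs=1, rng_seed=seed))

best, history = run_pso_search(
    evaluator,
    PSOConfig(runs=1, iterations=3, swarm_size=5, rng_seed=seed),
    desk_space(),
    input_shape=(32, 32, 3),
)
print(f"evaluations: {evaluator.n_calls}")          # runs x iters x swarm = 15
print(f"gbest (1-epoch fitness): {history.final_gbest_fitness:.3f}")
print(f"gbest architecture: {best.notation()}")

result, _ = evaluator.score(best, epochs=5)
print(f"retrained 5 epochs: accuracy={result.accuracy:.3f} "
      f"macro AUC={result.auc:.3f} kappa={result.kappa:.3f} "
      f"params={result.parameter_count:,}")
# The 1-epoch fitness underestimates final quality; the retrained global
# best typically exceeds 0.85 validation accuracy on this separable
# profile.
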