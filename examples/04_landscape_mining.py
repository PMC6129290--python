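"""Mining an evaluated-configuration history.

After a search, the history table is analysed for parameter-fitness
correlations, the parameter values shared by the best fraction of
configurations, and single-threshold decision rules separating the top
configurations from the rest.
"""

import dataclasses

from flexcop import (
    analyze_history,
    evaluate_config,
    make_producer_consumer_toy,
    run_exhaustive,
    subspace,
)
from flexcop.optimize import history_frame

bundle = make_producer_consumer_toy(horizon=40.0, dt=0.5)
fitness = dataclasses.replace(bundle.fitness, horizon=40.0)
space = subspace(bundle.space, {"KT": (0.05,), "NH4": (0.5, 3.5, 7.0)})


def objective(config, seed):
    return evaluate_config(
        config, space, bundle.models, bundle.layout_template, fitness,
        n_replicates=1, base_seed=seed,
    ).mean


history = history_frame(run_exhaustive(space, objective).history)
report = analyze_history(history, top_fraction=0.05, min_accuracy=0.85,
                         params=["sucrPer", "synecho", "NH4"])

print("fitness correlations (Pearson r):")
for name, r in report.correlations.fitness_correlations().items():
    tag = "" if report.correlations.is_defined(name, "fitness_mean") else " (undefined)"
    print(f"  {name:8s} {r:+.3f}{tag}")
# a positive producer-biomass and negative ammonium correlation is the
# expected physiology: more feeder -> more sucrose; more nitrogen ->
# longer growth phase, less product
print("values shared by the top 5%:", report.top_profile)
for rule in report.rules:
    print(f"rule: {rule.describe()}  (balanced accuracy {rule.accuracy:.2f})")
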