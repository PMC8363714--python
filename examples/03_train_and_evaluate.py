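"""Train a small ensemble on simulated populations and evaluate it.

A reduced version of the full study: 150 simulations per class at a
small scale (N = 300, 3 kb), a 2-member ensemble with 64-unit layers,
and held-out evaluation.  Runs in about a minute; the full desk-scale
replication (2,000 per class, 3 members, 128 units) is what
scripts/acceptance.py executes.
"""

from clonesel import SimConfig
from clonesel.benchmark import run_class_benchmark
from clonesel.classifier import Hyperparams

result = run_class_benchmark(
    n_per_class=150,
    seed=42,
    sim_config=SimConfig(N=300, L=3000, generations=300),
    hyper=Hyperparams.desk_scale(hidden_units=64, ensemble_size=2,
                                 subsample_size=8000, seed=42),
)
report = result.report

print("held-out confusion matrix (rows = true class):")
labels = list(result.model.class_labels)
print(f"{'':<12}" + "".join(f"{l[:8]:>10}" for l in labels))
for k, lbl in enumerate(labels):
    row = "".join(f"{int(v):>10}" for v in report.confusion[k])
    print(f"{lbl:<12}{row}")
print(f"\noverall accuracy: {report.overall_accuracy:.3f}")
for lbl, acc in report.per_class_accuracy.items():
    print(f"  {lbl:<12} {acc:.3f}")
print("\nparameter recovery (Spearman rank correlation, truth vs estimate):")
for name, rho in report.spearman.items():
    print(f"  {name:<12} {rho:+.3f}")
print(
    "\nSelection-bearing classes are recovered best; neutral and weakly\n"
    "negative populations are mutually confusable -- purifying selection\n"
    "near the drift barrier leaves almost no footprint."
)
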