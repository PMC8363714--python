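"""End-to-end scaled-down benchmark: simulate, featurize, train, evaluate.

This is the pipeline behind the package's headline numbers: a
class-balanced grid of forward simulations at desk scale (N = 1,000,
10 kb region, population-scaled selection held at reference values), the
16-statistic extraction, a reduced ensemble (3 members, 128-unit
layers), and held-out evaluation of the 4-class confusion surface.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .classifier import (
    ConfusionReport,
    EnsembleModel,
    Hyperparams,
    TrainingCorpus,
    build_training_corpus,
    evaluate_on_corpus,
    train_ensemble,
)
from .features import FeatureConfig, assemble_features
from .params import CLASS_LABELS, SimConfig, sample_class_params, sample_novel_params
from .sim import run_simulation


def simulate_class_grid(
    n_per_class: int,
    sim_config: SimConfig | None = None,
    seed: int = 0,
    novel: bool = False,
    progress: bool = False,
):
    """Simulate and featurize a class-balanced grid.

    Returns (X, y, Y): the feature matrix, class labels, and regression
    targets (log10 mu, p, s_p mean, s_n mean at reference scale).
    ``novel=True`` draws from parameter families absent from the
    training grid (generalization probe).
    """
    sim_config = sim_config or SimConfig.desk_scale()
    fcfg = FeatureConfig.from_sim_config(sim_config)
    sampler = sample_novel_params if novel else sample_class_params
    rng = np.random.default_rng(seed)
    X, y, Y = [], [], []
    t0 = time.time()
    for k, lbl in enumerate(CLASS_LABELS):
        for i in range(n_per_class):
            params = sampler(lbl, rng)
            sim_seed = int(rng.integers(2**31 - 1))
            vt = run_simulation(params, sim_config, seed=sim_seed)
            X.append(assemble_features(vt, fcfg).values)
            y.append(lbl)
            Y.append(params.regression_targets())
        if progress:
            print(f"  {lbl}: {n_per_class} simulations "
                  f"({time.time() - t0:.0f}s elapsed)", flush=True)
    return np.vstack(X), np.array(y), np.vstack(Y)


@dataclass
class BenchmarkResult:
    report: ConfusionReport
    model: EnsembleModel
    corpus: TrainingCorpus


def run_class_benchmark(
    n_per_class: int = 2000,
    seed: int = 1,
    sim_config: SimConfig | None = None,
    hyper: Hyperparams | None = None,
    progress: bool = False,
) -> BenchmarkResult:
    """Replicate the 4-class confusion surface at desk scale.

    Simulates ``n_per_class`` replicates per class, builds a
    90/10 deduplicated corpus, trains the reduced ensemble, and
    evaluates the held-out split.  Fully determined by ``seed``.
    """
    sim_config = sim_config or SimConfig.desk_scale()
    hyper = hyper or Hyperparams.desk_scale(seed=seed)
    X, y, Y = simulate_class_grid(
        n_per_class, sim_config, seed=seed, progress=progress
    )
    corpus = build_training_corpus(X, y, Y, seed=seed)
    model = train_ensemble(corpus, hyper)
    report = evaluate_on_corpus(model, corpus)
    return BenchmarkResult(report=report, model=model, corpus=corpus)
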