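"""Fully synthetic cohorts with the statistical structure the pipeline assumes.

Real deep-panel blood-sequencing cohorts are controlled access, so every
downstream stage is exercised against synthetic cohorts built here: a
261-gene AML-style panel with named driver genes, per-subject variant
tables generated class-conditionally by the forward clonal simulator and
passed through the deep-sequencing observation model (binomial reads at
~5000x, duplex retention rule), synthetic CADD-style pathogenicity
scores, subject metadata, and a ground-truth table for recovery tests.

The CADD model is a fixture convenience: scores are baseline noise plus
a positive shift for mutations with nonzero selection coefficients, so
pathogenicity summaries have signal by construction.  It emulates the
*direction* of real score enrichment, not its distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .params import CLASS_LABELS, SimConfig, sample_class_params
from .sim import apply_sequencing_model, run_simulation

#: Known AML driver genes flagged in the default panel.
DRIVER_GENES = (
    "DNMT3A", "TET2", "IDH1", "IDH2", "TP53", "JAK2", "ASXL1", "SRSF2",
    "SF3B1", "U2AF1", "NPM1", "FLT3", "CEBPA", "RUNX1", "KRAS", "NRAS",
    "WT1", "KIT", "GATA2", "PPM1D",
)


@dataclass(frozen=True)
class FixtureConfig:
    """Study design of a synthetic cohort."""

    n_per_group: int = 5                  # subjects per (class x status)
    classes: tuple = CLASS_LABELS
    statuses: tuple = ("case", "control")
    sim_config: SimConfig = field(
        default_factory=lambda: SimConfig(N=500, L=5_000, generations=300)
    )
    panel_size: int = 261
    driver_genes: tuple = DRIVER_GENES
    mean_gene_length: float = 1_500.0
    depth: int = 5000
    min_reads: int = 5
    min_per_strand: int = 2
    age_range: tuple = (36.0, 74.4)
    cadd_baseline_mean: float = 5.0
    cadd_baseline_sd: float = 3.0
    cadd_shift: float = 10.0
    cadd_shift_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be non-negative")
        if self.depth < self.min_reads:
            raise ValueError("depth below the read-retention minimum")
        if self.panel_size < len(self.driver_genes):
            raise ValueError("panel smaller than the driver-gene list")


def synth_panel(cfg: FixtureConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthesize the gene panel: names, coding lengths, driver flags."""
    names = list(cfg.driver_genes) + [
        f"GENE{i:03d}" for i in range(1, cfg.panel_size - len(cfg.driver_genes) + 1)
    ]
    lengths = np.maximum(
        rng.lognormal(np.log(cfg.mean_gene_length), 0.5, size=cfg.panel_size), 150
    ).astype(int)
    driver = np.zeros(cfg.panel_size, bool)
    driver[: len(cfg.driver_genes)] = True
    return pd.DataFrame({"gene": names, "length_bp": lengths, "driver": driver})


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort; ``write`` lays it out as a cohort directory."""

    panel: pd.DataFrame
    meta: pd.DataFrame
    variants: dict          # subject_id -> DataFrame
    cadd: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        (outdir / "variants").mkdir(parents=True, exist_ok=True)
        self.panel.to_csv(outdir / "panel.tsv", sep="\t", index=False)
        self.meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
        self.cadd.to_csv(outdir / "cadd.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for subject, vt in self.variants.items():
            vt.to_csv(outdir / "variants" / f"{subject}.tsv", sep="\t",
                      index=False)
        return outdir


def _assign_genes(vt: pd.DataFrame, panel: pd.DataFrame,
                  rng: np.random.Generator) -> np.ndarray:
    """Length-weighted gene assignment; beneficial mutations go to drivers."""
    lengths = panel["length_bp"].to_numpy(float)
    p_all = lengths / lengths.sum()
    drv = panel["driver"].to_numpy(bool)
    p_drv = np.where(drv, lengths, 0.0)
    p_drv = p_drv / p_drv.sum() if p_drv.sum() > 0 else p_all
    genes = np.empty(len(vt), dtype=object)
    beneficial = vt["s"].to_numpy(float) > 0 if "s" in vt.columns else np.zeros(len(vt), bool)
    for i in range(len(vt)):
        probs = p_drv if beneficial[i] else p_all
        genes[i] = panel["gene"].iloc[int(rng.choice(len(panel), p=probs))]
    return genes


def _cadd_scores(vt: pd.DataFrame, cfg: FixtureConfig,
                 rng: np.random.Generator) -> np.ndarray:
    base = np.maximum(
        rng.normal(cfg.cadd_baseline_mean, cfg.cadd_baseline_sd, len(vt)), 0.0
    )
    selected = np.abs(vt["s"].to_numpy(float)) > 0 if "s" in vt.columns else np.zeros(len(vt), bool)
    shift = np.maximum(rng.normal(cfg.cadd_shift, cfg.cadd_shift_sd, len(vt)), 0.0)
    return np.round(base + shift * selected, 2)


def synth_cohort(cfg: FixtureConfig) -> SyntheticCohort:
    """Generate a class-balanced synthetic cohort.

    Per subject: parameters drawn from the subject's class grid, a
    forward simulation, the sequencing observation model, length-weighted
    panel-gene assignment (beneficial mutations restricted to driver
    genes, mirroring the simulator's driver-territory convention),
    synthetic CADD scores, and a metadata row.  Ground-truth classes and
    parameters go to the truth table.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = synth_panel(cfg, rng)
    drv_share = float(
        panel.loc[panel["driver"], "length_bp"].sum() / panel["length_bp"].sum()
    )
    sim_cfg = replace(cfg.sim_config, driver_frac=drv_share)

    meta_rows, truth_rows, cadd_rows = [], [], []
    variants: dict[str, pd.DataFrame] = {}
    sid = 0
    for status in cfg.statuses:
        for class_label in cfg.classes:
            for _ in range(cfg.n_per_group):
                subject = f"S{sid:04d}"
                sid += 1
                params = sample_class_params(class_label, rng)
                vt = run_simulation(params, sim_cfg,
                                    seed=int(rng.integers(2**31 - 1)))
                true_vaf = vt["vaf"].to_numpy(float).copy()
                obs = apply_sequencing_model(
                    vt, depth=cfg.depth, min_reads=cfg.min_reads,
                    min_per_strand=cfg.min_per_strand, rng=rng,
                )
                obs = obs.reset_index(drop=True)
                kept = obs["variant_id"].to_numpy()
                idx_map = {v: i for i, v in enumerate(vt["variant_id"])}
                obs["true_vaf"] = [true_vaf[idx_map[v]] for v in kept]
                obs["gene"] = _assign_genes(obs, panel, rng)
                obs["variant_id"] = [f"{subject}_v{i}" for i in range(len(obs))]
                scores = _cadd_scores(obs, cfg, rng)
                cadd_rows.extend(
                    {"variant_id": v, "cadd": c}
                    for v, c in zip(obs["variant_id"], scores)
                )
                out_cols = ["variant_id", "gene", "consequence", "vaf",
                            "reads_fwd", "reads_rev", "depth", "true_vaf"]
                variants[subject] = obs[out_cols]

                age = float(rng.uniform(*cfg.age_range))
                if status == "case":
                    follow, event = float(rng.uniform(0.03, 12.4)), True
                else:
                    follow, event = float(rng.uniform(3.36, 14.9)), False
                meta_rows.append(
                    {"subject_id": subject, "status": status, "age": round(age, 1),
                     "follow_time": round(follow, 2), "event": event}
                )
                truth_rows.append(
                    {"subject_id": subject, "class": params.class_label,
                     "mu": params.mu, "p_beneficial": params.p_beneficial,
                     "s_pos_mean": params.s_pos_mean,
                     "s_neg_mean": params.s_neg_mean}
                )

    meta_cols = ["subject_id", "status", "age", "follow_time", "event"]
    truth_cols = ["subject_id", "class", "mu", "p_beneficial", "s_pos_mean",
                  "s_neg_mean"]
    return SyntheticCohort(
        panel=panel,
        meta=pd.DataFrame(meta_rows, columns=meta_cols),
        variants=variants,
        cadd=pd.DataFrame(cadd_rows, columns=["variant_id", "cadd"]),
        truth=pd.DataFrame(truth_rows, columns=truth_cols),
    )
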