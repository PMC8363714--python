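"""Apply a trained ensemble to per-subject variant tables.

This layer consumes the outputs of upstream variant calling (TSV or
VCF), classifies each subject's blood population into an evolutionary
class, and produces the downstream summaries: class proportions by
10-year age bin with binomial standard errors, population-size
rescaling of mutation-rate estimates (theta-invariance), dominant-clone
extraction, and driver/passenger pathogenicity summaries with
function-altering gene-set intersections.

Inferential comparisons on real data (chi-squared, rank-sum) are
delegated to scipy; only the computations specific to this analysis are
implemented natively.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ClassPrediction, EnsembleModel, predict_sample
from .features import FeatureConfig, assemble_features
from .params import CLASS_LABELS

logger = logging.getLogger(__name__)

_SILENT = {"silent", "synonymous", "syn"}
_MISSENSE = {"missense", "nonsense", "nonsynonymous", "non-synonymous", "nonsyn"}


@dataclass
class CohortRecord:
    """One subject: metadata, variant table, and (after classification) prediction."""

    subject_id: str
    status: str                   # "case" | "control"
    age: float                    # years at sampling
    follow_time: float = 0.0      # years of follow-up
    event: bool = False           # progressed to malignancy
    variants: pd.DataFrame | None = None
    prediction: ClassPrediction | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case/control, got {self.status!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.follow_time < 0:
            raise ValueError("follow-up time must be non-negative")


def read_panel(path) -> pd.DataFrame:
    """Gene panel TSV: columns gene, length_bp, driver."""
    panel = pd.read_csv(path, sep="\t")
    required = {"gene", "length_bp", "driver"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    panel["driver"] = panel["driver"].astype(bool)
    return panel


def _normalize_consequence(value, line_no: int) -> str:
    v = str(value).strip().lower()
    if v in _SILENT:
        return "silent"
    if v in _MISSENSE:
        return "missense"
    raise ValueError(f"malformed consequence {value!r} at line {line_no}")


def read_variant_table(
    path,
    panel: pd.DataFrame,
    cadd_path=None,
    min_reads: int = 5,
    min_per_strand: int = 2,
) -> pd.DataFrame:
    """Read one subject's variant table (TSV dialect or VCF).

    TSV columns: ``gene``, ``consequence``, ``vaf``; optional
    ``variant_id``, ``reads_fwd``, ``reads_rev``, ``depth``, ``cadd``.
    Rows are annotated with the panel's driver flag (unknown genes get a
    warning and a non-driver default).  When strand read counts are
    present, rows failing the duplex retention rule (>= ``min_reads``
    total with >= ``min_per_strand`` per strand) are dropped and the
    count is logged.  ``cadd_path`` points to a TSV (variant_id, cadd)
    merged onto the rows.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        vt = _read_vcf(path)
    else:
        vt = pd.read_csv(path, sep="\t")
    if len(vt) == 0:
        vt = pd.DataFrame(
            columns=["variant_id", "vaf", "consequence", "gene", "driver"]
        )
        vt.attrs["provenance"] = "observed"
        return vt

    for col in ("gene", "consequence", "vaf"):
        if col not in vt.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "variant_id" not in vt.columns:
        vt["variant_id"] = [f"{path.stem}_v{i}" for i in range(len(vt))]

    vt["consequence"] = [
        _normalize_consequence(v, i + 2) for i, v in enumerate(vt["consequence"])
    ]
    vaf = pd.to_numeric(vt["vaf"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(vaf) | (vaf <= 0) | (vaf > 1))
    if len(bad):
        raise ValueError(f"{path}: malformed VAF at line {int(bad[0]) + 2}")
    vt["vaf"] = vaf

    # read-support retention rule
    if {"reads_fwd", "reads_rev"} <= set(vt.columns):
        fwd = vt["reads_fwd"].to_numpy(int)
        rev = vt["reads_rev"].to_numpy(int)
        keep = ((fwd + rev) >= min_reads) & (fwd >= min_per_strand) & (rev >= min_per_strand)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("%s: dropped %d variants failing read-support rule",
                        path.name, n_drop)
        vt = vt.loc[keep].reset_index(drop=True)

    driver_map = dict(zip(panel["gene"], panel["driver"]))
    unknown = sorted(set(vt["gene"]) - set(driver_map))
    if unknown:
        warnings.warn(
            f"{path.name}: genes not in panel treated as non-driver: "
            f"{unknown[:5]}", stacklevel=2,
        )
    vt["driver"] = [bool(driver_map.get(g, False)) for g in vt["gene"]]

    if cadd_path is not None:
        cadd = pd.read_csv(cadd_path, sep="\t")
        vt = vt.merge(cadd[["variant_id", "cadd"]], on="variant_id", how="left",
                      suffixes=("_orig", ""))
    vt.attrs["provenance"] = "observed"
    return vt


def _read_vcf(path: Path) -> pd.DataFrame:
    """Minimal VCF reader: per-record INFO keys GENE, CSQCLASS, VAF, FR, RR."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "gene": info.get("GENE", "NA"),
                "consequence": info.get("CSQCLASS", "missense"),
                "vaf": float(info.get("VAF", np.nan)),
                "reads_fwd": int(info.get("FR", 0)),
                "reads_rev": int(info.get("RR", 0)),
                "depth": int(info.get("DP", 0)),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) and (df["reads_fwd"] + df["reads_rev"]).sum() == 0:
        df = df.drop(columns=["reads_fwd", "reads_rev", "depth"])
    return df


def load_cohort(cohort_dir, panel: pd.DataFrame | None = None) -> list[CohortRecord]:
    """Load a cohort directory (meta.tsv + variants/<subject>.tsv [+ cadd.tsv])."""
    cohort_dir = Path(cohort_dir)
    meta = pd.read_csv(cohort_dir / "meta.tsv", sep="\t")
    if panel is None:
        panel = read_panel(cohort_dir / "panel.tsv")
    cadd_path = cohort_dir / "cadd.tsv"
    cadd_path = cadd_path if cadd_path.exists() else None
    records = []
    for _, row in meta.iterrows():
        vt = read_variant_table(
            cohort_dir / "variants" / f"{row['subject_id']}.tsv",
            panel, cadd_path=cadd_path,
        )
        records.append(
            CohortRecord(
                subject_id=str(row["subject_id"]),
                status=str(row["status"]),
                age=float(row["age"]),
                follow_time=float(row.get("follow_time", 0.0)),
                event=bool(row.get("event", False)),
                variants=vt,
            )
        )
    return records


def classify_cohort(
    model: EnsembleModel,
    cohort: list[CohortRecord],
    feature_cfg: FeatureConfig,
) -> pd.DataFrame:
    """Featurize and classify every subject; returns the prediction table.

    Each record's ``prediction`` field is populated in place.  The
    prediction table has one row per subject with the mean +/- SE
    softmax over the four classes and the four parameter estimates.
    """
    rows = []
    for rec in cohort:
        fv = assemble_features(rec.variants, feature_cfg)
        pred = predict_sample(model, fv)
        rec.prediction = pred
        row = {"subject_id": rec.subject_id, "status": rec.status,
               "age": rec.age}
        row.update(pred.as_row())
        rows.append(row)
    columns = ["subject_id", "status", "age", "predicted_class", "tie"]
    if rows:
        columns = list(rows[0].keys())
    return pd.DataFrame(rows, columns=columns)


def rescale_mutation_rate(mu_hat: float, N_ref: float = 10_000, N_new: float = 10_000) -> float:
    """Rescale a mutation-rate estimate to another assumed HSC pool size.

    The population-scaled mutation rate theta = 4.N.mu is what the data
    constrain, so holding theta fixed gives mu_new = mu_hat * N_ref / N_new.
    """
    if mu_hat <= 0 or N_ref <= 0 or N_new <= 0:
        raise ValueError("all arguments must be positive")
    return mu_hat * N_ref / N_new


def age_bin_summary(
    predictions: pd.DataFrame,
    bin_width: int = 10,
    age_range: tuple[int, int] = (30, 80),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class proportions per (10-year age bin x status) with binomial SE.

    SE = sqrt(p(1-p)/n).  Bins are left-closed/right-open; subjects
    outside ``age_range`` go to flagged flanking bins.  Returns the
    summary table and the per-(bin, class) case-vs-control chi-squared
    comparisons (scipy ``chi2_contingency``).
    """
    lo, hi = age_range
    edges = list(range(lo, hi + 1, bin_width))

    def _bin(age: float) -> tuple[str, bool]:
        if age < lo:
            return f"<{lo}", True
        if age >= hi:
            return f">={hi}", True
        for e in edges[:-1]:
            if e <= age < e + bin_width:
                return f"[{e},{e + bin_width})", False
        raise AssertionError  # pragma: no cover

    df = predictions.copy()
    binned = [_bin(a) for a in df["age"]]
    df["age_bin"] = [b for b, _ in binned]
    df["age_bin_flagged"] = [f for _, f in binned]

    rows = []
    for (age_bin, status), grp in df.groupby(["age_bin", "status"]):
        n = len(grp)
        if n == 0:
            continue
        for lbl in CLASS_LABELS:
            p = float(np.mean(grp["predicted_class"] == lbl))
            rows.append(
                {
                    "age_bin": age_bin,
                    "status": status,
                    "class": lbl,
                    "p": p,
                    "se": float(np.sqrt(p * (1 - p) / n)),
                    "n": n,
                    "flagged": bool(grp["age_bin_flagged"].iloc[0]),
                }
            )
    summary = pd.DataFrame(rows)

    tests = []
    for age_bin, grp in df.groupby("age_bin"):
        cases = grp[grp["status"] == "case"]
        ctrls = grp[grp["status"] == "control"]
        if len(cases) == 0 or len(ctrls) == 0:
            logger.info("age bin %s lacks one status group; omitted", age_bin)
            continue
        for lbl in CLASS_LABELS:
            table = np.array(
                [
                    [np.sum(cases["predicted_class"] == lbl),
                     np.sum(cases["predicted_class"] != lbl)],
                    [np.sum(ctrls["predicted_class"] == lbl),
                     np.sum(ctrls["predicted_class"] != lbl)],
                ]
            )
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            chi2, pval, _, _ = stats.chi2_contingency(table)
            tests.append(
                {"age_bin": age_bin, "class": lbl,
                 "chi2": float(chi2), "p_value": float(pval)}
            )
    return summary, pd.DataFrame(tests)


def dominant_clone(vt: pd.DataFrame) -> pd.Series:
    """The variant with the highest VAF in a subject's blood sample.

    Ties are broken by higher CADD score, then first occurrence, and
    flagged (``tie`` field).  The returned row carries ``cadd_bin``,
    the width-10 pathogenicity interval floor(cadd/10)*10.
    """
    if len(vt) == 0:
        raise ValueError("cannot extract a dominant clone from an empty table")
    vaf = vt["vaf"].to_numpy(float)
    top = vaf == vaf.max()
    tie = bool(top.sum() > 1)
    cand = vt.loc[top]
    if tie and "cadd" in cand.columns:
        cadd = cand["cadd"].to_numpy(float)
        cadd = np.where(np.isfinite(cadd), cadd, -np.inf)
        cand = cand.iloc[[int(np.argmax(cadd))]]
    row = cand.iloc[0].copy()
    row["tie"] = tie
    score = row.get("cadd", np.nan)
    row["cadd_bin"] = (
        float(np.floor(score / 10.0) * 10.0) if np.isfinite(score) else np.nan
    )
    return row


def function_altering_gene_sets(
    cohort: list[CohortRecord], cadd_threshold: float = 10.0
) -> dict:
    """Genes harboring function-altering (CADD > threshold) mutations per class.

    Returns ``{"per_class": {class: [genes]}, "intersections": {...}}``
    where intersections maps each combination of classes (joined by
    ``+``) to the genes found in exactly those classes -- the
    computation underlying an UpSet-style display.
    """
    per_class: dict[str, set] = {lbl: set() for lbl in CLASS_LABELS}
    for rec in cohort:
        if rec.prediction is None or rec.variants is None:
            continue
        vt = rec.variants
        if "cadd" not in vt.columns or len(vt) == 0:
            continue
        hits = vt.loc[vt["cadd"].astype(float) > cadd_threshold, "gene"]
        per_class[rec.prediction.predicted_class].update(hits)

    intersections = {}
    for r in range(1, len(CLASS_LABELS) + 1):
        for combo in itertools.combinations(CLASS_LABELS, r):
            inset = set.intersection(*(per_class[c] for c in combo))
            outset = set.union(
                *(per_class[c] for c in CLASS_LABELS if c not in combo),
                set(),
            )
            exact = inset - outset
            if exact:
                intersections["+".join(combo)] = sorted(exact)
    return {
        "per_class": {lbl: sorted(genes) for lbl, genes in per_class.items()},
        "intersections": intersections,
    }


def pathogenicity_summary(
    cohort: list[CohortRecord], cadd_threshold: float = 10.0
) -> dict:
    """Driver vs passenger CADD summaries per evolutionary class.

    Per class: mean +/- SEM CADD for mutations in driver vs non-driver
    genes, with a two-sided rank-sum comparison (scipy).  Variants
    without a CADD score are excluded and counted.  Also returns the
    function-altering gene sets and their class intersections.
    """
    out: dict = {"classes": {}, "n_missing_cadd": 0}
    by_class: dict[str, dict[str, list]] = {
        lbl: {"driver": [], "passenger": []} for lbl in CLASS_LABELS
    }
    for rec in cohort:
        if rec.prediction is None or rec.variants is None:
            continue
        vt = rec.variants
        if "cadd" not in vt.columns:
            out["n_missing_cadd"] += len(vt)
            continue
        scores = vt["cadd"].astype(float)
        missing = ~np.isfinite(scores)
        out["n_missing_cadd"] += int(missing.sum())
        ok = vt.loc[~missing]
        lbl = rec.prediction.predicted_class
        by_class[lbl]["driver"].extend(ok.loc[ok["driver"], "cadd"].astype(float))
        by_class[lbl]["passenger"].extend(
            ok.loc[~ok["driver"].astype(bool), "cadd"].astype(float)
        )

    for lbl, groups in by_class.items():
        drv, psg = np.asarray(groups["driver"]), np.asarray(groups["passenger"])
        if len(drv) == 0 and len(psg) == 0:
            logger.info("class %s has no scored mutations; omitted", lbl)
            continue

        def _summ(x):
            if len(x) == 0:
                return {"n": 0, "mean": float("nan"), "sem": float("nan")}
            return {
                "n": int(len(x)),
                "mean": float(np.mean(x)),
                "sem": float(stats.sem(x)) if len(x) > 1 else 0.0,
            }

        entry = {"driver": _summ(drv), "passenger": _summ(psg)}
        if len(drv) and len(psg):
            res = stats.ranksums(drv, psg)
            entry["ranksum"] = {"statistic": float(res.statistic),
                                "p_value": float(res.pvalue)}
        out["classes"][lbl] = entry
    out["gene_sets"] = function_altering_gene_sets(cohort, cadd_threshold)
    return out
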