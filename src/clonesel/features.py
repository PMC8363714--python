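"""The ordered 16-statistic summary of a variant table.

Every sample -- a simulated population or an individual's deep-sequenced
blood profile -- is reduced to the same ordered vector of 16 summary
statistics before classification:

1. total mutation count
2. silent count
3. missense count
4-6.  silent counts in low / intermediate / high VAF bins
7-9.  missense counts in low / intermediate / high VAF bins
10.   overall pN/pS (per-site missense over silent proportions)
11-13. per-bin pN/pS
14.   Tajima's D
15.   Fay & Wu's H
16.   mutation count in known driver genes / driver territory

VAF bins are low (0, 0.1), intermediate [0.1, 0.8], high (0.8, 1].
The site-frequency-spectrum statistics (D, H) are computed on a
pseudo-sample of ``sample_n`` haploid genomes obtained by rounding each
VAF to a derived-allele count; deep coverage makes the VAF nearly
continuous, so the rounding loses little information.

Undefined statistics (no segregating sites; zero denominators) are
imputed as 0 and flagged; the count features disambiguate "no data"
from a true zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_NAMES = (
    "total_count",
    "silent_count",
    "missense_count",
    "silent_low",
    "silent_intermediate",
    "silent_high",
    "missense_low",
    "missense_intermediate",
    "missense_high",
    "pnps_overall",
    "pnps_low",
    "pnps_intermediate",
    "pnps_high",
    "tajimas_d",
    "fay_wu_h",
    "driver_count",
)

#: Version tag stored with trained models; models refuse feature vectors
#: produced by a different layout.
LAYOUT_VERSION = "fv16.1"


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings shared by simulated and observed data."""

    vaf_low: float = 0.1
    vaf_high: float = 0.8
    sample_n: int = 100
    L_syn: float = 20_000 / 3.0
    L_nonsyn: float = 40_000 / 3.0

    def __post_init__(self) -> None:
        if not 0 < self.vaf_low < self.vaf_high < 1:
            raise ValueError("need 0 < vaf_low < vaf_high < 1")
        if self.sample_n < 4:
            raise ValueError("sample_n must be >= 4 for SFS statistics")
        if self.L_syn <= 0 or self.L_nonsyn <= 0:
            raise ValueError("site totals must be positive")

    @classmethod
    def from_sim_config(cls, config, **overrides) -> "FeatureConfig":
        """Derive site totals and pseudo-sample size from a SimConfig."""
        kw = dict(
            sample_n=config.sample_n,
            L_syn=config.L_syn,
            L_nonsyn=config.L_nonsyn,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 16-statistic vector plus flags for imputed statistics."""

    values: np.ndarray
    flags: dict = field(default_factory=dict)
    layout_version: str = LAYOUT_VERSION

    def __post_init__(self) -> None:
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"feature vector must have length {len(FEATURE_NAMES)}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES))


def sfs_from_vafs(vafs: np.ndarray, sample_n: int) -> np.ndarray:
    """Unfolded pseudo-sample SFS from continuous variant frequencies.

    Each variant with 0 < vaf < 1 is assigned derived-allele count
    round(vaf * n) clipped to [1, n-1], so ultra-rare detected variants
    stay singletons and near-fixed ones stay at n-1; vaf = 1 (fixed) is
    excluded.  Returns counts at derived count i for i = 1..n-1.
    """
    if sample_n < 2:
        raise ValueError("sample_n must be >= 2")
    n = int(sample_n)
    vafs = np.asarray(vafs, dtype=float)
    vafs = vafs[(vafs > 0) & (vafs < 1)]
    sfs = np.zeros(n - 1, dtype=np.int64)
    if len(vafs) == 0:
        return sfs
    counts = np.clip(np.rint(vafs * n).astype(np.int64), 1, n - 1)
    np.add.at(sfs, counts - 1, 1)
    return sfs


def _theta_pi(sfs: np.ndarray, n: int) -> float:
    i = np.arange(1, n)
    return float(np.sum(2.0 * i * (n - i) * sfs) / (n * (n - 1)))


def _theta_h(sfs: np.ndarray, n: int) -> float:
    i = np.arange(1, n)
    return float(np.sum(2.0 * i * i * sfs) / (n * (n - 1)))


def tajimas_d(sfs: np.ndarray, n: int) -> float:
    """Tajima's D from an unfolded SFS of a sample of n genomes.

    D = (theta_pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard
    variance constants.  Returns 0.0 when there are no segregating
    sites (callers flag this as undefined).
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    sfs = np.asarray(sfs)
    if sfs.shape != (n - 1,):
        raise ValueError(f"SFS must have length n-1 = {n - 1}")
    S = int(sfs.sum())
    if S == 0:
        return 0.0
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0
    return (_theta_pi(sfs, n) - S / a1) / np.sqrt(var)


def fay_wu_h(sfs: np.ndarray, n: int) -> float:
    """Fay & Wu's H = theta_pi - theta_H (unnormalized form).

    Negative H indicates an excess of high-frequency derived variants,
    the classical hitchhiking signature.  Returns 0.0 when there are no
    segregating sites.
    """
    if n < 3:
        raise ValueError("Fay & Wu's H requires n >= 3")
    sfs = np.asarray(sfs)
    if sfs.shape != (n - 1,):
        raise ValueError(f"SFS must have length n-1 = {n - 1}")
    if sfs.sum() == 0:
        return 0.0
    return _theta_pi(sfs, n) - _theta_h(sfs, n)


def pn_ps(
    missense_count: int,
    silent_count: int,
    L_nonsyn: float,
    L_syn: float,
) -> float:
    """Per-site proportion of missense relative to silent mutations.

    (missense/L_nonsyn) / (silent/L_syn); < 1 suggests purifying
    selection against nonsynonymous variants.  A zero silent count makes
    the ratio undefined; it is reported as 0 (callers flag it).
    """
    if L_nonsyn <= 0 or L_syn <= 0:
        raise ValueError("site totals must be positive")
    if silent_count == 0:
        return 0.0
    return (missense_count / L_nonsyn) / (silent_count / L_syn)


def assemble_features(vt: pd.DataFrame, cfg: FeatureConfig) -> FeatureVector:
    """Compute the ordered 16-statistic vector of a variant table.

    Pure function of (table, config); the identical code path serves
    simulated and observed tables.
    """
    required = ("vaf", "consequence", "driver")
    for col in required:
        if col not in vt.columns:
            raise ValueError(f"variant table lacks required column {col!r}")
    if len(vt):
        bad = vt.index[
            vt["consequence"].isna() | vt["driver"].isna() | vt["vaf"].isna()
        ].tolist()
        if bad:
            raise ValueError(f"missing annotations at rows {bad[:20]}")

    vaf = vt["vaf"].to_numpy(float) if len(vt) else np.empty(0)
    silent = vt["consequence"].to_numpy() == "silent" if len(vt) else np.empty(0, bool)
    missense = ~silent if len(vt) else np.empty(0, bool)
    driver = vt["driver"].to_numpy(bool) if len(vt) else np.empty(0, bool)

    low = vaf < cfg.vaf_low
    high = vaf > cfg.vaf_high
    mid = ~low & ~high

    def _count(mask) -> int:
        return int(np.sum(mask))

    n_sil = _count(silent)
    n_mis = _count(missense)
    counts = {
        "silent": (n_sil, _count(silent & low), _count(silent & mid), _count(silent & high)),
        "missense": (n_mis, _count(missense & low), _count(missense & mid), _count(missense & high)),
    }

    flags = {}

    def _ratio(mis, sil, tag):
        r = pn_ps(mis, sil, cfg.L_nonsyn, cfg.L_syn)
        if sil == 0:
            flags[tag] = True
        return r

    sfs = sfs_from_vafs(vaf, cfg.sample_n)
    S = int(sfs.sum())
    if S == 0:
        flags["sfs_undefined"] = True
    d = tajimas_d(sfs, cfg.sample_n)
    h = fay_wu_h(sfs, cfg.sample_n)

    values = np.array(
        [
            n_sil + n_mis,
            n_sil,
            n_mis,
            counts["silent"][1],
            counts["silent"][2],
            counts["silent"][3],
            counts["missense"][1],
            counts["missense"][2],
            counts["missense"][3],
            _ratio(n_mis, n_sil, "pnps_overall_zero_denominator"),
            _ratio(counts["missense"][1], counts["silent"][1], "pnps_low_zero_denominator"),
            _ratio(counts["missense"][2], counts["silent"][2], "pnps_intermediate_zero_denominator"),
            _ratio(counts["missense"][3], counts["silent"][3], "pnps_high_zero_denominator"),
            d,
            h,
            _count(driver),
        ],
        dtype=float,
    )
    return FeatureVector(values=values, flags=flags)


def featurize_tables(
    tables, cfg: FeatureConfig
) -> pd.DataFrame:
    """Feature matrix (one row per table) with the 16 canonical columns."""
    rows = [assemble_features(vt, cfg).values for vt in tables]
    mat = np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
    return pd.DataFrame(mat, columns=list(FEATURE_NAMES))
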