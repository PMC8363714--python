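"""The per-sample variant table and its on-disk TSV dialect.

A variant table is a pandas DataFrame with one row per segregating
variant.  Required columns:

- ``variant_id``: unique identifier within the table
- ``vaf``: variant allele frequency in (0, 1] (cell fraction for
  simulated tables, read fraction for observed ones)
- ``consequence``: ``"silent"`` or ``"missense"`` (nonsense variants are
  pooled with missense upstream)
- ``gene``: gene or territory label
- ``driver``: boolean, variant falls in a known driver gene / territory

Optional columns: ``s`` (true selection coefficient, simulated tables),
``cadd`` (scaled deleteriousness score), ``reads_fwd``, ``reads_rev``,
``depth``, ``origin_gen``.  ``df.attrs["provenance"]`` records whether
the table is ``"simulated"`` or ``"observed"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("variant_id", "vaf", "consequence", "gene", "driver")
CONSEQUENCES = ("silent", "missense")


def make_variant_table(data: dict, provenance: str = "simulated") -> pd.DataFrame:
    """Assemble and validate a variant table from column arrays."""
    vt = pd.DataFrame(data)
    vt.attrs["provenance"] = provenance
    validate_variant_table(vt)
    return vt


def empty_variant_table(provenance: str = "simulated") -> pd.DataFrame:
    vt = pd.DataFrame(
        {
            "variant_id": pd.Series(dtype=np.int64),
            "vaf": pd.Series(dtype=float),
            "consequence": pd.Series(dtype=object),
            "gene": pd.Series(dtype=object),
            "driver": pd.Series(dtype=bool),
        }
    )
    vt.attrs["provenance"] = provenance
    return vt


def validate_variant_table(vt: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in vt.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if len(vt) == 0:
        return
    vaf = vt["vaf"].to_numpy(float)
    if np.any(~np.isfinite(vaf)) or np.any(vaf <= 0) or np.any(vaf > 1):
        bad = vt.index[(~np.isfinite(vaf)) | (vaf <= 0) | (vaf > 1)].tolist()
        raise ValueError(f"vaf outside (0, 1] at rows {bad[:10]}")
    bad_cons = ~vt["consequence"].isin(CONSEQUENCES)
    if bad_cons.any():
        raise ValueError(
            "unknown consequence at rows "
            f"{vt.index[bad_cons].tolist()[:10]} (expected silent/missense)"
        )
    if vt["driver"].isna().any():
        raise ValueError("driver flag missing for some rows")


def write_variant_table(vt: pd.DataFrame, path) -> None:
    vt.to_csv(path, sep="\t", index=False)


def read_simulated_variant_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_variant_table`."""
    vt = pd.read_csv(path, sep="\t")
    if len(vt) and vt["driver"].dtype != bool:
        vt["driver"] = vt["driver"].astype(bool)
    vt.attrs["provenance"] = "simulated"
    validate_variant_table(vt)
    return vt
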