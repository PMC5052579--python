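"""Flat-file readers for the CSV exchange schemas.

All inter-stage data travel as RFC-4180 CSV (UTF-8, "." decimal): a sample
table of biochemistry replicates, community matrices (samples × taxa or
species, integer counts), and a trait table. Readers validate headers up
front and fail with the offending column named, so a malformed input
aborts before any statistics run.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_samples", "read_community", "read_traits", "SchemaError"]

SAMPLE_COLUMNS = (
    "area",
    "state",
    "site",
    "replicate",
    "phytopigment_ug_g",
    "protein_mg_g",
    "carbohydrate_mg_g",
    "lipid_mg_g",
)
TRAIT_COLUMNS = ("name", "level", "guild", "cp_score", "biovol_factor")


class SchemaError(ValueError):
    """An input file does not match its declared schema."""


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing sample columns {missing}")
    return df


def read_community(path: str | Path) -> pd.DataFrame:
    """Read a samples × taxa count matrix keyed by ``sample_id``."""
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise SchemaError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    df = df.set_index("sample_id")
    if df.empty:
        return df.astype(int)  # header-only file: a valid empty matrix
    non_numeric = [
        c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])
    ]
    if non_numeric:
        raise SchemaError(f"{path}: non-numeric count columns {non_numeric}")
    if (df.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative counts present")
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing trait columns {missing}")
    bad_levels = set(df["level"].unique()) - {"taxon", "species"}
    if bad_levels:
        raise SchemaError(f"{path}: unknown trait levels {sorted(bad_levels)}")
    return df


def design_from_community(index: pd.Index) -> pd.DataFrame:
    """Recover area/state/site/replicate factors from sample_id labels of
    the form ``Area_State_Site_rN``."""
    rows = []
    for sid in index:
        parts = str(sid).split("_")
        if len(parts) != 4:
            raise SchemaError(f"sample_id {sid!r} is not 'area_state_site_rN'")
        rows.append(
            {"sample_id": sid, "area": parts[0], "state": parts[1],
             "site": parts[2], "replicate": parts[3]}
        )
    return pd.DataFrame(rows).set_index("sample_id")
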