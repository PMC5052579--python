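"""Biochemical composition of sedimentary organic matter.

Converts the four measured compound pools (phytopigments, proteins,
carbohydrates, lipids) to carbon equivalents, sums the three macromolecular
pools into biopolymeric carbon (BPC, the standard proxy for food available
to benthic consumers), and derives the three nutritional-quality
descriptors: the phytopigment and protein contributions to BPC (%) and the
protein-to-carbohydrate ratio.

Concentration units follow benthic-biogeochemistry convention: pigments in
``μg g⁻¹`` dry sediment, macromolecules in ``mg g⁻¹`` dry sediment, carbon
equivalents in ``mg C g⁻¹``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CarbonFactors",
    "carbon_equivalents",
    "biopolymeric_c",
    "quality_indicators",
    "derive_biochemistry",
]

#: Carbon content per unit mass of each macromolecular pool (mg C per mg).
#: Standard conversion factors of the sediment-biochemistry literature,
#: verified to reproduce published BPC tabulations; override via
#: :class:`CarbonFactors` if a different calibration is required.
DEFAULT_PROTEIN_C = 0.49
DEFAULT_CARBOHYDRATE_C = 0.40
DEFAULT_LIPID_C = 0.75

#: Phytopigment-to-carbon factor (μg C per μg pigment). Unlike the three
#: macromolecular factors this value is not anchored by a reproducible
#: published column (implied per-row factors are mutually inconsistent), so
#: any output depending on it is advisory; see ``quality_indicators``.
DEFAULT_PHYTOPIGMENT_C = 40.0


@dataclass(frozen=True)
class CarbonFactors:
    """Per-compound carbon-equivalent factors (mg C per mg compound).

    ``phytopigment`` is expressed in μg C per μg pigment.
    """

    protein: float = DEFAULT_PROTEIN_C
    carbohydrate: float = DEFAULT_CARBOHYDRATE_C
    lipid: float = DEFAULT_LIPID_C
    phytopigment: float = DEFAULT_PHYTOPIGMENT_C

    def __post_init__(self) -> None:
        for name in ("protein", "carbohydrate", "lipid", "phytopigment"):
            if not getattr(self, name) > 0:
                raise ValueError(f"carbon factor {name!r} must be strictly positive")


def _check_nonnegative(df: pd.DataFrame, columns: tuple[str, ...]) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise ValueError(f"negative concentration in column {col!r} (row {bad!r})")


def carbon_equivalents(
    records: pd.DataFrame, factors: CarbonFactors | None = None
) -> pd.DataFrame:
    """Convert raw concentrations to carbon equivalents.

    Parameters
    ----------
    records
        One row per sediment replicate with columns ``phytopigment_ug_g``,
        ``protein_mg_g``, ``carbohydrate_mg_g``, ``lipid_mg_g``.
    factors
        Carbon-equivalent factors; defaults to the standard protocol values
        (0.49 / 0.40 / 0.75 mg C per mg).

    Returns
    -------
    DataFrame with columns ``protein_c``, ``carbohydrate_c``, ``lipid_c``
    (mg C g⁻¹) and ``phytopigment_c`` (mg C g⁻¹, converted from μg).
    """
    factors = factors or CarbonFactors()
    required = ("phytopigment_ug_g", "protein_mg_g", "carbohydrate_mg_g", "lipid_mg_g")
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise KeyError(f"missing concentration columns: {missing}")
    _check_nonnegative(records, required)
    out = pd.DataFrame(index=records.index)
    out["protein_c"] = records["protein_mg_g"] * factors.protein
    out["carbohydrate_c"] = records["carbohydrate_mg_g"] * factors.carbohydrate
    out["lipid_c"] = records["lipid_mg_g"] * factors.lipid
    # μg pigment → μg C → mg C
    out["phytopigment_c"] = records["phytopigment_ug_g"] * factors.phytopigment / 1000.0
    return out


def biopolymeric_c(carbon: pd.DataFrame) -> pd.Series:
    """Biopolymeric carbon: the exact sum of protein, carbohydrate and
    lipid carbon equivalents (mg C g⁻¹)."""
    return carbon["protein_c"] + carbon["carbohydrate_c"] + carbon["lipid_c"]


def quality_indicators(records: pd.DataFrame, carbon: pd.DataFrame) -> pd.DataFrame:
    """Nutritional-quality descriptors of the sedimentary organic matter.

    * ``pct_protein_bpc`` — protein C as % of biopolymeric C.
    * ``pct_phyto_bpc`` — phytopigment C as % of biopolymeric C. This
      descriptor inherits the untrusted pigment-to-carbon factor and should
      be read as a relative, not absolute, index.
    * ``prt_cho_ratio`` — protein : carbohydrate on *raw mass*
      concentrations, the convention under which published tabulations are
      internally consistent (C-based ratios are not).

    Zero denominators yield NaN (reported as not-available downstream),
    never a division error.
    """
    bpc = biopolymeric_c(carbon)
    out = pd.DataFrame(index=records.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_protein_bpc"] = np.where(
            bpc > 0, 100.0 * carbon["protein_c"] / bpc, np.nan
        )
        out["pct_phyto_bpc"] = np.where(
            bpc > 0, 100.0 * carbon["phytopigment_c"] / bpc, np.nan
        )
        cho = records["carbohydrate_mg_g"].to_numpy(dtype=float)
        out["prt_cho_ratio"] = np.where(
            cho > 0, records["protein_mg_g"] / records["carbohydrate_mg_g"], np.nan
        )
    return out


def derive_biochemistry(
    records: pd.DataFrame, factors: CarbonFactors | None = None
) -> pd.DataFrame:
    """Full per-replicate derivation: C equivalents, BPC and quality
    descriptors, keeping any design columns (area/state/site/replicate)."""
    carbon = carbon_equivalents(records, factors)
    quality = quality_indicators(records, carbon)
    keep = [
        c
        for c in ("area", "state", "site", "replicate")
        if c in records.columns
    ]
    out = pd.concat([records[keep], carbon, quality], axis=1)
    out.insert(len(keep) + 3, "bpc_mg_g", biopolymeric_c(carbon))
    return out


def round_half_up(x, decimals: int = 1):
    """Round half away from zero, matching report-table presentation
    (numpy's bankers rounding would turn 0.25 → 0.2)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    rounded = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if rounded.ndim == 0:
        return float(rounded)
    return rounded
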