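"""Published per-site summary tables shipped with the package.

Three small report tables transcribed from the source study of this
system (Western–Central Mediterranean hard-bottom meadow/barren survey)
are bundled as package data and serve as regression anchors:

* ``table1a`` — per-site sediment biochemistry (means ± sd) with the
  published biopolymeric-C and nutritional-quality columns;
* ``table1b`` — per-site meiofaunal standing stocks, taxon richness,
  nematode diversity indices and trophic-group percentages;
* ``table3`` — Jaccard β-diversity partitions at the three contrast
  scales.

These are summaries (site means), not raw data; they anchor internal
identities (BPC sums, the Pielou relation, β-additivity, richness-loss
ranges), not full re-analysis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["table1a", "table1b", "table3"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("meiostates.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def table1a() -> pd.DataFrame:
    """Per-site organic-matter biochemistry (24 rows)."""
    return _load("table1a.csv")


def table1b() -> pd.DataFrame:
    """Per-site standing stocks and diversity indices (24 rows)."""
    return _load("table1b.csv")


def table3() -> pd.DataFrame:
    """Jaccard β-partitions at the site, state and area scales (20 rows)."""
    return _load("table3.csv")
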