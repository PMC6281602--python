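"""Published campaign-level input tables.

The per-day production table reproduces the printed rate measurements from
the Station ALOHA diel campaigns (summer 2015 at 15 m, spring 2016 at 25 m):
¹⁴C primary production, 2–20 µm size-fraction primary production, night-time
autotrophic respiration, and daily net TAG carbon production.  These printed
rates are inputs; the derived percentage contributions and campaign
summaries are recomputed by :mod:`dielflux.flux`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dielflux.flux import percent_of_pp

__all__ = ["station_aloha_production", "derive_production_percentages"]

_ROWS = [
    # date, season, depth_m, pp_14c, pp_14c_sd, pp_2_20, pp_2_20_sd, ar_night, tag_prod_c
    ("2015-07-27", "summer", 15.0, 17.6, 0.4, 5.4, 2.0, 7.6, 1.08),
    ("2015-07-28", "summer", 15.0, 14.9, 2.4, 2.9, 0.9, 5.2, 1.16),
    ("2015-07-29", "summer", 15.0, 16.9, 1.5, 4.3, 0.8, 6.2, 0.69),
    ("2015-08-01", "summer", 15.0, 14.7, 1.2, 3.2, 0.7, 6.1, 1.13),
    ("2016-03-25", "spring", 25.0, 5.8, 0.5, np.nan, np.nan, 1.8, 0.42),
    ("2016-03-26", "spring", 25.0, 5.0, 0.7, 2.7, 1.0, 0.7, 0.40),
    ("2016-03-27", "spring", 25.0, 5.8, 0.5, 3.3, 1.0, 2.6, 0.41),
]


def station_aloha_production() -> pd.DataFrame:
    """Per-day production rates (mg C m⁻³ d⁻¹) from the two cruises.

    The 2–20 µm fraction was not determined on 2016-03-25 (NaN).
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "date",
            "season",
            "depth_m",
            "pp_14c",
            "pp_14c_sd",
            "pp_2_20",
            "pp_2_20_sd",
            "ar_night",
            "tag_prod_c",
        ],
    )


def derive_production_percentages(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach %TAG-C of total and of 2–20 µm primary production."""
    t = station_aloha_production() if table is None else table.copy()
    t["pct_of_pp"] = percent_of_pp(t["tag_prod_c"], t["pp_14c"])
    t["pct_of_2_20"] = percent_of_pp(t["tag_prod_c"], t["pp_2_20"])
    return t
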