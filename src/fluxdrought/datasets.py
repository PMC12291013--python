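"""Small built-in reference tables.

``drought_2018_19_site_table`` carries the published per-site summary of
the 2018–19 Australian drought at the 14 OzFlux eddy-covariance sites
used throughout this package's worked examples: ecosystem group, relative
precipitation change (ΔP %), absolute and relative moisture-index change
(ΔMI, ΔMI %) between the pre-drought baseline and the drought window, and
the growing-year start month.  Severity classes are *not* stored — they
are recomputed from ΔMI % by :func:`fluxdrought.indices.classify_delta_mi`.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # site, group, delta_P_pct, delta_MI, delta_MI_pct, gy_start_month
    ("Sturt Plains", "grass", -56.0, -0.19, -58.0, 10),
    ("Yanco", "grass", -47.0, -0.13, -54.0, 1),
    ("Alice Springs Mulga", "very_dry", -66.0, -0.13, -68.0, 12),
    ("Calperum", "very_dry", -54.0, -0.09, -57.0, 1),
    ("Ti Tree East", "very_dry", -66.0, -0.11, -67.0, 12),
    ("Cumberland Plain", "dry", -32.0, -0.18, -36.0, 1),
    ("Gingin", "dry", -14.0, -0.04, -14.0, 6),
    ("Daly Uncleared", "seasonally_wet", -38.0, -0.24, -40.0, 10),
    ("Dry River", "seasonally_wet", -45.0, -0.23, -50.0, 11),
    ("Howard Springs", "seasonally_wet", -30.0, -0.34, -35.0, 9),
    ("Litchfield", "seasonally_wet", -35.0, -0.39, -38.0, 10),
    ("Robson Creek", "wet", 32.0, 0.30, 30.0, 2),
    ("Tumbarumba", "wet", -19.0, -0.34, -28.0, 6),
    ("Wombat Forest", "wet", 0.4, -0.02, -3.0, 5),
]


def drought_2018_19_site_table() -> pd.DataFrame:
    """Published 14-site drought summary (ΔP %, ΔMI, ΔMI %, start month)."""
    return pd.DataFrame(
        _ROWS,
        columns=["site", "group", "delta_P_pct", "delta_MI",
                 "delta_MI_pct", "gy_start_month"],
    ).set_index("site")
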