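"""Published summary tables from the U.S. EPA National Lakes Assessment.

The raw NLA site files are public downloads and are not bundled here; what
this module carries are the small printed national-scale summaries needed as
*inputs* to desk-scale computations: the national class-proportion estimates
for 2007 and 2012, the class-transition counts for the 401 lakes sampled in
both surveys, and the per-class TP/color quartiles of the 1013 classifiable
2012 lakes that calibrate the synthetic generator.

All proportions are percent of the lake population; TP is µg/L, true color
is platinum-cobalt units (PCU).
"""

from __future__ import annotations

import pandas as pd

#: National design-based class proportion estimates (percent ± SE), lakes ≥ 4 ha.
NATIONAL_ESTIMATES = pd.DataFrame(
    [
        ("blue", 2007, 45.7, 2.7),
        ("green", 2007, 20.8, 2.2),
        ("brown", 2007, 10.0, 1.7),
        ("murky", 2007, 23.5, 2.3),
        ("blue", 2012, 27.7, 3.0),
        ("green", 2012, 20.6, 2.4),
        ("brown", 2012, 16.4, 3.2),
        ("murky", 2012, 35.4, 3.6),
    ],
    columns=["category", "year", "proportion", "se"],
)

#: Class-transition counts for the 401 lakes sampled in both 2007 and 2012.
#: Rows are origin (2007) class, columns destination (2012) class.
TRANSITION_COUNTS = pd.DataFrame(
    [
        # blue  green  brown  murky
        [124, 43, 26, 11],  # blue origin
        [3, 69, 6, 33],  # green origin
        [3, 0, 11, 6],  # brown origin
        [0, 8, 2, 56],  # murky origin
    ],
    index=pd.Index(["blue", "green", "brown", "murky"], name="origin"),
    columns=pd.Index(["blue", "green", "brown", "murky"], name="destination"),
)

#: Per-class TP (µg/L) and color (PCU) quartiles of the 1013 classifiable
#: lakes in the 2012 survey: (Q1, median, Q3).
CLASS_QUARTILES = {
    "blue": {"tp": (10.0, 16.5, 24.0), "color": (7.5, 11.0, 15.0)},
    "green": {"tp": (45.0, 65.0, 124.0), "color": (11.0, 15.0, 18.0)},
    "brown": {"tp": (15.0, 20.0, 25.0), "color": (25.0, 30.0, 44.0)},
    "murky": {"tp": (59.0, 110.0, 297.5), "color": (25.0, 30.0, 38.0)},
}

#: Per-class median biomass (µg dry weight/L) of the 2012 survey, used to
#: calibrate the synthetic community generator.
CLASS_BIOMASS_MEDIANS = {
    "zooplankton": {"blue": 49.18, "green": 88.37, "brown": 54.66, "murky": 150.04},
    "phytoplankton": {"blue": 156.9, "green": 579.83, "brown": 211.61, "murky": 865.29},
}

#: Mean direction of per-lake (ΔTP, Δcolor) change among the 401 resampled
#: lakes, degrees counterclockwise from the +ΔTP axis. Used as the default
#: drift direction of the synthetic generator.
RESAMPLED_MEAN_ANGLE_DEG = 32.68

#: The nine aggregated Omernik level-III ecoregions of the survey design.
ECOREGIONS = (
    "Coastal Plains",
    "Northern Appalachians",
    "Southern Appalachians",
    "Northern Plains",
    "Southern Plains",
    "Temperate Plains",
    "Upper Midwest",
    "Western Mountains",
    "Xeric",
)
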