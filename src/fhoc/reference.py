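"""Reference constants shared across the package.

Holds the published percentile anchors (5th / 50th / 95th, in mm) for femoral
head ossification center (FHOC) size in healthy Korean children aged 0.5-11
years, and the twelve age bins used for age-stratified reporting.  The anchors
drive the synthetic cohort generator and serve as recovery targets for the
growth-chart fitting tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Ages (years) at which the reference anchors are tabulated.
ANCHOR_AGES: tuple[float, ...] = (0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)

# Per-sex anchor quantiles of FHOC size (mm) at the ages above.
_FEMALE_ANCHORS = {
    "q5_mm": (4.664, 6.887, 11.095, 14.987, 18.562, 21.821,
              24.764, 27.390, 29.701, 31.694, 33.372, 34.733),
    "q50_mm": (8.386, 10.662, 15.009, 19.082, 22.883, 26.410,
               29.664, 32.644, 35.352, 37.786, 39.947, 41.835),
    "q95_mm": (11.418, 13.836, 18.450, 22.768, 26.790, 30.516,
               33.946, 37.079, 39.917, 42.458, 44.703, 46.652),
}
_MALE_ANCHORS = {
    "q5_mm": (5.097, 7.397, 11.713, 15.649, 19.204, 22.379,
              25.174, 27.589, 29.624, 31.278, 32.552, 33.446),
    "q50_mm": (9.202, 11.420, 15.640, 19.571, 23.212, 26.565,
               29.628, 32.402, 34.887, 37.083, 38.990, 40.608),
    "q95_mm": (13.031, 15.425, 19.952, 24.130, 27.959, 31.438,
               34.567, 37.347, 39.778, 41.859, 43.591, 44.974),
}

#: Twelve age bins [lo, hi) in years used for subgroup reporting.  Infancy is
#: split more finely because FHOC growth is fastest there.
DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = (
    (0.5, 0.75), (0.75, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 5.0),
    (5.0, 6.0), (6.0, 7.0), (7.0, 8.0), (8.0, 9.0), (9.0, 10.0), (10.0, 11.0),
)

#: Quantile levels fitted by default for growth charts.
DEFAULT_TAUS: tuple[float, ...] = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)

SEXES = ("female", "male")
SIDES = ("left", "right")


def default_anchor_table() -> dict[str, pd.DataFrame]:
    """Anchor percentile table per sex.

    Returns
    -------
    dict mapping ``"female"``/``"male"`` to a DataFrame with columns
    ``age_years, q5_mm, q50_mm, q95_mm``.
    """
    out = {}
    for sex, data in (("female", _FEMALE_ANCHORS), ("male", _MALE_ANCHORS)):
        df = pd.DataFrame({"age_years": ANCHOR_AGES, **data})
        out[sex] = df
    return out


def validate_anchor_table(table: dict[str, pd.DataFrame]) -> None:
    """Check anchor-table invariants.

    Raises ``ValueError`` if quantiles cross (q5 >= q50 or q50 >= q95 at any
    age) or the median is not non-decreasing in age.
    """
    for sex, df in table.items():
        required = {"age_years", "q5_mm", "q50_mm", "q95_mm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"anchor table for {sex!r} missing columns {sorted(missing)}")
        q5 = np.asarray(df["q5_mm"], float)
        q50 = np.asarray(df["q50_mm"], float)
        q95 = np.asarray(df["q95_mm"], float)
        if not (np.all(q5 < q50) and np.all(q50 < q95)):
            raise ValueError(f"anchor quantiles cross for sex {sex!r}: require q5 < q50 < q95 at every age")
        if np.any(np.diff(q50) < 0):
            raise ValueError(f"anchor median must be non-decreasing in age for sex {sex!r}")
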