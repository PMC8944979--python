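"""Categorical skeletal-pattern labels from cephalometric angles.

The three label axes partition the real line; the clinically normal bands
are closed central intervals (``mean ± width``), and boundary values are
assigned to the central class:

* skeletal class (ANB): I on [0°, 4°], II above, III below;
* divergence: normodivergent on [40°, 42°], hypo below, hyper above;
* growth pattern (total gonial angle): normal on [115°, 125°], horizontal
  below (decreased angle), post-rotation above (increased angle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["PatternLabels", "classify", "classify_table",
           "SKELETAL_CLASSES", "DIVERGENCE_CLASSES", "GROWTH_CLASSES"]

SKELETAL_CLASSES = ("I", "II", "III")
DIVERGENCE_CLASSES = ("hypo", "normo", "hyper")
GROWTH_CLASSES = ("horizontal", "normal", "post_rotation")

ANB_BAND = (0.0, 4.0)          # 2 ± 2 degrees
DIVERGENCE_BAND = (40.0, 42.0)  # 41 ± 1 degrees
GONIAL_BAND = (115.0, 125.0)    # 120 ± 5 degrees


@dataclass(frozen=True)
class PatternLabels:
    skeletal_class: str
    divergence_class: str
    growth_class: str


def _band_label(x: float, band: tuple[float, float], below: str, central: str,
                above: str, name: str) -> str:
    if math.isnan(x):
        raise ValueError(f"{name} is NaN; labels are defined only for finite angles")
    if x < band[0]:
        return below
    if x > band[1]:
        return above
    return central


def classify(anb_deg: float, divergence_deg: float, gonial_deg_mean: float) -> PatternLabels:
    """Map the three angles (degrees) to their categorical pattern labels."""
    return PatternLabels(
        skeletal_class=_band_label(anb_deg, ANB_BAND, "III", "I", "II", "ANB"),
        divergence_class=_band_label(divergence_deg, DIVERGENCE_BAND,
                                     "hypo", "normo", "hyper", "divergence"),
        growth_class=_band_label(gonial_deg_mean, GONIAL_BAND,
                                 "horizontal", "normal", "post_rotation", "gonial angle"),
    )


def classify_table(df: pd.DataFrame, gonial_col: str = "gonial_deg") -> pd.DataFrame:
    """Append label columns to a table with ``anb_deg``, ``divergence_deg``
    and a gonial-angle column (mean of sides, or per-row value)."""
    out = df.copy()
    labels = [classify(r["anb_deg"], r["divergence_deg"], r[gonial_col])
              for _, r in df.iterrows()]
    out["skeletal_class"] = [l.skeletal_class for l in labels]
    out["divergence_class"] = [l.divergence_class for l in labels]
    out["growth_class"] = [l.growth_class for l in labels]
    return out
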