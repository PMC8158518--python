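"""Names and reference levels of the 21 lipoprotein main fractions.

The quantified variables are the apolipoproteins (Apo-A1, Apo-A2, Apo-B),
cholesterol, free cholesterol, phospholipids and triglycerides attributed to
the four density classes VLDL, IDL, LDL and HDL.  Concentrations are in
mg/dL throughout the package.

``GROUP_MEDIANS`` holds per-fraction median concentrations for healthy adult
blood donors, split by sex and by age group within sex (YM/OM = young/old
men, YW/OW = young/old women).  They are the default targets of the
synthetic cohort generator in :mod:`liponet.synthetic`.
"""

from __future__ import annotations

import pandas as pd

#: Canonical ordering of the 21 main fractions.
FRACTION_NAMES: tuple[str, ...] = (
    "Apo-A1 HDL",
    "Apo-A2 HDL",
    "Apo-B VLDL",
    "Apo-B IDL",
    "Apo-B LDL",
    "Cholesterol VLDL",
    "Cholesterol IDL",
    "Cholesterol LDL",
    "Cholesterol HDL",
    "Free cholesterol VLDL",
    "Free cholesterol IDL",
    "Free cholesterol LDL",
    "Free cholesterol HDL",
    "Phospholipids VLDL",
    "Phospholipids IDL",
    "Phospholipids LDL",
    "Phospholipids HDL",
    "Triglycerides VLDL",
    "Triglycerides IDL",
    "Triglycerides LDL",
    "Triglycerides HDL",
)

#: Density classes, used for the block-correlation structure of the
#: synthetic cohort and as a node attribute in exported networks.
LIPOPROTEIN_CLASSES: tuple[str, ...] = ("VLDL", "IDL", "LDL", "HDL")


def fraction_class(name: str) -> str:
    """Density class (VLDL/IDL/LDL/HDL) of a fraction, from its name."""
    for cls in LIPOPROTEIN_CLASSES:
        if name.endswith(cls):
            return cls
    return "unknown"


# Median concentrations (mg/dL) per study group, indexed by fraction.
_MEDIANS = {
    #                       M       W      YM      OM      YW      OW
    "Apo-A1 HDL":        (156.6, 176.8, 155.3, 160.1, 170.3, 184.0),
    "Apo-A2 HDL":        (26.8,  30.3,  26.2,  28.1,  28.6,  32.2),
    "Apo-B IDL":         (3.1,   2.6,   2.6,   3.9,   1.8,   3.2),
    "Apo-B LDL":         (61.1,  63.2,  55.9,  67.8,  51.9,  74.1),
    "Apo-B VLDL":        (6.6,   5.0,   5.4,   8.1,   4.7,   5.2),
    "Cholesterol HDL":   (66.7,  76.9,  66.4,  67.7,  73.8,  80.1),
    "Cholesterol IDL":   (6.9,   4.7,   5.6,   8.9,   3.1,   6.0),
    "Cholesterol LDL":   (154.8, 146.1, 153.3, 159.3, 124.6, 165.7),
    "Cholesterol VLDL":  (14.0,  9.0,   10.6,  18.1,  8.4,   8.9),
    "Free cholesterol HDL":  (13.4, 16.8, 12.9, 13.8, 16.2, 17.5),
    "Free cholesterol IDL":  (1.9,  1.4,  1.6,  2.6,  0.90, 1.8),
    "Free cholesterol LDL":  (40.0, 38.8, 38.8, 41.6, 33.4, 44.2),
    "Free cholesterol VLDL": (7.7,  5.7,  5.8,  9.7,  5.5,  5.9),
    "Phospholipids HDL":  (74.7, 93.3, 73.2, 77.0, 91.0, 96.3),
    "Phospholipids IDL":  (5.2,  3.9,  4.5,  6.435, 2.9, 4.7),
    "Phospholipids LDL":  (77.7, 76.3, 75.6, 81.1, 66.1, 86.0),
    "Phospholipids VLDL": (19.6, 14.0, 15.7, 24.1, 13.6, 14.2),
    "Triglycerides HDL":  (7.3,  9.2,  6.4,  8.2,  9.5,  9.1),
    "Triglycerides IDL":  (7.5,  5.2,  4.8,  10.7, 4.4,  5.5),
    "Triglycerides LDL":  (5.49, 8.1,  4.0,  7.5,  6.2,  9.5),
    "Triglycerides VLDL": (45.4, 29.7, 31.5, 61.1, 27.1, 29.8),
}

#: Reference median concentration (mg/dL) per fraction (rows, canonical
#: order) and study group (columns M, W, YM, OM, YW, OW).
GROUP_MEDIANS: pd.DataFrame = pd.DataFrame.from_dict(
    _MEDIANS, orient="index", columns=["M", "W", "YM", "OM", "YW", "OW"]
).loc[list(FRACTION_NAMES)]
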