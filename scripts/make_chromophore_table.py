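"""Regenerate the packaged chromophore absorption table.

Writes ``src/brunox/data/hb_water_extinction_synthetic.tsv``: a synthetic
1-nm reconstruction of the near-infrared specific absorption of
oxyhaemoglobin and deoxyhaemoglobin and of the absorption coefficient of
pure water, built by monotone (PCHIP) interpolation through anchor values
taken from the standard published compilations of haemoglobin molar
extinction and water absorption.  It reproduces the spectral features the
oximetry algorithms rely on — the HHb band at 760 nm, the rise of HbO2
through 800-900 nm, the isosbestic point near 800 nm, and the water bands
near 740 and 836 nm — but is not a verbatim copy of any measured dataset,
hence "synthetic" in the filename.

Output units (all natural-log convention):
  alpha_hbo2, alpha_hhb : mm^-1 per uM
  mua_water             : mm^-1 (pure water)

Haemoglobin anchors are base-10 molar extinction [cm^-1 M^-1]; conversion
to natural-log mm^-1 uM^-1 multiplies by ln(10) * 0.1 cm->mm * 1e-6 M->uM.
Water anchors are natural-log absorption [cm^-1]; conversion divides by 10.
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

# base-10 molar extinction, cm^-1 M^-1
HBO2_ANCHORS = [
    (650, 368), (660, 320), (670, 290), (680, 277), (690, 276),
    (700, 290), (710, 314), (720, 342), (730, 390), (740, 446),
    (750, 518), (760, 586), (770, 650), (780, 710), (790, 762),
    (800, 816), (810, 864), (820, 916), (830, 974), (840, 1022),
    (850, 1058), (860, 1092), (870, 1128), (880, 1154), (890, 1178),
    (900, 1198), (910, 1220), (920, 1264), (940, 1214), (960, 1156),
    (980, 1103), (1000, 1050),
]

HHB_ANCHORS = [
    (650, 3743), (660, 3227), (670, 2795), (680, 2407), (690, 2051),
    (700, 1794), (710, 1580), (720, 1410), (730, 1316), (740, 1325),
    (750, 1460), (755, 1590), (760, 1670), (765, 1610), (770, 1440),
    (780, 1170), (790, 944), (800, 762), (810, 718), (820, 694),
    (830, 690), (840, 693), (850, 691), (860, 726), (870, 740),
    (880, 761), (890, 780), (900, 792), (910, 800), (920, 810),
    (940, 816), (960, 818), (980, 820), (1000, 800),
]

# natural-log absorption of pure water, cm^-1
WATER_ANCHORS = [
    (650, 0.0032), (670, 0.0042), (690, 0.0052), (700, 0.0060),
    (710, 0.0073), (720, 0.0104), (730, 0.0170), (735, 0.0220),
    (740, 0.0266), (745, 0.0262), (750, 0.0257), (760, 0.0255),
    (770, 0.0248), (780, 0.0236), (790, 0.0221), (800, 0.0206),
    (810, 0.0214), (820, 0.0237), (830, 0.0325), (836, 0.0434),
    (840, 0.0428), (845, 0.0415), (850, 0.0405), (860, 0.0430),
    (870, 0.0480), (880, 0.0548), (890, 0.0610), (900, 0.0679),
    (910, 0.0762), (920, 0.1120), (930, 0.1700), (940, 0.2670),
    (950, 0.3200), (960, 0.3900), (970, 0.4500), (980, 0.4300),
    (990, 0.3900), (1000, 0.3600),
]

MOLAR_BASE10_CM_TO_MM_PER_UM = np.log(10.0) * 0.1 * 1e-6


def _interp(anchors, grid):
    wl, val = np.array(anchors, dtype=float).T
    return PchipInterpolator(wl, val)(grid)


def main() -> None:
    grid = np.arange(650.0, 1000.0 + 0.5, 1.0)
    hbo2 = _interp(HBO2_ANCHORS, grid) * MOLAR_BASE10_CM_TO_MM_PER_UM
    hhb = _interp(HHB_ANCHORS, grid) * MOLAR_BASE10_CM_TO_MM_PER_UM
    water = _interp(WATER_ANCHORS, grid) / 10.0

    out = Path(__file__).resolve().parents[1] / "src" / "brunox" / "data" / \
        "hb_water_extinction_synthetic.tsv"
    with out.open("w") as fh:
        fh.write("wavelength_nm\talpha_hbo2\talpha_hhb\tmua_water\n")
        for row in zip(grid, hbo2, hhb, water):
            fh.write("%.1f\t%.6e\t%.6e\t%.6e\n" % row)
    print(f"wrote {out} ({out.stat().st_size} bytes, {grid.size} rows)")


if __name__ == "__main__":
    main()
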