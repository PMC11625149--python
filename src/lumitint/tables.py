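"""Reproduction of the platform's printed calibration and contrast tables.

The reference characterization reports (a) six grey values with measured
optical power and luminance (the calibration anchors) and (b) the
per-condition stimulus/background bookkeeping at the dim and bright ends of
the usable range: wall and stimulus grey values, lens transmission and
alpha, behind-lens grey values and luminances, and Weber contrasts.  This
module stores those printed values and recomputes each derivable cell
through the calibration → lens chain so the two can be compared
side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    GreyLuminanceTable,
    build_grey_luminance_table,
    grey_from_luminance,
    reference_curve,
)
from .lens import alpha_from_transmission
from .protocol import LUM_BRIGHT, LUM_DIM, weber_contrast

__all__ = [
    "CALIBRATION_ANCHORS",
    "PRINTED_CONTRAST_ROWS",
    "printed_weber_contrasts",
    "reproduce_contrast_tables",
]

#: Measured calibration anchors: grey → (power μW, log10 power, luminance
#: cd/m², log10 luminance).
CALIBRATION_ANCHORS = pd.DataFrame(
    {
        "grey": [255, 192, 128, 64, 10, 0],
        "power_uw": [93.0, 48.0, 19.0, 4.3, 0.095, 0.013],
        "log10_power": [1.97, 1.68, 1.29, 0.63, -1.02, -1.89],
        "luminance": [140.0, 76.0, 30.0, 6.6, 0.14, 0.013],
        "log10_lum": [2.15, 1.88, 1.48, 0.82, -0.85, -1.89],
    }
)


@dataclass(frozen=True)
class _ContrastRow:
    table: str  # "dim" | "bright"
    lens: str
    transmission: float
    wall_grey: int  # pre-lens (original) grey
    stim_grey: int  # pre-lens stimulus grey used by the simulation chain
    printed_stim_grey: int  # as printed (sunglasses-dim prints 37; see note)
    printed_alpha: float
    printed_wall_lens_grey: int
    printed_stim_lens_grey: int
    printed_wall_lum: float
    printed_stim_lum: float
    printed_weber: float


#: The six condition rows of the dim- and bright-end contrast tables.  The
#: sunglasses-dim stimulus is simulated at grey 17, whose fitted luminance
#: (0.359 cd/m², 0.072 behind the 20 % lens) matches the printed behind-lens
#: luminance 0.07 and contrast 2.5; the printed grey 37 is inconsistent with
#: its own luminance column (fit luminance 1.97 cd/m²).
PRINTED_CONTRAST_ROWS = [
    _ContrastRow("dim", "normal", 0.95, 10, 14, 14, 0.0, 10, 14, 0.14, 0.24, 0.71),
    _ContrastRow("dim", "sunglasses", 0.20, 10, 17, 37, 0.8, 2, 7, 0.02, 0.07, 2.50),
    _ContrastRow("dim", "self_tint", 0.70, 10, 14, 14, 0.2, 8, 11, 0.09, 0.15, 0.67),
    _ContrastRow("bright", "normal", 0.95, 255, 230, 230, 0.016, 251, 226, 135.0, 105.0, -0.22),
    _ContrastRow("bright", "sunglasses", 0.20, 255, 230, 230, 0.506, 126, 113, 28.0, 22.0, -0.21),
    _ContrastRow("bright", "self_tint", 0.30, 255, 230, 230, 0.408, 151, 136, 41.0, 33.0, -0.20),
]


def printed_weber_contrasts() -> dict[tuple[str, str], float]:
    return {(r.table, r.lens): r.printed_weber for r in PRINTED_CONTRAST_ROWS}


def reproduce_contrast_tables(
    curve: CalibrationCurve | None = None,
) -> pd.DataFrame:
    """Recompute the contrast-table cells through the calibration chain.

    For each condition row the commanded wall luminance (140 or 0.14 cd/m²,
    the measured endpoints of the usable range) and the fitted stimulus
    luminance are attenuated by the lens transmission and pushed through the
    inverse lookup, yielding behind-lens greys, alphas and Weber contrasts.
    Contrasts are reported three ways: as printed, recomputed from the
    printed behind-lens luminances, and recomputed from the chain's
    behind-lens grey values.
    """
    curve = curve or reference_curve()
    table: GreyLuminanceTable = build_grey_luminance_table(curve)
    rows = []
    for r in PRINTED_CONTRAST_ROWS:
        wall_lum = LUM_DIM if r.table == "dim" else LUM_BRIGHT
        stim_lum = table.entry(r.stim_grey)
        wall_behind_grey, alpha = alpha_from_transmission(
            r.transmission, r.wall_grey, table, wall_lum=wall_lum
        )
        stim_behind_grey = grey_from_luminance(table, stim_lum * r.transmission)
        weber_printed_lums = round(
            weber_contrast(r.printed_stim_lum, r.printed_wall_lum), 2
        )
        weber_chain = weber_contrast(
            table.entry(stim_behind_grey), table.entry(wall_behind_grey)
        )
        rows.append(
            {
                "table": r.table,
                "lens": r.lens,
                "transmission": r.transmission,
                "wall_grey": r.wall_grey,
                "stim_grey": r.stim_grey,
                "printed_stim_grey": r.printed_stim_grey,
                "printed_wall_lens_grey": r.printed_wall_lens_grey,
                "chain_wall_lens_grey": wall_behind_grey,
                "printed_stim_lens_grey": r.printed_stim_lens_grey,
                "chain_stim_lens_grey": stim_behind_grey,
                "printed_alpha": r.printed_alpha,
                "chain_alpha": round(alpha, 3),
                "alpha_from_printed_grey": round(
                    1.0 - r.printed_wall_lens_grey / r.wall_grey, 3
                ),
                "printed_wall_lum": r.printed_wall_lum,
                "chain_wall_lum": wall_lum * r.transmission,
                "printed_stim_lum": r.printed_stim_lum,
                "chain_stim_lum": stim_lum * r.transmission,
                "printed_weber": r.printed_weber,
                "weber_from_printed_lums": weber_printed_lums,
                "weber_from_chain": round(float(weber_chain), 2),
            }
        )
    return pd.DataFrame(rows)
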