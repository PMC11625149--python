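"""Synthetic photometer-sweep fixtures.

Real calibration data are a photometer sweep over all 256 grey values with
three repeats each.  The generator here emulates the reference headset's
measured response: mean powers follow the in-package rational fit, with
band-dependent multiplicative repeat noise matching the reported relative
standard deviations — about 2 % for greys 17–255, about 5 % for 8–16 and
about 20 % for 0–7.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, PowerMeasurement, reference_curve

__all__ = ["NOISE_BANDS", "generate_calibration_fixture", "load_measurements", "measurements_from_frame"]

#: (grey_lo, grey_hi, relative SD) of repeat variability per grey band.
NOISE_BANDS = ((0, 7, 0.20), (8, 16, 0.05), (17, 255, 0.02))


def _band_sd(grey: np.ndarray) -> np.ndarray:
    sd = np.empty(grey.shape, dtype=float)
    for lo, hi, s in NOISE_BANDS:
        sd[(grey >= lo) & (grey <= hi)] = s
    return sd


def generate_calibration_fixture(
    seed: int = 0,
    n_repeats: int = 3,
    noise_scale: float = 1.0,
    curve: Optional[CalibrationCurve] = None,
    path: Optional[Path | str] = None,
) -> pd.DataFrame:
    """Synthetic sweep: columns grey, repeat, power_uW.

    Powers are drawn as mean × (1 + sd·z) with the band-dependent relative
    SD (scaled by ``noise_scale``; 0 reproduces the fit exactly), floored at
    a small positive value so log-transforms stay defined.
    """
    curve = curve or reference_curve()
    rng = np.random.default_rng(seed)
    grey = np.repeat(np.arange(256), n_repeats)
    repeat = np.tile(np.arange(n_repeats), 256)
    mean_power = 10.0 ** np.asarray(curve.log_power(grey), dtype=float)
    sd = _band_sd(grey) * noise_scale
    power = mean_power * (1.0 + sd * rng.standard_normal(len(grey)))
    power = np.maximum(power, 1e-6)
    df = pd.DataFrame({"grey": grey, "repeat": repeat, "power_uW": power})
    if path is not None:
        df.to_csv(path, index=False)
    return df


def measurements_from_frame(df: pd.DataFrame) -> list[PowerMeasurement]:
    return [
        PowerMeasurement(grey=int(r.grey), power=float(r.power_uW), repeat_index=int(r.repeat))
        for r in df.itertuples()
    ]


def load_measurements(path: Path | str) -> list[PowerMeasurement]:
    """Read a sweep CSV (columns grey, repeat, power_uW) into measurements."""
    df = pd.read_csv(path)
    missing = {"grey", "repeat", "power_uW"} - set(df.columns)
    if missing:
        raise ValueError(f"sweep file missing columns: {sorted(missing)}")
    return measurements_from_frame(df)
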