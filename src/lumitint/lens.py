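"""Spectacle-lens transmission models and the virtual light-sensor trigger.

Static lenses (clear "normal" lenses, sunglasses) pass a fixed fraction of
the incident light.  Self-tinting (electrochromic-style) lenses switch
between a clear state (transmission t_max, default 0.9) and a tinted state
(t_min, default 0.1) with first-order exponential kinetics

    clear → dark:  T(t) = (t_max − t_min)·exp(−k·t) + t_min
    dark → clear:  T(t) = −(t_max − t_min)·exp(−k·t) + t_max

where k is the rate constant in 1/s (fast lens 2.073, slow lens 0.691; the
response time to 90 % completion is ln(10)/k ≈ 1.11 s and 3.33 s).  Switching
is triggered by a binary light sensor reading the ambient (pre-lens)
luminance against a threshold (default 4 cd/m²) followed by an electronic
delay (default 100 ms).

On a display, a lens of transmission T in front of a surface of luminance L
is emulated by darkening the surface to L·T, i.e. re-rendering it at the
grey value whose calibrated luminance is nearest L·T and compositing an
opaque overlay with alpha = 1 − grey_behind/grey_original.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .calibration import CalibrationError, GreyLuminanceTable, grey_from_luminance

__all__ = [
    "SwitchDirection",
    "SwitchingProfile",
    "LensSpec",
    "LensState",
    "FAST_RATE",
    "SLOW_RATE",
    "transmission_at",
    "response_time",
    "sensor_trigger",
    "alpha_from_transmission",
    "fast_self_tinting",
    "slow_self_tinting",
    "normal_lens",
    "sunglasses",
]

FAST_RATE = 2.073  # 1/s, "fast" electrochromic lens
SLOW_RATE = 0.691  # 1/s, "slow" electrochromic lens
SENSOR_THRESHOLD = 4.0  # cd/m²
SENSOR_DELAY = 0.1  # s


class SwitchDirection(str, Enum):
    CLEAR_TO_DARK = "clear_to_dark"
    DARK_TO_CLEAR = "dark_to_clear"
    IDLE = "idle"


@dataclass(frozen=True)
class SwitchingProfile:
    """Kinetics of a self-tinting lens' transmission change."""

    shape: str = "exponential"  # "exponential" | "linear"
    t_max: float = 0.9
    t_min: float = 0.1
    rate: float = FAST_RATE  # 1/s (exponential) or transmission/s slope (linear)
    delay: float = SENSOR_DELAY  # s, electronic delay after the sensor fires

    def __post_init__(self) -> None:
        if not 0 < self.t_min < self.t_max <= 1:
            raise ValueError("require 0 < t_min < t_max ≤ 1")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if self.shape not in ("exponential", "linear"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class LensSpec:
    """A static or self-tinting lens as used in one experimental condition."""

    mode: str  # "static" | "self_tinting"
    static_transmission: Optional[float] = None  # normal 0.95, sunglasses 0.20
    profile: Optional[SwitchingProfile] = None
    sensor_threshold: float = SENSOR_THRESHOLD
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode == "static":
            if self.static_transmission is None or not 0 < self.static_transmission <= 1:
                raise ValueError("static mode requires static_transmission in (0, 1]")
        elif self.mode == "self_tinting":
            if self.profile is None:
                raise ValueError("self_tinting mode requires a SwitchingProfile")
        else:
            raise ValueError(f"unknown lens mode {self.mode!r}")

    @property
    def is_static(self) -> bool:
        return self.mode == "static"


@dataclass
class LensState:
    """Instantaneous lens state during a trial."""

    transmission: float
    direction: SwitchDirection = SwitchDirection.IDLE
    time_since_trigger: float = 0.0


def fast_self_tinting() -> LensSpec:
    return LensSpec(
        mode="self_tinting", profile=SwitchingProfile(rate=FAST_RATE), label="self_tint_fast"
    )


def slow_self_tinting() -> LensSpec:
    return LensSpec(
        mode="self_tinting", profile=SwitchingProfile(rate=SLOW_RATE), label="self_tint_slow"
    )


def normal_lens() -> LensSpec:
    return LensSpec(mode="static", static_transmission=0.95, label="normal")


def sunglasses() -> LensSpec:
    return LensSpec(mode="static", static_transmission=0.20, label="sunglasses")


def transmission_at(
    profile: SwitchingProfile, direction: SwitchDirection, t
) -> np.ndarray | float:
    """Transmission at time ``t`` (s) after switch onset.

    Accepts scalars or arrays.  Outside a switch (IDLE) the question is
    ill-posed; callers hold the steady-state value instead.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time since switch onset must be non-negative")
    span = profile.t_max - profile.t_min
    if profile.shape == "exponential":
        if direction is SwitchDirection.CLEAR_TO_DARK:
            out = span * np.exp(-profile.rate * t_arr) + profile.t_min
        elif direction is SwitchDirection.DARK_TO_CLEAR:
            out = -span * np.exp(-profile.rate * t_arr) + profile.t_max
        else:
            raise ValueError("transmission_at requires an active switch direction")
        # guard against float rounding nudging the exponential past the bounds
        out = np.clip(out, profile.t_min, profile.t_max)
    else:  # linear ramp at `rate` transmission units per second, clipped
        if direction is SwitchDirection.CLEAR_TO_DARK:
            out = np.clip(profile.t_max - profile.rate * t_arr, profile.t_min, profile.t_max)
        elif direction is SwitchDirection.DARK_TO_CLEAR:
            out = np.clip(profile.t_min + profile.rate * t_arr, profile.t_min, profile.t_max)
        else:
            raise ValueError("transmission_at requires an active switch direction")
    return out if out.ndim else float(out)


def response_time(profile: SwitchingProfile) -> float:
    """Time to complete 90 % of the transmission change.

    For exponential kinetics this is ln(10)/rate; for a linear ramp the full
    ramp duration (t_max − t_min)/rate is returned instead.
    """
    if profile.shape == "exponential":
        return math.log(10.0) / profile.rate
    return (profile.t_max - profile.t_min) / profile.rate


def sensor_trigger(
    times: Sequence[float],
    luminance: Sequence[float],
    threshold: float = SENSOR_THRESHOLD,
    delay: float = SENSOR_DELAY,
) -> Optional[tuple[float, SwitchDirection]]:
    """First threshold crossing of the ambient luminance, plus the delay.

    The binary sensor reads the pre-lens (wall) luminance.  The crossing time
    is interpolated between samples — linearly in log10 luminance, which is
    exact for the log-linear ramps this platform commands.  Returns
    ``(onset_time, switch_direction)`` or ``None`` when the series never
    crosses.  Falling below the threshold commands dark → clear (the scene
    went dark, the lens clears); rising above commands clear → dark.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(times, dtype=float)
    lum = np.asarray(luminance, dtype=float)
    if t.shape != lum.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("times and luminance must be equal-length 1-D series")
    above = lum > threshold
    flips = np.nonzero(above[1:] != above[:-1])[0]
    if len(flips) == 0:
        return None
    i = int(flips[0])
    # Log-space linear interpolation of the crossing instant.
    l0, l1 = math.log10(lum[i]), math.log10(lum[i + 1])
    frac = (math.log10(threshold) - l0) / (l1 - l0)
    t_cross = t[i] + frac * (t[i + 1] - t[i])
    direction = (
        SwitchDirection.DARK_TO_CLEAR if above[i] else SwitchDirection.CLEAR_TO_DARK
    )
    return t_cross + delay, direction


def alpha_from_transmission(
    transmission: float,
    wall_grey: int,
    lum_table: GreyLuminanceTable,
    wall_lum: Optional[float] = None,
) -> tuple[int, float]:
    """Convert a lens transmission into the display compositing pair.

    The luminance behind the lens is ``wall_lum × transmission`` (by default
    ``wall_lum`` is the calibrated raw luminance of ``wall_grey``; the trial
    scheduler passes the commanded wall luminance instead, which is what the
    platform actually drives).  The behind-lens grey is found by inverse
    lookup in the raw table and the overlay opacity is
    alpha = 1 − grey_behind/grey_original, clamped to [0, 1].
    """
    if not 0 < transmission <= 1:
        raise ValueError("transmission must lie in (0, 1]")
    if wall_grey == 0:
        raise CalibrationError("wall grey 0 is degenerate for alpha compositing")
    if not 0 < wall_grey <= 255:
        raise CalibrationError(f"wall grey {wall_grey} outside usable range")
    base = lum_table.entry(wall_grey) if wall_lum is None else wall_lum
    lum_behind = base * transmission
    lum_behind = min(max(lum_behind, lum_table.lum_min), lum_table.lum_max)
    grey_behind = grey_from_luminance(lum_table, lum_behind)
    alpha = 1.0 - grey_behind / wall_grey
    return grey_behind, float(min(max(alpha, 0.0), 1.0))
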