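"""Per-trial event timelines for the luminance-transition protocol.

A trial emulates an indoor–outdoor transition: the scene's light source (the
walls) ramps across three magnitudes of luminance at a constant log10 rate
(1 or 3 log10 units/s), a virtual light sensor triggers the self-tinting
lens, and once the target luminance is reached a small Gaussian blob
(FWHM 0.6°) fades in at 0.3 log10 units/s over 333 ms in one of four corners
(±10° eccentricity).  After (simulated) detection an interstimulus interval
of 4 s lets the visual system settle.  Everything is computed in closed form
on a continuous time axis and then sampled at the display frame rate, so
event times are frame-rate robust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationError, LinearizationTable, nearest_greys
from .lens import (
    LensSpec,
    SwitchDirection,
    fast_self_tinting,
    normal_lens,
    response_time,
    sensor_trigger,
    slow_self_tinting,
    sunglasses,
    transmission_at,
)

__all__ = [
    "StimulusSpec",
    "TrialConfig",
    "Timeline",
    "CORNERS",
    "build_wall_schedule",
    "stimulus_fade",
    "fade_start_luminance",
    "weber_contrast",
    "stimulus_profile",
    "run_trial",
    "build_session",
    "default_conditions",
    "dim_stimulus_grey",
]

CORNERS = ("upper_left", "upper_right", "lower_left", "lower_right")

#: Commanded endpoint luminances of the usable display range (cd/m²).
LUM_BRIGHT = 140.0
LUM_DIM = 0.14

#: Stimulus target greys per condition.  Bright backgrounds use grey 230 for
#: every lens.  Dim backgrounds use grey 14 except for sunglasses, whose
#: stimulus sits at grey 17 so that the behind-lens luminance (0.20 × 0.359
#: ≈ 0.07 cd/m²) realises the much higher Weber contrast (≈2.5) that keeps
#: the target just perceivable at that scotopic background level.
BRIGHT_STIM_GREY = 230
_DIM_STIM_GREY = {"sunglasses": 17}
_DIM_STIM_GREY_DEFAULT = 14


def dim_stimulus_grey(lens_label: str) -> int:
    return _DIM_STIM_GREY.get(lens_label, _DIM_STIM_GREY_DEFAULT)


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and dynamics of the low-contrast detection target."""

    target_grey: int
    fwhm: float = 0.6  # degrees
    eccentricity: float = 10.0  # degrees
    fade_rate: float = 0.3  # log10 units / s
    fade_duration: float = 0.333  # s
    corner: Optional[str] = None  # None → drawn per trial

    def __post_init__(self) -> None:
        if self.fwhm <= 0 or self.fade_rate <= 0 or self.fade_duration < 0:
            raise ValueError("fwhm and fade_rate must be positive, fade_duration ≥ 0")
        if self.corner is not None and self.corner not in CORNERS:
            raise ValueError(f"unknown corner {self.corner!r}")


@dataclass(frozen=True)
class TrialConfig:
    """Full specification of one trial."""

    direction: str  # "decrease" | "increase"
    ramp_rate: float  # log10 units / s
    lens: LensSpec
    stimulus: StimulusSpec
    lum_start: float = LUM_BRIGHT
    lum_end: float = LUM_DIM
    isi: float = 4.0  # s
    frame_rate: float = 90.0  # Hz
    stimulus_window: float = 4.0  # s of sampled frames after stimulus onset
    seed: int = 0
    condition: str = ""
    participant: str = "P00"
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("decrease", "increase"):
            raise ValueError(f"direction must be decrease/increase, got {self.direction!r}")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be positive")
        if self.lum_start <= 0 or self.lum_end <= 0:
            raise ValueError("luminances must be positive")
        if self.lum_start == self.lum_end:
            raise ValueError("lum_start and lum_end must differ")

    @property
    def ramp_duration(self) -> float:
        return abs(math.log10(self.lum_end / self.lum_start)) / self.ramp_rate


@dataclass
class Timeline:
    """Frame-wise record of one trial plus its labelled event times."""

    frames: pd.DataFrame
    events: dict[str, float]
    config: TrialConfig
    corner: str
    transmission_at_stim_onset: float

    @property
    def stim_onset(self) -> float:
        return self.events["stim_onset"]


def build_wall_schedule(
    lum_start: float,
    lum_end: float,
    ramp_rate: float,
    frame_rate: float,
    lin_table: Optional[LinearizationTable] = None,
    extra_duration: float = 0.0,
) -> pd.DataFrame:
    """Sample the wall-luminance ramp at the display frame rate.

    The commanded log10 luminance is linear in time between the endpoints
    with slope ±ramp_rate; duration = |Δlog10|/ramp_rate.  When a
    linearization table is given, each frame also carries the displayed
    output grey realizing the commanded luminance.  ``extra_duration``
    appends constant frames at the end luminance.
    """
    if ramp_rate <= 0 or frame_rate <= 0:
        raise ValueError("ramp_rate and frame_rate must be positive")
    if lum_start <= 0 or lum_end <= 0:
        raise CalibrationError("endpoint luminances must be positive")
    log0, log1 = math.log10(lum_start), math.log10(lum_end)
    duration = abs(log1 - log0) / ramp_rate
    n = int(math.floor((duration + extra_duration) * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    log_lum = np.where(
        t <= duration,
        log0 + (log1 - log0) * np.minimum(t, duration) / duration if duration > 0 else log1,
        log1,
    )
    frame = pd.DataFrame({"t": t, "wall_lum": 10.0**log_lum})
    if lin_table is not None:
        lo, hi = lin_table.log_lum_min, lin_table.log_lum_max
        if min(log0, log1) < lo - 0.02 or max(log0, log1) > hi + 0.02:
            raise CalibrationError("ramp endpoints outside the linearized range")
        clipped = np.clip(log_lum, lo, hi)
        frac = (clipped - lo) / (hi - lo)
        inp = np.rint(lin_table.grey_min + frac * (255 - lin_table.grey_min)).astype(int)
        frame["wall_grey"] = lin_table.output_grey[inp]
    return frame


def fade_start_luminance(
    target_lum: float, background_lum: float, fade_rate: float = 0.3, fade_duration: float = 0.333
) -> float:
    """Stimulus luminance at fade onset.

    The fade covers fade_rate × fade_duration log10 units ending at the
    target; the start lies on the background side of the target, so the
    contrast magnitude grows monotonically during the fade for both
    increments (dim target above background) and decrements (bright target
    below background).
    """
    if target_lum <= 0 or background_lum <= 0:
        raise ValueError("luminances must be positive")
    span = fade_rate * fade_duration
    sign = -1.0 if target_lum >= background_lum else 1.0
    return target_lum * 10.0 ** (sign * span)


def stimulus_fade(
    target_lum: float,
    background_lum: float,
    fade_rate: float = 0.3,
    fade_duration: float = 0.333,
    t=0.0,
) -> np.ndarray | float:
    """Stimulus luminance at time ``t`` (s) since fade onset.

    Log-linear ramp from the start luminance to ``target_lum`` over
    ``fade_duration``; constant at the target afterwards.
    """
    start = fade_start_luminance(target_lum, background_lum, fade_rate, fade_duration)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time since fade onset must be non-negative")
    if fade_duration == 0:
        out = np.full_like(t_arr, target_lum)
    else:
        frac = np.minimum(t_arr / fade_duration, 1.0)
        out = 10.0 ** (math.log10(start) + frac * (math.log10(target_lum) - math.log10(start)))
    return out if out.ndim else float(out)


def weber_contrast(stim_lum: float, background_lum: float):
    """Weber contrast (L_stim − L_bg)/L_bg; negative for decrements."""
    bg = np.asarray(background_lum, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background luminance must be positive")
    out = (np.asarray(stim_lum, dtype=float) - bg) / bg
    return out if out.ndim else float(out)


def stimulus_profile(spec: StimulusSpec, radial_offset) -> np.ndarray | float:
    """Relative intensity of the isotropic Gaussian blob at a radial offset (deg)."""
    r = np.asarray(radial_offset, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial offset must be non-negative")
    sigma = spec.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    out = np.exp(-(r**2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


def _initial_lens_state(lens: LensSpec, start_lum: float) -> tuple[float, SwitchDirection]:
    """Steady-state transmission before the ramp: dark when bright, clear when dark."""
    if lens.is_static:
        return lens.static_transmission, SwitchDirection.IDLE
    prof = lens.profile
    if start_lum > lens.sensor_threshold:
        return prof.t_min, SwitchDirection.CLEAR_TO_DARK
    return prof.t_max, SwitchDirection.DARK_TO_CLEAR


def run_trial(config: TrialConfig, lin_table: LinearizationTable) -> Timeline:
    """Compose one trial's full frame-wise timeline and event record."""
    lens = config.lens
    stim = config.stimulus
    lum_table = lin_table.lum_table

    ramp_dur = config.ramp_duration
    sched = build_wall_schedule(
        config.lum_start,
        config.lum_end,
        config.ramp_rate,
        config.frame_rate,
        lin_table,
        extra_duration=stim.fade_duration + config.stimulus_window,
    )
    t = sched["t"].to_numpy()
    wall_lum = sched["wall_lum"].to_numpy()

    events: dict[str, float] = {"ramp_start": 0.0, "ramp_end": ramp_dur}

    # --- lens transmission trace -------------------------------------------
    init_T, _ = _initial_lens_state(lens, config.lum_start)
    transmission = np.full_like(wall_lum, init_T)
    if not lens.is_static:
        trig = sensor_trigger(
            t, wall_lum, threshold=lens.sensor_threshold, delay=lens.profile.delay
        )
        if trig is not None:
            onset, direction = trig
            events["sensor_cross"] = onset - lens.profile.delay
            events["lens_onset"] = onset
            events["lens_90pct"] = onset + response_time(lens.profile)
            active = t >= onset
            transmission[active] = transmission_at(lens.profile, direction, t[active] - onset)

    # --- stimulus fade ------------------------------------------------------
    stim_onset = ramp_dur  # the stimulus fades in when the target luminance is reached
    events["stim_onset"] = stim_onset
    events["stim_full"] = stim_onset + stim.fade_duration
    target_lum = lum_table.entry(stim.target_grey)
    background = config.lum_end
    stim_lum = np.full_like(wall_lum, np.nan)
    vis = t >= stim_onset
    stim_lum[vis] = stimulus_fade(
        target_lum, background, stim.fade_rate, stim.fade_duration, t[vis] - stim_onset
    )
    weber = np.full_like(wall_lum, np.nan)
    weber[vis] = weber_contrast(stim_lum[vis], wall_lum[vis])

    # --- compositing trace --------------------------------------------------
    wall_grey = sched["wall_grey"].to_numpy()
    lum_behind = np.clip(wall_lum * transmission, lum_table.lum_min, lum_table.lum_max)
    grey_behind = nearest_greys(lum_table, lum_behind)
    alpha = np.clip(1.0 - grey_behind / np.maximum(wall_grey, 1), 0.0, 1.0)

    rng = np.random.default_rng(config.seed)
    corner = stim.corner or CORNERS[int(rng.integers(len(CORNERS)))]
    events["trial_end"] = float(t[-1]) + config.isi

    frames = pd.DataFrame(
        {
            "t": t,
            "wall_grey": wall_grey,
            "wall_lum": wall_lum,
            "transmission": transmission,
            "alpha": alpha,
            "grey_behind": grey_behind,
            "stim_lum": stim_lum,
            "weber": weber,
        }
    )
    T_onset = float(np.interp(stim_onset, t, transmission))
    return Timeline(
        frames=frames,
        events=events,
        config=config,
        corner=corner,
        transmission_at_stim_onset=T_onset,
    )


def default_conditions() -> list[tuple[LensSpec, float]]:
    """The 4 lens × 2 ramp-rate factorial of the assessment protocol."""
    lenses = [fast_self_tinting(), slow_self_tinting(), normal_lens(), sunglasses()]
    return [(lens, rate) for lens in lenses for rate in (3.0, 1.0)]


def build_session(
    conditions: Optional[Sequence[tuple[LensSpec, float]]] = None,
    trials_per_direction: int = 20,
    seed: int = 0,
    participant: str = "P00",
) -> list[TrialConfig]:
    """Ordered trial list for one participant.

    Per condition, ``trials_per_direction`` luminance decreases are tested
    consecutively, then the same number of increases.  The order of the
    conditions themselves is shuffled per participant seed; corners and any
    observer noise derive from per-trial seeds spawned from the same stream.
    """
    if conditions is None:
        conditions = default_conditions()
    if len(conditions) == 0:
        raise ValueError("conditions must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conditions))
    trials: list[TrialConfig] = []
    idx = 0
    for ci in order:
        lens, rate = conditions[ci]
        label = f"{lens.label or lens.mode}_{rate:g}logs"
        for direction in ("decrease", "increase"):
            if direction == "decrease":
                lum_start, lum_end = LUM_BRIGHT, LUM_DIM
                stim_grey = dim_stimulus_grey(lens.label)
            else:
                lum_start, lum_end = LUM_DIM, LUM_BRIGHT
                stim_grey = BRIGHT_STIM_GREY
            for _ in range(trials_per_direction):
                trials.append(
                    TrialConfig(
                        direction=direction,
                        ramp_rate=rate,
                        lens=lens,
                        stimulus=StimulusSpec(target_grey=stim_grey),
                        lum_start=lum_start,
                        lum_end=lum_end,
                        seed=int(rng.integers(2**31)),
                        condition=label,
                        participant=participant,
                        trial_index=idx,
                    )
                )
                idx += 1
    return trials
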