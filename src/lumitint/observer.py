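"""Synthetic observer and detection-time statistics.

The observer here is an explicitly synthetic stand-in for a human
participant: it exists so that the full pipeline (calibration → lens →
trial timeline → detection log → statistics) can be exercised and tested
end to end.  It is a simple mechanistic model, not a fit to human data:

* The baseline contrast threshold rises toward low luminance following a
  de Vries–Rose/Weber transition, θ(L) = θ_w·√(1 + L_half/L).
* An adaptation state tracks the log10 luminance behind the lens at a
  finite, direction-specific speed (dark adaptation much slower than light
  adaptation, in seconds per log10 unit).  The residual unadapted gap at
  stimulus onset inflates the threshold; the inflation decays exponentially
  with a time constant proportional to the gap, and more slowly the deeper
  the final level sits in the scotopic range.
* Detection occurs when the stimulus' Weber-contrast magnitude first
  exceeds the effective threshold; a Gaussian motor latency is added.

Detection-time statistics follow the conventions of the assessment
protocol: per-condition medians with interquartile ranges, exact Wilcoxon
signed-rank comparisons of per-participant medians between conditions, and
a one-sided unpaired t-test for learning effects across trial blocks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .protocol import Timeline, stimulus_fade, weber_contrast

__all__ = [
    "ObserverParams",
    "DetectionRecord",
    "simulate_detection",
    "simulate_session",
    "records_to_frame",
    "median_iqr",
    "summarize",
    "paired_test",
    "compare_conditions",
    "learning_effect",
    "LearningEffect",
]


@dataclass(frozen=True)
class ObserverParams:
    """Tunable parameters of the synthetic observer.

    ``contrast_threshold`` is the photopic Weber-contrast threshold;
    ``lum_half`` (cd/m²) sets where the threshold starts rising toward low
    light.  The adaptation taus are in seconds per log10 unit of luminance
    change; ``penalty_gain`` converts residual unadapted log-units into
    threshold inflation, and ``scotopic_slowdown`` lengthens the decay per
    log10 unit the onset level lies below ``lum_scotopic``.
    """

    contrast_threshold: float = 0.12
    motor_latency: float = 0.80  # s
    latency_sd: float = 0.15  # s
    adaptation_tau_dark: float = 0.5  # s per log10 unit
    adaptation_tau_light: float = 0.25  # s per log10 unit
    penalty_gain: float = 12.0
    penalty_exponent: float = 2.0  # threshold inflation grows as gap**exponent
    lum_half: float = 1.0  # cd/m²
    lum_scotopic: float = 0.1  # cd/m²
    scotopic_slowdown: float = 1.0  # per log10 unit below lum_scotopic
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.contrast_threshold, self.motor_latency, self.adaptation_tau_dark,
               self.adaptation_tau_light, self.lum_half, self.lum_scotopic) <= 0:
            raise ValueError("observer parameters must be positive")
        if self.latency_sd < 0 or self.penalty_gain < 0 or self.scotopic_slowdown < 0:
            raise ValueError("latency_sd, penalty_gain and scotopic_slowdown must be ≥ 0")


@dataclass(frozen=True)
class DetectionRecord:
    """Outcome of one trial."""

    participant_id: str
    condition: str
    direction: str
    trial_index: int
    corner: str
    reported_corner: str
    detection_time: float  # s from stimulus onset; NaN when missed
    correct: bool


def _adaptation_gap_at_onset(timeline: Timeline, params: ObserverParams) -> tuple[float, float, float]:
    """Track the adaptation state over the trial; return (gap, Lb_onset, signed).

    The state starts fully adapted to the pre-trial behind-lens level and
    moves toward the instantaneous behind-lens log10 luminance at a maximum
    speed of 1/tau log-units per second (dark- or light-direction tau).
    Returns the absolute residual gap at stimulus onset, the behind-lens
    luminance at onset, and the sign of (state − level) there (positive
    while adapting downward, i.e. to dark).
    """
    fr = timeline.frames
    t = fr["t"].to_numpy()
    lb = np.log10(fr["wall_lum"].to_numpy() * fr["transmission"].to_numpy())
    a = lb[0]
    onset = timeline.events["stim_onset"]
    rate_dark = 1.0 / params.adaptation_tau_dark
    rate_light = 1.0 / params.adaptation_tau_light
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        diff = lb[i] - a
        rate = rate_light if diff > 0 else rate_dark
        step = min(abs(diff), rate * dt)
        a += math.copysign(step, diff)
        if t[i] >= onset:
            break
    lb_onset = float(np.interp(onset, t, lb))
    signed = a - lb_onset
    return abs(signed), 10.0**lb_onset, signed


def _threshold_fn(timeline: Timeline, params: ObserverParams):
    """Closed-form effective threshold θ_eff(t since stimulus onset)."""
    gap, lum_onset, signed = _adaptation_gap_at_onset(timeline, params)
    theta0 = params.contrast_threshold * math.sqrt(1.0 + params.lum_half / lum_onset)
    if gap <= 1e-12 or params.penalty_gain == 0.0:
        return lambda ts: theta0, theta0
    tau = (params.adaptation_tau_dark if signed > 0 else params.adaptation_tau_light) * gap
    if signed > 0:  # adapting into darkness: slower still at scotopic levels
        depth = max(0.0, math.log10(params.lum_scotopic / lum_onset))
        tau *= 1.0 + params.scotopic_slowdown * depth

    inflation = params.penalty_gain * gap**params.penalty_exponent

    def theta(ts: float) -> float:
        return theta0 * (1.0 + inflation * math.exp(-ts / tau))

    return theta, theta0


def simulate_detection(
    timeline: Timeline,
    params: ObserverParams,
    rng: Optional[np.random.Generator] = None,
) -> DetectionRecord:
    """Turn one trial timeline into a detection record.

    The stimulus' Weber-contrast magnitude (closed form: log-linear fade to
    the target, constant background after the ramp) is compared against the
    effective threshold; the first crossing, refined by root bracketing
    between frames, plus a Gaussian motor latency gives the detection time.
    A trial whose contrast never reaches threshold within the stimulus
    window is recorded as missed.
    """
    cfg = timeline.config
    if rng is None:
        rng = np.random.default_rng(params.seed ^ cfg.seed)
    stim = cfg.stimulus
    target_lum = timeline.frames["stim_lum"].dropna().iloc[-1]
    background = cfg.lum_end

    def contrast_mag(ts: float) -> float:
        sl = stimulus_fade(target_lum, background, stim.fade_rate, stim.fade_duration, ts)
        return abs(weber_contrast(sl, background))

    theta, _ = _threshold_fn(timeline, params)
    horizon = cfg.stimulus_window + stim.fade_duration

    def h(ts: float) -> float:
        return contrast_mag(ts) - theta(ts)

    t_star: Optional[float] = None
    if h(0.0) >= 0.0:
        t_star = 0.0
    else:
        grid = np.linspace(0.0, horizon, max(int(horizon * cfg.frame_rate), 2))
        vals = np.array([h(ts) for ts in grid])
        pos = np.nonzero(vals >= 0)[0]
        if len(pos):
            i = int(pos[0])
            t_star = float(optimize.brentq(h, grid[i - 1], grid[i], xtol=1e-9))

    if t_star is None:
        return DetectionRecord(
            participant_id=cfg.participant,
            condition=cfg.condition,
            direction=cfg.direction,
            trial_index=cfg.trial_index,
            corner=timeline.corner,
            reported_corner="none",
            detection_time=float("nan"),
            correct=False,
        )
    latency = params.motor_latency + params.latency_sd * rng.standard_normal()
    dt = max(t_star + latency, 1e-6)
    return DetectionRecord(
        participant_id=cfg.participant,
        condition=cfg.condition,
        direction=cfg.direction,
        trial_index=cfg.trial_index,
        corner=timeline.corner,
        reported_corner=timeline.corner,
        detection_time=float(dt),
        correct=True,
    )


def simulate_session(
    trials: Sequence, lin_table, params: ObserverParams
) -> list[DetectionRecord]:
    """Run every trial of a session through the observer."""
    from .protocol import run_trial

    rng = np.random.default_rng(params.seed)
    return [simulate_detection(run_trial(cfg, lin_table), params, rng) for cfg in trials]


def records_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": r.participant_id,
                "condition": r.condition,
                "direction": r.direction,
                "trial": r.trial_index,
                "corner": r.corner,
                "response": r.reported_corner,
                "rt_s": r.detection_time,
                "correct": r.correct,
            }
            for r in records
        ]
    )


def median_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range with linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)


def summarize(
    records: Iterable[DetectionRecord],
    by: tuple[str, ...] = ("condition", "direction"),
) -> pd.DataFrame:
    """Per-condition median and IQR of correct detection times."""
    df = records_to_frame(records)
    df = df[df["correct"]]
    rows = []
    for keys, grp in df.groupby(list(by)):
        if grp.empty:
            continue
        med, iqr = median_iqr(grp["rt_s"])
        row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        row.update({"median_rt_s": med, "iqr_s": iqr, "n": len(grp)})
        rows.append(row)
    if not rows:
        warnings.warn("no correct detections to summarize")
    return pd.DataFrame(rows)


def paired_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "wilcoxon",
    alternative: str = "two-sided",
) -> float:
    """Paired comparison of two matched samples; returns the p-value.

    ``wilcoxon`` uses the exact signed-rank null distribution for N ≤ 25
    (zero differences dropped, classical Wilcoxon convention; identical
    samples give p = 1).  ``ttest`` switches to the paired t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if method == "ttest":
        return float(stats.ttest_rel(x, y, alternative=alternative).pvalue)
    if method != "wilcoxon":
        raise ValueError(f"unknown method {method!r}")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    n = len(d)
    no_ties = len(np.unique(np.abs(d))) == n
    if n <= 16:
        # Exact sign-flip null, valid with tied magnitudes (average ranks).
        ranks = stats.rankdata(np.abs(d))
        t_obs = ranks[d > 0].sum()
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        t_null = signs @ ranks
        p_ge = np.mean(t_null >= t_obs - 1e-12)
        p_le = np.mean(t_null <= t_obs + 1e-12)
        if alternative == "greater":
            return float(p_ge)
        if alternative == "less":
            return float(p_le)
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    mode = "exact" if n <= 25 and no_ties else "approx"
    return float(stats.wilcoxon(d, alternative=alternative, method=mode).pvalue)


def compare_conditions(
    records: Iterable[DetectionRecord],
    method: str = "wilcoxon",
    alternative: str = "two-sided",
    correction: Optional[str] = None,
) -> pd.DataFrame:
    """Pairwise condition comparisons of per-participant medians per direction.

    Participants must be present in every compared condition (paired design,
    N ≥ 3).  Multiple-comparison correction is off by default; ``"holm"``
    applies a Holm step-down within each direction panel.
    """
    df = records_to_frame(records)
    df = df[df["correct"]]
    med = (
        df.groupby(["direction", "condition", "participant"])["rt_s"]
        .median()
        .reset_index()
    )
    rows = []
    for direction, panel in med.groupby("direction"):
        pivot = panel.pivot(index="participant", columns="condition", values="rt_s")
        if pivot.isna().any().any():
            raise ValueError("unpaired participants across conditions")
        if len(pivot) < 3:
            raise ValueError("need N ≥ 3 participants for paired comparisons")
        pvals, pairs = [], []
        for c1, c2 in combinations(pivot.columns, 2):
            pvals.append(paired_test(pivot[c1], pivot[c2], method, alternative))
            pairs.append((c1, c2))
        if correction == "holm":
            order = np.argsort(pvals)
            m = len(pvals)
            adj = np.empty(m)
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, (m - rank) * pvals[i])
                adj[i] = min(running, 1.0)
            pvals = list(adj)
        elif correction is not None:
            raise ValueError(f"unknown correction {correction!r}")
        for (c1, c2), p in zip(pairs, pvals):
            rows.append(
                {"direction": direction, "condition_a": c1, "condition_b": c2, "p_value": p}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LearningEffect:
    mean_difference: float  # first block minus last block, s
    t_statistic: float
    p_value: float  # one-sided, direction: later block faster


def learning_effect(
    records: Iterable[DetectionRecord], block_size: int = 20
) -> LearningEffect:
    """One-sided unpaired t-test: are the last ``block_size`` increase trials faster?

    Increase-direction trials are ordered by trial index across the session;
    the first and last blocks are compared with a Student t-test under the
    alternative that the later block has shorter detection times.
    """
    df = records_to_frame(records)
    df = df[(df["direction"] == "increase") & df["correct"]].sort_values("trial")
    if len(df) < 2 * block_size:
        raise ValueError(
            f"need at least {2 * block_size} increase trials, got {len(df)}"
        )
    first = df["rt_s"].to_numpy()[:block_size]
    last = df["rt_s"].to_numpy()[-block_size:]
    res = stats.ttest_ind(first, last, equal_var=True, alternative="greater")
    return LearningEffect(
        mean_difference=float(first.mean() - last.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
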