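"""Display grey-value → luminance calibration and log-linearizing look-up tables.

A VR headset's display is driven with 8-bit achromatic grey values (0–255)
whose optical output is strongly non-linear.  This module models the measured
grey → optical-power response with a five-coefficient rational function

    f(g) = (a·g² + b·g + c) / (g² + d·g + e)        [log10 power in μW]

converts optical power to luminance with a single photometric scale factor
(cd/m² per μW), and builds the 256-entry look-up table (LUT) that remaps
requested grey values so that equal grey steps produce equal steps in
log10 luminance — the substrate for simulating smooth multi-magnitude
luminance ramps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PowerMeasurement",
    "CalibrationCurve",
    "GreyLuminanceTable",
    "LinearizationTable",
    "REFERENCE_COEFFICIENTS",
    "LUM_PER_UW",
    "reference_curve",
    "evaluate_log_power",
    "power_to_luminance",
    "fit_response",
    "build_grey_luminance_table",
    "grey_from_luminance",
    "build_linearization_table",
    "contrast_ratio",
    "CalibrationError",
]

#: Rational-fit coefficients (a, b, c, d, e) of the reference headset's
#: grey → log10(power/μW) response.
REFERENCE_COEFFICIENTS = (7.04, 1706.0, -63550.0, 1274.0, 30270.0)

#: Photometric scale anchoring luminance to optical power, fixed by the
#: measured pair at full drive: 140 cd/m² at 93 μW.
LUM_PER_UW = 140.0 / 93.0

#: Directly measured grey → luminance anchors (cd/m²) used to validate the
#: power-based calibration and as the commanded endpoint luminances of the
#: usable range.
MEASURED_LUMINANCE = {255: 140.0, 192: 76.0, 128: 30.0, 64: 6.6, 10: 0.14, 0: 0.013}

GREY_MIN_USABLE = 10
#: Target log10-luminance endpoints of the usable range (3 magnitudes).
LOG_LUM_MIN = -0.85
LOG_LUM_MAX = 2.15


class CalibrationError(ValueError):
    """Raised for degenerate calibration data or out-of-domain queries."""


@dataclass(frozen=True)
class PowerMeasurement:
    """One photometer reading: optical power at a driven grey value."""

    grey: int
    power: float  # μW
    repeat_index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.grey <= 255:
            raise CalibrationError(f"grey {self.grey} outside 0–255")
        if self.power <= 0:
            raise CalibrationError(f"power must be positive, got {self.power}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted rational grey → log10-power response plus the luminance scale."""

    a: float
    b: float
    c: float
    d: float
    e: float
    lum_per_uw: float = LUM_PER_UW

    @property
    def coefficients(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e)

    def log_power(self, grey) -> np.ndarray | float:
        """Vectorised rational evaluation without the domain check."""
        g = np.asarray(grey, dtype=float)
        out = (self.a * g**2 + self.b * g + self.c) / (g**2 + self.d * g + self.e)
        return out if out.ndim else float(out)

    def luminance(self, grey) -> np.ndarray | float:
        """Fit-predicted luminance in cd/m² at a grey value."""
        lp = self.log_power(grey)
        return self.lum_per_uw * 10.0 ** np.asarray(lp) if np.ndim(lp) else self.lum_per_uw * 10.0**lp

    def validate(self) -> None:
        g = np.arange(256, dtype=float)
        denom = g**2 + self.d * g + self.e
        if np.any(denom <= 0):
            raise CalibrationError("rational denominator not positive on [0, 255]")
        y = self.log_power(g)
        if np.any(np.diff(y) <= 0):
            raise CalibrationError("fitted response is not strictly increasing on [0, 255]")
        if self.lum_per_uw <= 0:
            raise CalibrationError("lum_per_uw must be positive")


def reference_curve() -> CalibrationCurve:
    """The in-package preset curve from the reference headset characterization."""
    return CalibrationCurve(*REFERENCE_COEFFICIENTS)


def evaluate_log_power(curve: CalibrationCurve, grey: float) -> float:
    """log10 optical power (μW) predicted by the fit at an in-range grey value."""
    if not 0 <= grey <= 255:
        raise CalibrationError(f"grey {grey} outside 0–255")
    return float(curve.log_power(grey))


def power_to_luminance(curve: CalibrationCurve, power: float) -> float:
    """Convert optical power (μW) to luminance (cd/m²) by the linear scale."""
    if power < 0:
        raise CalibrationError(f"power must be non-negative, got {power}")
    return power * curve.lum_per_uw


def contrast_ratio(l_high: float, l_low: float) -> float:
    """Dynamic-range ratio l_high / l_low of two luminances."""
    if l_low <= 0:
        raise CalibrationError("l_low must be positive")
    return l_high / l_low


def _aggregate_log_means(measurements: Iterable[PowerMeasurement]) -> tuple[np.ndarray, np.ndarray]:
    df = pd.DataFrame(
        [(m.grey, m.power) for m in measurements], columns=["grey", "power"]
    )
    if df.empty:
        raise CalibrationError("no measurements supplied")
    means = df.groupby("grey")["power"].mean()
    greys = means.index.to_numpy(dtype=float)
    return greys, np.log10(means.to_numpy(dtype=float))


def fit_response(
    measurements: Iterable[PowerMeasurement],
    lum_per_uw: float = LUM_PER_UW,
) -> CalibrationCurve:
    """Least-squares fit of log10 mean power vs grey to the rational form.

    Repeats at the same grey are averaged in linear power first (the sweep
    protocol records three repeats per grey); the fit is unweighted on the
    log10 of those per-grey means.  Initialisation uses Sanathanan–Koerner
    iterations of the linearisation y·(g²+d·g+e) = a·g²+b·g+c (each pass
    reweighted by the previous denominator, which removes the strong bias of
    the plain linearised solve); refinement then runs in a denominator
    parameterisation (g+p)(g+q) with p, q > 0, which structurally excludes
    poles on the grey range.
    """
    greys, y = _aggregate_log_means(measurements)
    if len(greys) < 10:
        raise CalibrationError(
            f"need ≥10 distinct grey values spanning the range, got {len(greys)}"
        )
    if greys.max() - greys.min() < 128:
        raise CalibrationError("measurements must span most of [0, 255]")

    # Sanathanan–Koerner: a·g² + b·g + c − d·(g·y) − e·y = y·g², each row
    # divided by the previous iteration's denominator estimate.
    A = np.column_stack([greys**2, greys, np.ones_like(greys), -greys * y, -y])
    rhs = y * greys**2
    denom_prev = np.ones_like(greys)
    theta = None
    try:
        for _ in range(20):
            w = 1.0 / np.abs(denom_prev)
            theta, *_ = np.linalg.lstsq(A * w[:, None], rhs * w, rcond=None)
            denom_new = greys**2 + theta[3] * greys + theta[4]
            if np.any(denom_new == 0):
                break
            if np.max(np.abs(denom_new / denom_prev - 1.0)) < 1e-10:
                denom_prev = denom_new
                break
            denom_prev = denom_new
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise CalibrationError(f"degenerate calibration data: {exc}") from exc

    # Denominator roots → positive pole offsets p, q (fall back to the
    # symmetric split when the SK roots are complex or non-negative).
    d0, e0 = theta[3], theta[4]
    disc = d0 * d0 - 4.0 * e0
    if disc >= 0:
        r1 = (-d0 + math.sqrt(disc)) / 2.0
        r2 = (-d0 - math.sqrt(disc)) / 2.0
        p0, q0 = max(-r1, 1e-3), max(-r2, 1e-3)
    else:
        p0 = q0 = max(math.sqrt(abs(e0)), 1e-3)

    def residual(x: np.ndarray) -> np.ndarray:
        a, b, c, lp, lq = x
        p, q = np.exp(lp), np.exp(lq)
        denom = (greys + p) * (greys + q)
        return (a * greys**2 + b * greys + c) / denom - y

    x0 = np.array([theta[0], theta[1], theta[2], math.log(p0), math.log(q0)])
    sol = least_squares(residual, x0, method="lm", max_nfev=20000)
    p, q = np.exp(sol.x[3]), np.exp(sol.x[4])
    curve = CalibrationCurve(
        sol.x[0], sol.x[1], sol.x[2], p + q, p * q, lum_per_uw=lum_per_uw
    )
    try:
        curve.validate()
    except CalibrationError as exc:
        raise CalibrationError(
            f"fit produced an invalid response ({exc}); data may be non-monotone"
        ) from exc
    return curve


@dataclass(frozen=True)
class GreyLuminanceTable:
    """256-entry raw (un-linearized) grey → luminance response in cd/m²."""

    luminance: np.ndarray  # shape (256,)
    curve: CalibrationCurve

    def entry(self, grey: int) -> float:
        if not 0 <= grey <= 255:
            raise CalibrationError(f"grey {grey} outside 0–255")
        return float(self.luminance[int(grey)])

    @property
    def lum_min(self) -> float:
        return float(self.luminance[0])

    @property
    def lum_max(self) -> float:
        return float(self.luminance[255])


def build_grey_luminance_table(curve: CalibrationCurve) -> GreyLuminanceTable:
    """Tabulate the fitted raw response: entry(g) = lum_per_uw · 10^f(g)."""
    curve.validate()
    g = np.arange(256, dtype=float)
    lum = curve.lum_per_uw * 10.0 ** np.asarray(curve.log_power(g), dtype=float)
    lum.setflags(write=False)
    return GreyLuminanceTable(luminance=lum, curve=curve)


def grey_from_luminance(table: GreyLuminanceTable, target: float) -> int:
    """Inverse lookup: the grey whose raw luminance is nearest the target.

    Distance is measured in linear luminance; exact midpoints resolve to the
    lower grey.  The target must lie inside the table's luminance span.
    """
    if not table.lum_min <= target <= table.lum_max:
        raise CalibrationError(
            f"target {target} cd/m² outside displayable range "
            f"[{table.lum_min:.4g}, {table.lum_max:.4g}]"
        )
    # argmin returns the first (lower) index on ties.
    return int(np.argmin(np.abs(table.luminance - target)))


def nearest_greys(table: GreyLuminanceTable, targets: np.ndarray) -> np.ndarray:
    """Vectorised inverse lookup for many luminance targets (same metric)."""
    t = np.asarray(targets, dtype=float)
    if np.any((t < table.lum_min) | (t > table.lum_max)):
        raise CalibrationError("targets outside displayable range")
    hi = np.clip(np.searchsorted(table.luminance, t), 1, 255)
    lo = hi - 1
    pick_lo = (t - table.luminance[lo]) <= (table.luminance[hi] - t)
    return np.where(pick_lo, lo, hi)


@dataclass(frozen=True)
class LinearizationTable:
    """Grey → grey LUT realizing a log-linear luminance ramp over the usable range."""

    output_grey: np.ndarray  # shape (256,), int
    target_log_lum: np.ndarray  # shape (256,), log10 cd/m² (clamped below grey_min)
    grey_min: int
    log_lum_min: float
    log_lum_max: float
    lum_table: GreyLuminanceTable = field(repr=False)

    def map_grey(self, input_grey: int) -> int:
        if not 0 <= input_grey <= 255:
            raise CalibrationError(f"grey {input_grey} outside 0–255")
        return int(self.output_grey[int(input_grey)])

    def realized_luminance(self, input_grey: int) -> float:
        return self.lum_table.entry(self.map_grey(input_grey))

    def grey_for_log_luminance(self, log_lum: float) -> int:
        """Continuous inverse of the target line, rounded to the nearest input grey."""
        lo, hi = self.log_lum_min, self.log_lum_max
        if not min(lo, hi) - 1e-9 <= log_lum <= max(lo, hi) + 1e-9:
            raise CalibrationError(f"log luminance {log_lum} outside target range")
        frac = (log_lum - lo) / (hi - lo)
        return int(round(self.grey_min + frac * (255 - self.grey_min)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "input_grey": np.arange(256),
                "output_grey": self.output_grey,
                "target_log10_lum": self.target_log_lum,
                "realized_lum": self.lum_table.luminance[self.output_grey],
            }
        )


def build_linearization_table(
    curve: CalibrationCurve,
    grey_min: int = GREY_MIN_USABLE,
    log_lum_min: float = LOG_LUM_MIN,
    log_lum_max: float = LOG_LUM_MAX,
) -> LinearizationTable:
    """Build the log-linearizing LUT.

    Inputs in [grey_min, 255] target log-luminances linear in the input grey
    between ``log_lum_min`` and ``log_lum_max``; each target is realized by the
    nearest raw-table entry.  Greys below ``grey_min`` are excluded from the
    usable range (high measurement variability, coarse luminance steps) and
    clamp to the mapping of ``grey_min``.
    """
    if not 0 <= grey_min < 255:
        raise CalibrationError("grey_min must lie in [0, 255)")
    if log_lum_min >= log_lum_max:
        raise CalibrationError("log_lum_min must be below log_lum_max")
    table = build_grey_luminance_table(curve)
    if not (table.lum_min <= 10.0**log_lum_min and 10.0**log_lum_max <= table.lum_max):
        raise CalibrationError("target luminance range exceeds the displayable range")

    inp = np.arange(256)
    frac = (np.clip(inp, grey_min, 255) - grey_min) / (255 - grey_min)
    target_log = log_lum_min + frac * (log_lum_max - log_lum_min)
    out = np.array([grey_from_luminance(table, 10.0**t) for t in target_log], dtype=int)
    out.setflags(write=False)
    target_log.setflags(write=False)
    return LinearizationTable(
        output_grey=out,
        target_log_lum=target_log,
        grey_min=grey_min,
        log_lum_min=log_lum_min,
        log_lum_max=log_lum_max,
        lum_table=table,
    )
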