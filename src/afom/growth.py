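"""Viable-count arithmetic, growth-phase classification and per-cell fluorescence.

Couples CFU ml^-1 growth curves to peak fluorescence: converts plate counts
to CFU ml^-1, partitions a curve into lag / exponential / stationary phases
by log10-slope thresholds, and expresses fluorescence per 10^6 cells
(f_QSU/CFU), the enumeration-corrected quantity used to compare conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError
from .peaks import PeakSeries

logger = logging.getLogger(__name__)

#: Scale for enumeration correction: fluorescence is reported per 10^6 CFU.
CFU_SCALE = 1e6


@dataclass
class GrowthCurve:
    """Time-stamped viable counts for one replicate of one condition."""

    times_h: np.ndarray
    cfu_per_ml: np.ndarray
    replicate: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.cfu_per_ml, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise InputError("times and counts must be matching 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if np.any(~np.isfinite(c)) or np.any(c <= 0):
            raise InputError(
                "CFU ml^-1 must be positive and finite at every observed point; "
                "drop below-detection observations before constructing the curve"
            )
        self.times_h = t
        self.cfu_per_ml = c

    def __len__(self) -> int:
        return int(self.times_h.size)


@dataclass(frozen=True)
class PhaseAnnotation:
    """One growth phase and its closed time interval (h)."""

    phase: str  # "lag" | "exponential" | "stationary"
    interval: tuple[float, float]


@dataclass(frozen=True)
class PerCellFluorescence:
    """Enumeration-corrected fluorescence: QSU per 10^6 CFU, with log10."""

    f: float
    log10_f: float  # NaN when f <= 0
    peak: str | None = None
    time_h: float | None = None


def cfu_from_plate(colonies: int, dilution_factor: float, plated_volume_ml: float) -> float:
    """CFU ml^-1 from a plate count: ``colonies * dilution / volume``.

    Zero colonies gives 0.0, to be treated as below detection by callers.
    """
    if colonies < 0:
        raise InputError("colony count cannot be negative")
    if dilution_factor < 1:
        raise InputError("dilution factor must be >= 1")
    if not (plated_volume_ml > 0):
        raise InputError("plated volume must be positive")
    return colonies * dilution_factor / plated_volume_ml


def per_cell_fluorescence(
    qsu: float,
    cfu_per_ml: float,
    peak: str | None = None,
    time_h: float | None = None,
) -> PerCellFluorescence:
    """f = QSU / (CFU ml^-1 / 10^6): fluorescence per million viable cells."""
    if not (cfu_per_ml > 0):
        raise InputError(
            f"per-cell fluorescence undefined for CFU ml^-1 = {cfu_per_ml!r}"
        )
    f = qsu / (cfu_per_ml / CFU_SCALE)
    log10_f = math.log10(f) if f > 0 else float("nan")
    return PerCellFluorescence(f=f, log10_f=log10_f, peak=peak, time_h=time_h)


def per_cell_series(series: PeakSeries, curve: GrowthCurve) -> pd.DataFrame:
    """Per-time f_QSU/CFU for every peak in the series.

    The fluorescence and growth observations must share the same sampling
    times.
    """
    if len(curve) != series.times_h.size or not np.allclose(
        curve.times_h, series.times_h, rtol=0, atol=1e-9
    ):
        raise InputError(
            f"growth times do not match fluorescence times for replicate "
            f"{series.replicate!r} of condition {series.condition!r}"
        )
    frame = series.values.div(curve.cfu_per_ml / CFU_SCALE, axis=0)
    frame.index.name = "time_h"
    return frame


def classify_phases(
    curve: GrowthCurve,
    lag_slope_max: float = 0.05,
    stat_slope_max: float = 0.05,
) -> list[PhaseAnnotation]:
    """Partition a growth curve into lag, exponential and stationary phases.

    Piecewise slopes of log10(CFU) between consecutive observations drive
    the classification: the initial run of slopes below ``lag_slope_max``
    (log10 h^-1) is lag; the following run of slopes at or above
    ``stat_slope_max`` is exponential; the remainder is stationary. The
    returned intervals partition the observed range; lag or stationary may
    be zero-length. A curve with no slope reaching ``lag_slope_max`` is a
    single lag phase spanning the range (logged as a warning).
    """
    if len(curve) < 4:
        raise InsufficientDataError(
            f"phase classification needs >= 4 time points, got {len(curve)}"
        )
    t = curve.times_h
    slopes = np.diff(np.log10(curve.cfu_per_ml)) / np.diff(t)
    growing = slopes >= lag_slope_max
    if not growing.any():
        logger.warning(
            "no exponential phase detected (all slopes < %g log10/h)", lag_slope_max
        )
        return [PhaseAnnotation("lag", (float(t[0]), float(t[-1])))]
    k = int(np.argmax(growing))  # first growing interval ends the lag
    m = k
    while m < slopes.size and slopes[m] >= stat_slope_max:
        m += 1
    return [
        PhaseAnnotation("lag", (float(t[0]), float(t[k]))),
        PhaseAnnotation("exponential", (float(t[k]), float(t[m]))),
        PhaseAnnotation("stationary", (float(t[m]), float(t[-1]))),
    ]


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    """Read growth curves from delimited text.

    Columns: ``time_h`` plus either ``cfu_per_ml`` or the plate-count triple
    ``colonies, dilution, volume_ml`` (converted via :func:`cfu_from_plate`);
    optional ``replicate`` and ``condition`` split the file into one curve
    per (condition, replicate). Zero counts are below detection and dropped
    with a warning.
    """
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    if "time_h" not in frame.columns:
        raise InputError(f"{path}: missing required column 'time_h'")
    if "cfu_per_ml" not in frame.columns:
        triple = {"colonies", "dilution", "volume_ml"}
        if not triple.issubset(frame.columns):
            raise InputError(
                f"{path}: need column 'cfu_per_ml' or columns {sorted(triple)}"
            )
        frame["cfu_per_ml"] = [
            cfu_from_plate(int(c), float(d), float(v))
            for c, d, v in zip(frame["colonies"], frame["dilution"], frame["volume_ml"])
        ]
    below = frame["cfu_per_ml"] <= 0
    if below.any():
        logger.warning(
            "%s: dropped %d below-detection observation(s)", path, int(below.sum())
        )
        frame = frame[~below]
    keys = [k for k in ("condition", "replicate") if k in frame.columns]
    groups = frame.groupby(keys, sort=True) if keys else [((), frame)]
    curves = []
    for key, grp in groups:
        key = (key,) if not isinstance(key, tuple) else key
        labels = dict(zip(keys, [str(k) for k in key]))
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                grp["time_h"].to_numpy(),
                grp["cfu_per_ml"].to_numpy(),
                replicate=labels.get("replicate"),
                condition=labels.get("condition"),
            )
        )
    return curves


def write_growth_curve(curve: GrowthCurve, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "time_h": curve.times_h,
            "cfu_per_ml": curve.cfu_per_ml,
            "replicate": curve.replicate or "",
            "condition": curve.condition or "",
        }
    )
    frame.to_csv(path, index=False, float_format="%.10g")
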