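"""Coble-style peak regions and their quantification on corrected EEMs.

The peak-picking convention follows common dissolved-organic-matter usage:
a peak is an emission cross-section at one excitation wavelength, averaged
over an emission band. The bands used here:

=====  ==============  ==================  =========================
Peak   Excitation nm   Emission band nm    Interpretation
=====  ==============  ==================  =========================
T      275             340 (point)         tryptophan-like, protein
B      275             305 (point)         tyrosine-like, protein
C      340             420-470             humic-like
C+     400             470-505             humic-like, red-shifted
M      300             370-420             marine humic-like
=====  ==============  ==================  =========================

Point peaks read the single nearest emission pixel; a configurable band
half-width widens them when an averaged window is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eem import EEMatrix, nearest_index
from .errors import InputError, QualityError, RangeError, UndefinedBaselineError, UnitError


@dataclass(frozen=True)
class PeakDefinition:
    """A named optical region: one excitation wavelength and an emission band.

    ``emission_band_nm`` is a closed interval; ``lo == hi`` denotes a point
    peak read at the single nearest emission pixel.
    """

    name: str
    excitation_nm: float
    emission_band_nm: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.emission_band_nm
        if lo > hi:
            raise ValueError(f"peak {self.name}: emission band [{lo}, {hi}] inverted")
        if self.excitation_nm <= 0:
            raise ValueError(f"peak {self.name}: excitation must be positive")

    @property
    def is_point(self) -> bool:
        lo, hi = self.emission_band_nm
        return lo == hi


#: The three peaks quantified throughout this package.
STANDARD_PEAK_NAMES = ("T", "C", "C+")

_ALL_PEAKS = {
    "T": PeakDefinition("T", 275.0, (340.0, 340.0)),
    "B": PeakDefinition("B", 275.0, (305.0, 305.0)),
    "C": PeakDefinition("C", 340.0, (420.0, 470.0)),
    "C+": PeakDefinition("C+", 400.0, (470.0, 505.0)),
    # midpoint of the conventional 290-310 nm excitation range
    "M": PeakDefinition("M", 300.0, (370.0, 420.0)),
}


def standard_peaks(include_optional: bool = False) -> list[PeakDefinition]:
    """Peaks T, C and C+ (plus B and M when ``include_optional``)."""
    names = STANDARD_PEAK_NAMES + (("B", "M") if include_optional else ())
    return [_ALL_PEAKS[n] for n in names]


def peak_by_name(name: str) -> PeakDefinition:
    try:
        return _ALL_PEAKS[name]
    except KeyError:
        raise InputError(f"unknown peak {name!r}; known: {sorted(_ALL_PEAKS)}") from None


def pick_peak(
    eem: EEMatrix,
    peak: PeakDefinition,
    ex_tolerance_nm: float | None = None,
    point_band_halfwidth_nm: float = 0.0,
) -> float:
    """Mean QSU intensity of a peak region on a corrected EEM.

    Takes the emission cross-section at the excitation column nearest
    ``peak.excitation_nm`` and averages the unmasked intensities whose
    emission wavelength lies in the band. Point bands read the single
    nearest emission pixel unless ``point_band_halfwidth_nm`` widens them.

    Raises :class:`QualityError` when more than half the band is masked.
    """
    if eem.unit != "QSU":
        raise UnitError(f"pick_peak requires a QSU EEM, got unit {eem.unit!r}")
    col = nearest_index(eem.excitation, peak.excitation_nm, ex_tolerance_nm)
    lo, hi = peak.emission_band_nm
    if peak.is_point and point_band_halfwidth_nm > 0:
        lo, hi = lo - point_band_halfwidth_nm, hi + point_band_halfwidth_nm
    if lo == hi:
        rows = np.array([nearest_index(eem.emission, lo)])
    else:
        sel = (eem.emission.values >= lo - 1e-9) & (eem.emission.values <= hi + 1e-9)
        if not sel.any():
            raise RangeError(
                f"peak {peak.name}: emission band [{lo:g}, {hi:g}] nm contains no grid points"
            )
        rows = np.flatnonzero(sel)
    band = eem.intensity[rows, col]
    masked = eem.mask[rows, col]
    frac = float(np.mean(masked))
    if frac > 0.5:
        raise QualityError(
            f"peak {peak.name}: {frac:.0%} of the emission band is masked"
        )
    return float(np.mean(band[~masked]))


@dataclass
class PeakSeries:
    """Time-resolved QSU intensities for a set of peaks.

    ``values`` is a DataFrame indexed by time (h) with one column per peak.
    """

    times_h: np.ndarray
    values: pd.DataFrame
    replicate: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if t.ndim != 1:
            raise InputError("times must be 1-D")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing with no duplicates")
        self.times_h = t
        if len(self.values) != t.size:
            raise InputError("one value row per time required")

    @property
    def peak_names(self) -> list[str]:
        return list(self.values.columns)

    def value(self, peak: str, time_h: float) -> float:
        i = _time_index(self.times_h, time_h)
        return float(self.values.iloc[i][peak])


def _time_index(times: np.ndarray, t: float) -> int:
    hits = np.flatnonzero(np.isclose(times, t, rtol=0, atol=1e-9))
    if hits.size == 0:
        raise InputError(f"time {t:g} h not present in series (times: {list(times)})")
    return int(hits[0])


def extract_series(
    eems: list[tuple[float, EEMatrix]],
    peaks: list[PeakDefinition],
    replicate: str | None = None,
    condition: str | None = None,
    **pick_kwargs,
) -> PeakSeries:
    """One :func:`pick_peak` value per (time, peak) over a sorted time course."""
    times = np.array([t for t, _ in eems], dtype=float)
    if np.unique(times).size != times.size:
        raise InputError("duplicate times in EEM series")
    order = np.argsort(times)
    rows = []
    for i in order:
        t, eem = eems[i]
        rows.append({p.name: pick_peak(eem, p, **pick_kwargs) for p in peaks})
    frame = pd.DataFrame(rows, index=times[order], columns=[p.name for p in peaks])
    frame.index.name = "time_h"
    return PeakSeries(times[order], frame, replicate=replicate, condition=condition)


def percent_change(series: PeakSeries, peak: str, t1: float, t2: float) -> float:
    """``100 * (v(t2) - v(t1)) / v(t1)`` for one peak between two times.

    A zero baseline raises :class:`UndefinedBaselineError` -- very large
    published percentages typically arise from near-zero baselines, and a
    literally zero one has no defined percent change.
    """
    if not t1 < t2:
        raise InputError(f"require t1 < t2, got {t1} >= {t2}")
    v1 = series.value(peak, t1)
    v2 = series.value(peak, t2)
    if v1 == 0:
        raise UndefinedBaselineError(
            f"peak {peak}: value at t={t1:g} h is zero; percent change undefined"
        )
    return 100.0 * (v2 - v1) / v1
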