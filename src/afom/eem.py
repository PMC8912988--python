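"""Excitation-emission matrix (EEM) data model and delimited-text I/O.

An EEM holds fluorescence intensity on a two-dimensional wavelength grid,
stored as emission rows by excitation columns -- the same layout as the
on-disk dialect (first row = excitation header, first column = emission
wavelengths). The instrument grid this package was built around runs
excitation 200-600 nm in 1 nm steps and emission 247.88-829.85 nm in
1.16 nm steps, so emission wavelengths are generally not round numbers
and every lookup goes through :func:`nearest_index`.

Masked cells (scatter ridges, saturated pixels) are carried as a boolean
grid alongside the intensities and serialized as the sentinel token ``NA``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CoverageError,
    EEMParseError,
    RangeError,
    WavelengthLookupError,
)

logger = logging.getLogger(__name__)

#: Sentinel token for masked cells in delimited-text files.
MASK_SENTINEL = "NA"

#: Numeric format for all on-disk output (>= 9 significant digits).
IO_FORMAT = "%.10g"

_VALID_UNITS = ("raw", "QSU")


@dataclass(frozen=True)
class WavelengthAxis:
    """A strictly increasing grid of positive wavelengths in nanometres.

    Spacing may be non-integer (the emission axis steps by 1.16 nm).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength axis must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavelength axis contains non-finite values")
        if np.any(v <= 0):
            raise ValueError("wavelengths must be positive")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "WavelengthAxis":
        """Inclusive arithmetic grid ``start, start+step, ... <= stop``."""
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        return cls(start + step * np.arange(n))

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, i):
        return self.values[i]

    @property
    def spacing(self) -> float:
        """Largest gap between neighbouring grid points (nm); 1.0 for a single point."""
        if len(self) < 2:
            return 1.0
        return float(np.max(np.diff(self.values)))


def nearest_index(axis: WavelengthAxis, target: float, tolerance: float | None = None) -> int:
    """Index of the axis value closest to ``target``.

    Ties break toward the lower wavelength. ``tolerance`` defaults to one
    grid spacing of the axis; if no grid point lies within it a
    :class:`WavelengthLookupError` is raised.
    """
    tol = axis.spacing if tolerance is None else float(tolerance)
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    dist = np.abs(axis.values - float(target))
    idx = int(np.argmin(dist))  # first minimum = lower wavelength on a tie
    if dist[idx] > tol + 1e-12:
        raise WavelengthLookupError(
            f"no grid point within {tol:g} nm of {target:g} nm on axis "
            f"[{axis.values[0]:g}, {axis.values[-1]:g}] nm"
        )
    return idx


@dataclass
class EEMatrix:
    """Fluorescence intensity on an (emission x excitation) wavelength grid.

    Parameters
    ----------
    excitation, emission
        Wavelength axes (nm). Arrays are accepted and coerced.
    intensity
        Grid of shape ``(len(emission), len(excitation))``; raw counts or QSU.
    unit
        ``"raw"`` or ``"QSU"``. Changed only by QSU normalization.
    mask
        Boolean grid of the same shape; ``True`` marks invalid cells.
    meta
        Free-form labels (sample id, time_h, condition, processing log).
    """

    excitation: WavelengthAxis
    emission: WavelengthAxis
    intensity: np.ndarray
    unit: str = "raw"
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.excitation, WavelengthAxis):
            self.excitation = WavelengthAxis(self.excitation)
        if not isinstance(self.emission, WavelengthAxis):
            self.emission = WavelengthAxis(self.emission)
        inten = np.asarray(self.intensity, dtype=float)
        expected = (len(self.emission), len(self.excitation))
        if inten.shape != expected:
            raise ValueError(
                f"intensity shape {inten.shape} != (emission, excitation) {expected}"
            )
        self.intensity = inten
        if self.mask is None:
            self.mask = np.zeros(expected, dtype=bool)
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != expected:
                raise ValueError(f"mask shape {m.shape} != intensity shape {expected}")
            self.mask = m
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}, got {self.unit!r}")
        if not np.all(np.isfinite(self.intensity[~self.mask])):
            raise ValueError("unmasked intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def with_(self, **changes) -> "EEMatrix":
        """Copy with selected fields replaced (validates the result)."""
        kw = dict(
            excitation=self.excitation,
            emission=self.emission,
            intensity=self.intensity,
            unit=self.unit,
            mask=self.mask,
            meta=dict(self.meta),
        )
        kw.update(changes)
        return EEMatrix(**kw)


def crop_eem(
    eem: EEMatrix,
    ex_range: tuple[float, float],
    em_range: tuple[float, float],
) -> EEMatrix:
    """Restrict an EEM to the grid points inside closed wavelength intervals.

    Raises :class:`RangeError` if either interval selects no grid points.
    Metadata is preserved; cropping twice with the same ranges is a no-op.
    """
    out = eem
    for name, (lo, hi), axis in (
        ("excitation", ex_range, eem.excitation),
        ("emission", em_range, eem.emission),
    ):
        if lo > hi:
            raise ValueError(f"{name} range [{lo:g}, {hi:g}] is inverted")
        sel = (axis.values >= lo - 1e-9) & (axis.values <= hi + 1e-9)
        if not sel.any():
            raise RangeError(
                f"{name} range [{lo:g}, {hi:g}] nm selects no grid points on axis "
                f"[{axis.values[0]:g}, {axis.values[-1]:g}] nm"
            )
        if name == "excitation":
            out = out.with_(
                excitation=WavelengthAxis(axis.values[sel]),
                intensity=out.intensity[:, sel],
                mask=out.mask[:, sel],
            )
        else:
            out = out.with_(
                emission=WavelengthAxis(axis.values[sel]),
                intensity=out.intensity[sel, :],
                mask=out.mask[sel, :],
            )
    return out


# ---------------------------------------------------------------------------
# Delimited-text I/O ("axes-in-headers" dialect)
# ---------------------------------------------------------------------------


def _delimiter(dialect: str, sample_line: str | None = None) -> str:
    if dialect == "comma":
        return ","
    if dialect == "tab":
        return "\t"
    if dialect == "auto":
        if sample_line is None:
            return ","
        return "\t" if "\t" in sample_line else ","
    raise ValueError(f"unknown dialect {dialect!r}")


def write_eem(eem: EEMatrix, path: str | Path, dialect: str = "comma") -> None:
    """Write an EEM as delimited text.

    First row: empty cell then excitation wavelengths. Each following row:
    emission wavelength then intensities, with masked cells as ``NA``.
    Unit and metadata travel in ``#``-prefixed comment lines so that a
    write/read round trip preserves them.
    """
    delim = _delimiter(dialect)
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# unit: {eem.unit}\n")
        if eem.meta:
            fh.write("# meta: " + json.dumps(eem.meta, default=str) + "\n")
        header = [""] + [IO_FORMAT % v for v in eem.excitation.values]
        fh.write(delim.join(header) + "\n")
        for i, em in enumerate(eem.emission.values):
            cells = [IO_FORMAT % em]
            for j in range(len(eem.excitation)):
                if eem.mask[i, j]:
                    cells.append(MASK_SENTINEL)
                else:
                    cells.append(IO_FORMAT % eem.intensity[i, j])
            fh.write(delim.join(cells) + "\n")


def _parse_float(token: str, row: int, col: int, path: Path) -> float:
    try:
        return float(token)
    except ValueError:
        raise EEMParseError(
            f"{path}: non-numeric value {token!r} at row {row}, column {col}"
        ) from None


def read_eem(path: str | Path, dialect: str = "auto") -> EEMatrix:
    """Read an EEM written by :func:`write_eem` (or any file in the dialect).

    Parse errors report the offending row/column. ``NA`` cells are restored
    as masked with intensity 0.
    """
    path = Path(path)
    unit = "raw"
    meta: dict = {}
    lines: list[tuple[int, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("unit:"):
                    unit = body.split(":", 1)[1].strip()
                elif body.startswith("meta:"):
                    try:
                        meta = json.loads(body.split(":", 1)[1])
                    except json.JSONDecodeError:
                        raise EEMParseError(f"{path}: malformed meta line {lineno}")
                continue
            lines.append((lineno, line))
    if not lines:
        raise EEMParseError(f"{path}: no data rows")
    delim = _delimiter(dialect, lines[0][1])
    rows = [(n, next(csv.reader([text], delimiter=delim))) for n, text in lines]

    header_no, header = rows[0]
    if len(header) < 2 or len(rows) < 2:
        raise EEMParseError(f"{path}: need at least one excitation column and one emission row")
    ex_vals = [
        _parse_float(tok, header_no, j + 2, path) for j, tok in enumerate(header[1:])
    ]
    ncol = len(header)
    em_vals: list[float] = []
    inten = np.zeros((len(rows) - 1, ncol - 1))
    mask = np.zeros_like(inten, dtype=bool)
    for i, (lineno, row) in enumerate(rows[1:]):
        if len(row) != ncol:
            raise EEMParseError(
                f"{path}: row {lineno} has {len(row)} fields, expected {ncol}"
            )
        em_vals.append(_parse_float(row[0], lineno, 1, path))
        for j, tok in enumerate(row[1:]):
            if tok.strip() == MASK_SENTINEL:
                mask[i, j] = True
                inten[i, j] = 0.0
            else:
                inten[i, j] = _parse_float(tok, lineno, j + 2, path)
    try:
        ex_axis = WavelengthAxis(np.array(ex_vals))
        em_axis = WavelengthAxis(np.array(em_vals))
    except ValueError as exc:
        raise EEMParseError(f"{path}: invalid wavelength axis: {exc}") from None
    return EEMatrix(ex_axis, em_axis, inten, unit=unit, mask=mask, meta=meta)


# ---------------------------------------------------------------------------
# Absorbance spectra
# ---------------------------------------------------------------------------


@dataclass
class AbsorbanceSpectrum:
    """Dimensionless absorbance vs wavelength, referenced to a 1 cm path.

    Negative input values are clipped to zero (instrument baseline noise
    commonly dips below zero) with a logged warning. Values at arbitrary
    wavelengths inside the measured range come from linear interpolation.
    """

    wavelength: WavelengthAxis
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        if not isinstance(self.wavelength, WavelengthAxis):
            self.wavelength = WavelengthAxis(self.wavelength)
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 1 or a.size != len(self.wavelength):
            raise ValueError("absorbance must match the wavelength axis length")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        n_neg = int(np.sum(a < 0))
        if n_neg:
            logger.warning("clipped %d negative absorbance values to zero", n_neg)
            a = np.clip(a, 0.0, None)
        self.absorbance = a

    def at(self, wavelength_nm) -> np.ndarray:
        """Linearly interpolated absorbance; errors outside coverage."""
        wl = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        lo, hi = self.wavelength.values[0], self.wavelength.values[-1]
        if np.any(wl < lo - 1e-9) or np.any(wl > hi + 1e-9):
            bad = wl[(wl < lo - 1e-9) | (wl > hi + 1e-9)]
            raise CoverageError(
                f"wavelength {bad[0]:g} nm outside absorbance coverage [{lo:g}, {hi:g}] nm"
            )
        return np.interp(wl, self.wavelength.values, self.absorbance)


def write_absorbance(spec: AbsorbanceSpectrum, path: str | Path, dialect: str = "comma") -> None:
    """Two-column delimited text: wavelength_nm, absorbance."""
    delim = _delimiter(dialect)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"wavelength_nm{delim}absorbance\n")
        for wl, a in zip(spec.wavelength.values, spec.absorbance):
            fh.write(f"{IO_FORMAT % wl}{delim}{IO_FORMAT % a}\n")


def read_absorbance(path: str | Path, dialect: str = "auto") -> AbsorbanceSpectrum:
    path = Path(path)
    wl: list[float] = []
    ab: list[float] = []
    with path.open() as fh:
        first_delim: str | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if first_delim is None:
                first_delim = _delimiter(dialect, line)
            parts = line.split(first_delim)
            if len(parts) != 2:
                raise EEMParseError(
                    f"{path}: row {lineno} has {len(parts)} fields, expected 2"
                )
            try:
                wl.append(float(parts[0]))
                ab.append(float(parts[1]))
            except ValueError:
                if lineno == 1:
                    continue  # textual header
                raise EEMParseError(
                    f"{path}: non-numeric value at row {lineno}"
                ) from None
    if not wl:
        raise EEMParseError(f"{path}: no data rows")
    return AbsorbanceSpectrum(WavelengthAxis(np.array(wl)), np.array(ab))


def instrument_grid() -> tuple[WavelengthAxis, WavelengthAxis]:
    """The full instrument grid: excitation 200-600 nm step 1 nm; emission
    247.88-829.85 nm step 1.16 nm."""
    ex = WavelengthAxis.from_range(200.0, 600.0, 1.0)
    em = WavelengthAxis.from_range(247.88, 829.85, 1.16)
    return ex, em
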