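"""Raw EEM to corrected, QSU-normalized EEM.

The correction chain mirrors standard fluorescence practice for dissolved
organic matter work: inner-filter correction from the paired absorbance
spectrum (absorbance/ABA method), blank subtraction, first- and
second-order Rayleigh scatter masking, cropping to the UV-visible analysis
window (excitation 240-490 nm, emission 250-500 nm), and normalization to
quinine sulfate units (QSU), where 1 QSU is the fluorescence of a
1 ug L^-1 quinine sulfate solution at excitation 347.5 nm / emission 450 nm.

Stage order is a deliberate choice: the inner-filter effect is
sample-specific and must be undone before subtracting a blank of different
absorbance; cropping happens after masking so the scatter geometry is
intact when the ridges are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .eem import AbsorbanceSpectrum, EEMatrix, crop_eem, nearest_index
from .errors import AxisAlignmentError, UnitError

logger = logging.getLogger(__name__)

#: Quinine sulfate reference coordinates (nm).
QS_EXCITATION_NM = 347.5
QS_EMISSION_NM = 450.0


@dataclass(frozen=True)
class QsReference:
    """Raw-count intensity of the 1 ug L^-1 quinine sulfate standard.

    ``source`` records whether the value was supplied directly or read off
    a measured standard EEM at the grid point nearest (347.5, 450) nm.
    """

    intensity_raw: float
    source: str = "scalar"

    def __post_init__(self) -> None:
        if not (self.intensity_raw > 0):
            raise ValueError("QS reference intensity must be positive")

    @classmethod
    def from_eem(cls, standard: EEMatrix) -> "QsReference":
        """Reference from a measured quinine sulfate standard EEM."""
        if standard.unit != "raw":
            raise UnitError("QS standard EEM must be in raw counts")
        i = nearest_index(standard.emission, QS_EMISSION_NM)
        j = nearest_index(standard.excitation, QS_EXCITATION_NM)
        if standard.mask[i, j]:
            raise ValueError("QS standard EEM is masked at the reference cell")
        return cls(float(standard.intensity[i, j]), source="derived-from-EEM")


def _check_axes(a: EEMatrix, b: EEMatrix) -> None:
    for name, av, bv in (
        ("excitation", a.excitation.values, b.excitation.values),
        ("emission", a.emission.values, b.emission.values),
    ):
        if av.shape != bv.shape or not np.allclose(av, bv, rtol=0, atol=1e-6):
            raise AxisAlignmentError(f"{name} axes differ between sample and blank")


def subtract_blank(sample: EEMatrix, blank: EEMatrix) -> EEMatrix:
    """Elementwise sample minus blank; masks are unioned.

    Negative results are retained (not clipped) so near-zero signals stay
    unbiased.
    """
    _check_axes(sample, blank)
    if sample.unit != blank.unit:
        raise UnitError(
            f"sample unit {sample.unit!r} != blank unit {blank.unit!r}"
        )
    return sample.with_(
        intensity=sample.intensity - blank.intensity,
        mask=sample.mask | blank.mask,
    )


def correct_ife(
    eem: EEMatrix,
    abs_spec: AbsorbanceSpectrum,
    pathlength_cm: float = 1.0,
) -> EEMatrix:
    """Inner-filter correction by the absorbance (ABA) method.

    Each cell is multiplied by ``10^(L * (A(ex) + A(em)) / 2)`` where A is
    the 1 cm absorbance interpolated at the cell's excitation and emission
    wavelengths and L the cuvette pathlength in cm (default 1.0, a 10 mm
    cuvette). The mask is untouched.
    """
    if not (pathlength_cm > 0):
        raise ValueError("pathlength must be positive")
    a_ex = abs_spec.at(eem.excitation.values)
    a_em = abs_spec.at(eem.emission.values)
    factor = 10.0 ** (pathlength_cm * (a_em[:, None] + a_ex[None, :]) / 2.0)
    return eem.with_(intensity=eem.intensity * factor)


def mask_rayleigh(eem: EEMatrix, hw1: float = 10.0, hw2: float = 10.0) -> EEMatrix:
    """Mask first- and second-order Rayleigh scatter ridges.

    Cells with ``|em - ex| <= hw1`` (first order) or ``|em - 2 ex| <= hw2``
    (second order) are added to the mask; intensities are untouched.
    """
    if hw1 < 0 or hw2 < 0:
        raise ValueError("scatter half-widths must be non-negative")
    em = eem.emission.values[:, None]
    ex = eem.excitation.values[None, :]
    ridge = (np.abs(em - ex) <= hw1) | (np.abs(em - 2.0 * ex) <= hw2)
    return eem.with_(mask=eem.mask | ridge)


def normalize_qsu(eem: EEMatrix, ref: QsReference) -> EEMatrix:
    """Divide raw counts by the quinine sulfate reference; unit becomes QSU."""
    if eem.unit != "raw":
        raise UnitError("EEM is already QSU-normalized")
    return eem.with_(intensity=eem.intensity / ref.intensity_raw, unit="QSU")


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters with instrument-appropriate defaults."""

    pathlength_cm: float = 1.0
    scatter_hw1_nm: float = 10.0
    scatter_hw2_nm: float = 10.0
    crop_ex: tuple[float, float] = (240.0, 490.0)
    crop_em: tuple[float, float] = (250.0, 500.0)
    #: flag if any post-subtraction intensity < -(this fraction) * grid max
    negative_flag_fraction: float = 0.05


def preprocess_pipeline(
    sample: EEMatrix,
    blank: EEMatrix,
    abs_spec: AbsorbanceSpectrum,
    ref: QsReference,
    config: PreprocessConfig | None = None,
) -> EEMatrix:
    """Full correction chain: IFE (sample and blank) -> blank subtraction ->
    Rayleigh masking -> crop -> QSU normalization.

    Returns a QSU EEM carrying a processing log in ``meta["processing_log"]``.
    """
    cfg = config or PreprocessConfig()
    log: list[str] = []
    s = correct_ife(sample, abs_spec, cfg.pathlength_cm)
    b = correct_ife(blank, abs_spec, cfg.pathlength_cm)
    log.append(f"ife: ABA correction, pathlength {cfg.pathlength_cm:g} cm")
    d = subtract_blank(s, b)
    log.append("blank: subtracted (negative values retained)")
    unmasked = d.intensity[~d.mask]
    if unmasked.size:
        grid_max = float(np.max(unmasked))
        threshold = -cfg.negative_flag_fraction * max(grid_max, 0.0)
        if grid_max > 0 and float(np.min(unmasked)) < threshold:
            d.meta["negative_signal_flag"] = True
            log.append(
                f"warning: intensities below {cfg.negative_flag_fraction:.0%} "
                "of grid max after blank subtraction"
            )
    d = mask_rayleigh(d, cfg.scatter_hw1_nm, cfg.scatter_hw2_nm)
    log.append(
        f"rayleigh: masked orders 1/2 at half-widths "
        f"{cfg.scatter_hw1_nm:g}/{cfg.scatter_hw2_nm:g} nm"
    )
    d = crop_eem(d, cfg.crop_ex, cfg.crop_em)
    log.append(f"crop: ex {cfg.crop_ex} nm, em {cfg.crop_em} nm")
    q = normalize_qsu(d, ref)
    log.append(f"qsu: normalized to reference intensity {ref.intensity_raw:g}")
    q.meta["processing_log"] = log
    return q
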