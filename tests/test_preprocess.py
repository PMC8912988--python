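"""Preprocessing chain: blank, inner-filter, scatter mask, QSU scaling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from afom.eem import AbsorbanceSpectrum, EEMatrix, WavelengthAxis
from afom.errors import AxisAlignmentError, UnitError
from afom.peaks import standard_peaks, pick_peak
from afom.preprocess import (
    PreprocessConfig,
    QsReference,
    correct_ife,
    mask_rayleigh,
    normalize_qsu,
    preprocess_pipeline,
    subtract_blank,
)
from afom.synth import condition_spec, ideal_peak_qsu, simulate_eem


def _flat_absorbance(level: float) -> AbsorbanceSpectrum:
    return AbsorbanceSpectrum(
        WavelengthAxis(np.array([150.0, 900.0])), np.array([level, level])
    )


class TestSubtractBlank:
    def test_self_subtraction_is_zero(self, uniform_eem):
        out = subtract_blank(uniform_eem(4.0, "raw"), uniform_eem(4.0, "raw"))
        assert np.allclose(out.intensity, 0.0)

    def test_constant_shift_and_negatives_retained(self, uniform_eem):
        assert np.allclose(
            subtract_blank(uniform_eem(9.0, "raw"), uniform_eem(4.0, "raw")).intensity, 5.0
        )
        assert np.allclose(
            subtract_blank(uniform_eem(1.0, "raw"), uniform_eem(4.0, "raw")).intensity, -3.0
        )

    def test_mask_union(self, uniform_eem):
        sample, blank = uniform_eem(2.0, "raw"), uniform_eem(1.0, "raw")
        blank.mask[3, 4] = True
        out = subtract_blank(sample, blank)
        assert out.mask[3, 4] and int(out.mask.sum()) == 1

    def test_axis_mismatch_raises(self, uniform_eem):
        other = EEMatrix(
            WavelengthAxis.from_range(200.0, 600.0, 10.0),
            WavelengthAxis.from_range(250.0, 500.0, 10.0),
            np.zeros((26, 41)),
        )
        with pytest.raises(AxisAlignmentError):
            subtract_blank(uniform_eem(1.0, "raw"), other)


class TestInnerFilter:
    def test_zero_absorbance_is_identity(self, uniform_eem):
        eem = uniform_eem(3.0, "raw")
        assert np.allclose(correct_ife(eem, _flat_absorbance(0.0)).intensity, 3.0)

    def test_closed_form_factor(self, uniform_eem):
        # A(ex) = A(em) = 0.1 at 1 cm: factor 10^0.1
        out = correct_ife(uniform_eem(1.0, "raw"), _flat_absorbance(0.1), 1.0)
        assert np.allclose(out.intensity, 10.0**0.1)
        assert out.intensity[0, 0] == pytest.approx(1.258925412, abs=1e-9)

    def test_inverts_forward_attenuation(self, small_grid):
        ex, em = small_grid
        rng = np.random.default_rng(3)
        ideal = rng.uniform(1.0, 10.0, (len(em), len(ex)))
        wl = WavelengthAxis.from_range(150.0, 900.0, 25.0)
        abs_spec = AbsorbanceSpectrum(wl, 0.3 * np.exp(-(wl.values - 250.0) ** 2 / 2e4))
        a_ex = abs_spec.at(ex.values)
        a_em = abs_spec.at(em.values)
        attenuated = ideal * 10.0 ** (-(a_em[:, None] + a_ex[None, :]) / 2.0)
        out = correct_ife(EEMatrix(ex, em, attenuated), abs_spec)
        assert np.allclose(out.intensity, ideal, rtol=1e-9)


class TestRayleighMask:
    @pytest.mark.parametrize(
        "ex,em,masked",
        [
            (300.0, 300.0, True),   # on the first-order ridge
            (275.0, 340.0, False),  # Peak T region, far from both ridges
            (250.0, 495.0, True),   # |495 - 2*250| = 5 <= hw2
        ],
    )
    def test_ridge_membership(self, ex, em, masked):
        eem = EEMatrix(
            WavelengthAxis(np.array([ex])), WavelengthAxis(np.array([em])),
            np.zeros((1, 1)),
        )
        assert bool(mask_rayleigh(eem, 10.0, 10.0).mask[0, 0]) is masked

    @given(hw1=st.floats(0.0, 30.0), hw2=st.floats(0.0, 30.0))
    def test_masked_set_equals_bruteforce(self, hw1, hw2):
        ex = WavelengthAxis.from_range(240.0, 480.0, 16.0)
        em = WavelengthAxis.from_range(250.0, 700.0, 30.0)
        eem = EEMatrix(ex, em, np.zeros((len(em), len(ex))))
        got = mask_rayleigh(eem, hw1, hw2).mask
        for i, emv in enumerate(em.values):
            for j, exv in enumerate(ex.values):
                expected = abs(emv - exv) <= hw1 or abs(emv - 2 * exv) <= hw2
                assert got[i, j] == expected


class TestNormalizeQsu:
    def test_reference_definition(self, uniform_eem):
        ref = QsReference(500.0)
        out = normalize_qsu(uniform_eem(500.0, "raw"), ref)
        assert out.unit == "QSU" and np.allclose(out.intensity, 1.0)
        assert np.allclose(
            normalize_qsu(uniform_eem(1000.0, "raw"), ref).intensity, 2.0
        )

    def test_double_normalization_rejected(self, uniform_eem):
        with pytest.raises(UnitError):
            normalize_qsu(uniform_eem(1.0, "QSU"), QsReference(500.0))

    @given(ref_intensity=st.floats(0.1, 1e4))
    def test_ratios_preserved(self, ref_intensity):
        rng = np.random.default_rng(11)
        ex = WavelengthAxis.from_range(250.0, 290.0, 10.0)
        em = WavelengthAxis.from_range(300.0, 340.0, 10.0)
        vals = rng.uniform(1.0, 100.0, (5, 5))
        out = normalize_qsu(
            EEMatrix(ex, em, vals, unit="raw"), QsReference(ref_intensity)
        )
        assert np.allclose(out.intensity / out.intensity[0, 0], vals / vals[0, 0])


class TestPipeline:
    def test_blank_equals_sample_gives_zero(self, uniform_eem):
        out = preprocess_pipeline(
            uniform_eem(7.0, "raw"), uniform_eem(7.0, "raw"),
            _flat_absorbance(0.0), QsReference(100.0),
        )
        assert out.unit == "QSU"
        assert np.allclose(out.intensity[~out.mask], 0.0)
        assert any("qsu" in step for step in out.meta["processing_log"])

    def test_recovers_simulated_peaks_noise_off(self):
        spec = dataclasses.replace(condition_spec("SFW2"), noise_sd_qsu=0.0)
        sample, blank, abs_spec = simulate_eem(spec, 16.0)
        out = preprocess_pipeline(
            sample, blank, abs_spec, QsReference(spec.qs_reference_intensity)
        )
        for peak in standard_peaks():
            want = ideal_peak_qsu(spec, 16.0, peak)
            assert pick_peak(out, peak) == pytest.approx(want, rel=0.02)

    def test_sterile_control_stays_below_background(self):
        # blank-level sample: scatter only, no fluorophores
        spec = dataclasses.replace(condition_spec("SFW0"), fluorophores=())
        sample, blank, abs_spec = simulate_eem(spec, 48.0)
        out = preprocess_pipeline(
            sample, blank, abs_spec, QsReference(spec.qs_reference_intensity)
        )
        for peak in standard_peaks():
            assert abs(pick_peak(out, peak)) < 5.0

    def test_ife_commutes_with_qsu_scaling(self, uniform_eem):
        eem = uniform_eem(50.0, "raw")
        abs_spec = _flat_absorbance(0.08)
        ref = QsReference(123.0)
        a = normalize_qsu(correct_ife(eem, abs_spec), ref)
        b = correct_ife(normalize_qsu(eem, ref), abs_spec)
        assert np.allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_negative_signal_flagged(self, uniform_eem):
        sample = uniform_eem(1.0, "raw")
        sample.intensity[10, 10] = 100.0  # grid max
        blank = uniform_eem(1.0, "raw")
        blank.intensity[12, 12] = 50.0  # drives a large negative cell
        out = preprocess_pipeline(
            sample, blank, _flat_absorbance(0.0), QsReference(10.0)
        )
        assert out.meta.get("negative_signal_flag") is True
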