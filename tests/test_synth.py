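"""Forward model: determinism, closed forms, and recoverability."""

import dataclasses

import numpy as np
import pytest

from afom.errors import ParameterError
from afom.growth import classify_phases
from afom.peaks import peak_by_name, pick_peak, standard_peaks
from afom.preprocess import QsReference, preprocess_pipeline
from afom.synth import (
    SAMPLING_SCHEDULE,
    FluorophoreSpec,
    GrowthSpec,
    SimulationSpec,
    condition_spec,
    ideal_peak_qsu,
    ramp_kinetics,
    reduced_grid,
    simulate_eem,
    simulate_growth,
)


def _quiet(spec: SimulationSpec) -> SimulationSpec:
    return dataclasses.replace(
        spec,
        noise_sd_qsu=0.0,
        growth=dataclasses.replace(spec.growth, noise_cv=0.0),
    )


class TestGrowthModel:
    def test_closed_form_three_phase(self):
        spec = _quiet(condition_spec("SFW2"))  # lag 6, rate 1/3, capacity 1e7
        curve = simulate_growth(spec)
        assert curve.cfu_per_ml[0] == pytest.approx(1e5)
        i12 = list(curve.times_h).index(12.0)
        assert curve.cfu_per_ml[i12] == pytest.approx(1e7)
        phases = classify_phases(curve)
        assert [p.interval for p in phases] == [(0.0, 6.0), (6.0, 12.0), (12.0, 48.0)]

    def test_deterministic_under_seed(self):
        spec = condition_spec("SFW4", seed=42)
        a, b = simulate_growth(spec), simulate_growth(spec)
        assert np.array_equal(a.cfu_per_ml, b.cfu_per_ml)

    def test_lag_spanning_experiment_is_flat(self):
        growth = GrowthSpec(lag_h=48.0, noise_cv=0.0)
        spec = dataclasses.replace(condition_spec("SFW0"), growth=growth)
        curve = simulate_growth(_quiet(spec))
        assert np.allclose(curve.cfu_per_ml, 1e5)

    def test_capacity_below_inoculum_rejected(self):
        with pytest.raises(ParameterError):
            GrowthSpec(inoculum_cfu_per_ml=1e6, capacity_cfu_per_ml=1e5)

    def test_rate_recovered_from_exponential_segment(self):
        # default observation noise on: slope fit on the detected
        # exponential window recovers the generating rate within 5 %
        spec = condition_spec("SFW3", seed=9)
        curve = simulate_growth(spec)
        phases = classify_phases(curve)
        lo, hi = phases[1].interval
        sel = (curve.times_h >= lo) & (curve.times_h <= hi)
        slope = np.polyfit(curve.times_h[sel], np.log10(curve.cfu_per_ml[sel]), 1)[0]
        assert slope == pytest.approx(spec.growth.max_rate_log10_per_h, rel=0.05)


class TestEEMModel:
    def test_single_fluorophore_recovered_within_a_tenth_percent(self):
        # no scatter, no absorbance, noise off: pipeline output at Peak T
        # equals the generating amplitude up to sub-pixel center offset
        ex, em = reduced_grid()
        amp = {0.0: 5.0, 48.0: 5.0}
        spec = SimulationSpec(
            excitation=ex,
            emission=em,
            fluorophores=(FluorophoreSpec("T", 275.0, 340.0, 15.0, 20.0, amp),),
            scatter=dataclasses.replace(condition_spec("SFW0").scatter, amp1_qsu=0.0, amp2_qsu=0.0),
            absorbance=dataclasses.replace(condition_spec("SFW0").absorbance, baseline=0.0, per_amplitude=0.0),
            noise_sd_qsu=0.0,
        )
        sample, blank, abs_spec = simulate_eem(spec, 24.0)
        out = preprocess_pipeline(
            sample, blank, abs_spec, QsReference(spec.qs_reference_intensity)
        )
        assert pick_peak(out, peak_by_name("T")) == pytest.approx(5.0, rel=1e-3)

    def test_zero_fluorophores_is_null_after_preprocessing(self):
        spec = dataclasses.replace(condition_spec("SFW1", seed=3), fluorophores=())
        sample, blank, abs_spec = simulate_eem(spec, 8.0)
        out = preprocess_pipeline(
            sample, blank, abs_spec, QsReference(spec.qs_reference_intensity)
        )
        resid = out.intensity[~out.mask]
        # blank subtraction doubles the noise variance; bound the extreme
        # residual over the ~2.5e3 analysis-window pixels at 5 combined sigma
        combined_sd = np.sqrt(2.0) * spec.noise_sd_qsu
        assert np.max(np.abs(resid)) < 5.0 * combined_sd
        assert abs(np.mean(resid)) < 3.0 * combined_sd / np.sqrt(resid.size)

    def test_flat_absorbance_scales_by_closed_form(self):
        base = _quiet(condition_spec("SFW2"))
        a0 = dataclasses.replace(base.absorbance, baseline=0.0, per_amplitude=0.0)
        a2 = dataclasses.replace(base.absorbance, baseline=0.2, per_amplitude=0.0)
        s0, _, _ = simulate_eem(dataclasses.replace(base, absorbance=a0), 16.0)
        s2, _, _ = simulate_eem(dataclasses.replace(base, absorbance=a2), 16.0)
        assert np.allclose(s2.intensity, s0.intensity * 10.0**-0.2, rtol=1e-9)

    def test_seeded_determinism_bytewise(self):
        spec = condition_spec("SFW5", seed=17)
        a, _, _ = simulate_eem(spec, 7.0)
        b, _, _ = simulate_eem(spec, 7.0)
        assert a.intensity.tobytes() == b.intensity.tobytes()

    def test_time_outside_schedule_rejected(self):
        with pytest.raises(ParameterError):
            simulate_eem(condition_spec("SFW0"), 60.0)


class TestKinetics:
    def test_ramp_interpolation(self):
        fl = FluorophoreSpec("T", 275.0, 340.0, 15.0, 20.0, ramp_kinetics(2.0, 12.0))
        assert fl.amplitude(0.0) == 2.0
        assert fl.amplitude(4.0) == 2.0
        assert fl.amplitude(10.0) == pytest.approx(7.0)  # midpoint of 4-16 h ramp
        assert fl.amplitude(20.0) == 12.0

    def test_ideal_peak_tracks_amplitude_ordering(self):
        spec = condition_spec("SFW3")
        t_vals = [ideal_peak_qsu(spec, t, peak_by_name("C+")) for t in (0.0, 8.0, 16.0, 48.0)]
        assert t_vals[0] < t_vals[1] < t_vals[2] == pytest.approx(t_vals[3])


class TestConditionSet:
    def test_dataset_shape_and_determinism(self, synthetic_dataset, tmp_path):
        root, _, manifest = synthetic_dataset
        eems = sorted((root / "raw").glob("SFW*/rep*/eem_t*.csv"))
        assert len(eems) == 6 * 3 * len(SAMPLING_SCHEDULE)  # 270 sample EEMs
        assert set(manifest["conditions"]) == {f"SFW{i}" for i in range(6)}
        # regenerating one file under the same master seed is byte-identical
        from afom.synth import simulate_condition_set

        again = tmp_path / "again"
        simulate_condition_set(again, master_seed=1)
        name = "SFW2/rep2/eem_t07.00.csv"
        assert (again / name).read_bytes() == (root / "raw" / name).read_bytes()
        assert (again / "manifest.json").read_text() == (
            root / "raw" / "manifest.json"
        ).read_text()

    def test_recovered_f_total_ordering_follows_doc(self, synthetic_dataset):
        # generator builds higher amplitudes with more DOC; the recovered
        # f_total ordering must match the manifest's within nutrient level
        _, report, manifest = synthetic_dataset
        rec = {c: report["fraction_tables"][c].f_total for c in manifest["conditions"]}
        truth = {
            c: manifest["conditions"][c]["fraction_table"]["f_total"]
            for c in manifest["conditions"]
        }
        for trio in (("SFW0", "SFW2", "SFW4"), ("SFW1", "SFW3", "SFW5")):
            rec_order = sorted(trio, key=rec.get)
            true_order = sorted(trio, key=truth.get)
            assert rec_order == true_order

    def test_growth_phase_boundaries_in_manifest(self, synthetic_dataset):
        _, _, manifest = synthetic_dataset
        g = manifest["conditions"]["SFW2"]["growth"]
        assert g["lag_h"] == 6.0
        assert g["capacity_time_h"] == pytest.approx(12.0)
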