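"""Forward model for every input the pipeline consumes.

Generates EEM time series (separable Gaussian fluorophores, Rayleigh
scatter ridges, inner-filter attenuation, additive detector noise), paired
absorbance spectra, blanks, and three-phase (lag / exponential /
stationary) viable-count growth curves from a 10^5 CFU ml^-1 inoculum --
so the whole pipeline is exercisable, and checkable against ground truth,
without instrument data.

The default condition presets emulate the six simulated-freshwater
nutrient x DOC conditions: peak amplitudes plateau at each condition's
measured 48 h intensities, rising from low t=0 baselines between 4 and
16 h (per-cell fluorescence production leads cell division, so amplitude
rises before the 6 h lag/exponential boundary), while growth runs at the
rate that carries the culture from inoculum to carrying capacity across
the 6-12 h exponential window.

All randomness derives from integer seeds through ``numpy.random.default_rng``
seed sequences, so a fixed master seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .eem import (
    AbsorbanceSpectrum,
    EEMatrix,
    WavelengthAxis,
    crop_eem,
    instrument_grid,
    write_absorbance,
    write_eem,
)
from .errors import ParameterError
from .growth import GrowthCurve, write_growth_curve
from .peaks import PeakDefinition, pick_peak, standard_peaks
from .preprocess import PreprocessConfig
from .summary import CONDITION_ORDER, peak_fraction_table

#: The sampling schedule (h): hourly over 0-8 h, then 12, 16, 20, 24, 36, 48.
SAMPLING_SCHEDULE = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0,
                     12.0, 16.0, 20.0, 24.0, 36.0, 48.0)


def reduced_grid() -> tuple[WavelengthAxis, WavelengthAxis]:
    """Coarsened instrument grid (5 nm excitation, 4.64 nm emission steps)
    spanning the same ranges; the default for multi-condition datasets."""
    ex = WavelengthAxis.from_range(200.0, 600.0, 5.0)
    em = WavelengthAxis.from_range(247.88, 829.85, 4.64)
    return ex, em


@dataclass(frozen=True)
class FluorophoreSpec:
    """One separable 2-D Gaussian fluorophore with amplitude kinetics.

    ``amplitude_kinetics`` maps time (h) to ideal amplitude on the QSU
    scale; amplitudes at intermediate times are linearly interpolated.
    """

    name: str
    center_ex_nm: float
    center_em_nm: float
    sigma_ex_nm: float
    sigma_em_nm: float
    amplitude_kinetics: dict[float, float]

    def __post_init__(self) -> None:
        if self.sigma_ex_nm <= 0 or self.sigma_em_nm <= 0:
            raise ParameterError(f"fluorophore {self.name}: widths must be positive")
        if any(a < 0 for a in self.amplitude_kinetics.values()):
            raise ParameterError(f"fluorophore {self.name}: amplitudes must be >= 0")

    def amplitude(self, t: float) -> float:
        times = np.array(sorted(self.amplitude_kinetics))
        amps = np.array([self.amplitude_kinetics[k] for k in sorted(self.amplitude_kinetics)])
        return float(np.interp(t, times, amps))

    def scaled(self, factor: float) -> "FluorophoreSpec":
        return replace(
            self,
            amplitude_kinetics={t: a * factor for t, a in self.amplitude_kinetics.items()},
        )


@dataclass(frozen=True)
class ScatterSpec:
    """Gaussian Rayleigh ridges along em = ex and em = 2 ex (QSU scale)."""

    amp1_qsu: float = 50.0
    width1_nm: float = 6.0
    amp2_qsu: float = 10.0
    width2_nm: float = 6.0


@dataclass(frozen=True)
class AbsorbanceModel:
    """Flat baseline plus a contribution tracking each fluorophore's
    excitation band (absorbance units per QSU of amplitude)."""

    baseline: float = 0.01
    per_amplitude: float = 2e-5
    axis_start_nm: float = 195.0
    axis_stop_nm: float = 840.0
    axis_step_nm: float = 5.0


@dataclass(frozen=True)
class GrowthSpec:
    """Three-phase growth: flat lag, exponential at ``max_rate`` (log10 h^-1)
    to carrying capacity, then stationary."""

    inoculum_cfu_per_ml: float = 1e5
    lag_h: float = 6.0
    max_rate_log10_per_h: float = 1.0 / 3.0
    capacity_cfu_per_ml: float = 1e7
    #: observation CV of the (triplicate-mean) plate counts; 0 disables noise
    noise_cv: float = 0.023

    def __post_init__(self) -> None:
        if self.capacity_cfu_per_ml < self.inoculum_cfu_per_ml:
            raise ParameterError("carrying capacity below inoculum")
        if self.inoculum_cfu_per_ml <= 0 or self.max_rate_log10_per_h < 0:
            raise ParameterError("invalid growth parameters")
        if self.noise_cv < 0:
            raise ParameterError("noise CV must be >= 0")

    def cfu_at(self, t) -> np.ndarray:
        """Noise-free viable count at time(s) t (closed form)."""
        t = np.asarray(t, dtype=float)
        grown = self.inoculum_cfu_per_ml * 10.0 ** (
            self.max_rate_log10_per_h * np.clip(t - self.lag_h, 0.0, None)
        )
        return np.minimum(grown, self.capacity_cfu_per_ml)

    @property
    def capacity_time_h(self) -> float:
        """Time at which the noise-free curve reaches carrying capacity."""
        if self.max_rate_log10_per_h == 0:
            return self.lag_h
        span = math.log10(self.capacity_cfu_per_ml / self.inoculum_cfu_per_ml)
        return self.lag_h + span / self.max_rate_log10_per_h


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate one replicate's inputs."""

    excitation: WavelengthAxis = None  # type: ignore[assignment]
    emission: WavelengthAxis = None  # type: ignore[assignment]
    fluorophores: tuple[FluorophoreSpec, ...] = ()
    scatter: ScatterSpec = field(default_factory=ScatterSpec)
    absorbance: AbsorbanceModel = field(default_factory=AbsorbanceModel)
    noise_sd_qsu: float = 0.05
    growth: GrowthSpec = field(default_factory=GrowthSpec)
    qs_reference_intensity: float = 1000.0
    seed: int = 0
    times_h: tuple[float, ...] = SAMPLING_SCHEDULE

    def __post_init__(self) -> None:
        if self.excitation is None or self.emission is None:
            ex, em = instrument_grid()
            if self.excitation is None:
                object.__setattr__(self, "excitation", ex)
            if self.emission is None:
                object.__setattr__(self, "emission", em)
        if self.noise_sd_qsu < 0:
            raise ParameterError("noise SD must be >= 0")
        if self.qs_reference_intensity <= 0:
            raise ParameterError("QS reference intensity must be positive")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def simulate_growth(spec: SimulationSpec) -> GrowthCurve:
    """Three-phase growth curve sampled at the spec's schedule.

    Multiplicative lognormal observation noise (CV ``growth.noise_cv``) is
    applied under the spec seed; the noise-free curve is available from
    ``spec.growth.cfu_at``.
    """
    t = np.array(spec.times_h, dtype=float)
    cfu = spec.growth.cfu_at(t)
    if spec.growth.noise_cv > 0:
        rng = np.random.default_rng([spec.seed, 11])
        sigma = math.sqrt(math.log(1.0 + spec.growth.noise_cv**2))
        cfu = cfu * np.exp(rng.normal(0.0, sigma, size=t.size))
    return GrowthCurve(t, cfu)


def _signal_qsu(spec: SimulationSpec, t: float) -> np.ndarray:
    """Ideal fluorophore signal (QSU) on the grid at time t."""
    em = spec.emission.values[:, None]
    ex = spec.excitation.values[None, :]
    total = np.zeros((em.size, ex.size))
    for fl in spec.fluorophores:
        amp = fl.amplitude(t)
        if amp == 0:
            continue
        total += amp * np.exp(
            -0.5 * ((ex - fl.center_ex_nm) / fl.sigma_ex_nm) ** 2
        ) * np.exp(-0.5 * ((em - fl.center_em_nm) / fl.sigma_em_nm) ** 2)
    return total


def _scatter_qsu(spec: SimulationSpec) -> np.ndarray:
    em = spec.emission.values[:, None]
    ex = spec.excitation.values[None, :]
    sc = spec.scatter
    ridges = sc.amp1_qsu * np.exp(-0.5 * ((em - ex) / sc.width1_nm) ** 2)
    ridges += sc.amp2_qsu * np.exp(-0.5 * ((em - 2.0 * ex) / sc.width2_nm) ** 2)
    return ridges


def absorbance_at(spec: SimulationSpec, t: float) -> AbsorbanceSpectrum:
    """Sample absorbance at time t: baseline plus fluorophore bands."""
    model = spec.absorbance
    axis = WavelengthAxis.from_range(
        model.axis_start_nm, model.axis_stop_nm, model.axis_step_nm
    )
    a = np.full(len(axis), model.baseline)
    for fl in spec.fluorophores:
        a += (
            model.per_amplitude
            * fl.amplitude(t)
            * np.exp(-0.5 * ((axis.values - fl.center_ex_nm) / fl.sigma_ex_nm) ** 2)
        )
    return AbsorbanceSpectrum(axis, a)


def ideal_qsu_eem(spec: SimulationSpec, t: float) -> EEMatrix:
    """The noise-free, scatter-free, attenuation-free signal in QSU."""
    return EEMatrix(
        spec.excitation,
        spec.emission,
        _signal_qsu(spec, t),
        unit="QSU",
        meta={"time_h": t, "role": "ideal"},
    )


def simulate_eem(
    spec: SimulationSpec, t: float
) -> tuple[EEMatrix, EEMatrix, AbsorbanceSpectrum]:
    """Raw sample EEM, raw blank EEM and absorbance spectrum at time t.

    Sample = inner-filter-attenuated (signal + scatter) converted to raw
    counts plus additive Gaussian noise; blank = scatter only, attenuated
    by the same absorbance field (the blank shares the sample matrix, so
    correcting it with the sample absorbance inverts it exactly), plus its
    own noise. Noise streams derive from ``(seed, t)`` so each time point
    is independently reproducible.
    """
    if not (min(spec.times_h) <= t <= max(spec.times_h)):
        raise ParameterError(
            f"time {t} h outside the simulated range "
            f"[{min(spec.times_h)}, {max(spec.times_h)}] h"
        )
    abs_spec = absorbance_at(spec, t)
    a_ex = abs_spec.at(spec.excitation.values)
    a_em = abs_spec.at(spec.emission.values)
    atten = 10.0 ** (-(a_em[:, None] + a_ex[None, :]) / 2.0)
    scatter = _scatter_qsu(spec)
    ref = spec.qs_reference_intensity
    rng = np.random.default_rng([spec.seed, 13, int(round(t * 100))])
    shape = (len(spec.emission), len(spec.excitation))
    noise_sample = rng.normal(0.0, spec.noise_sd_qsu * ref, shape) if spec.noise_sd_qsu else 0.0
    noise_blank = rng.normal(0.0, spec.noise_sd_qsu * ref, shape) if spec.noise_sd_qsu else 0.0
    sample = EEMatrix(
        spec.excitation,
        spec.emission,
        ref * atten * (_signal_qsu(spec, t) + scatter) + noise_sample,
        unit="raw",
        meta={"time_h": t, "role": "sample"},
    )
    blank = EEMatrix(
        spec.excitation,
        spec.emission,
        ref * atten * scatter + noise_blank,
        unit="raw",
        meta={"time_h": t, "role": "blank"},
    )
    return sample, blank, abs_spec


def ideal_peak_qsu(
    spec: SimulationSpec,
    t: float,
    peak: PeakDefinition,
    crop: PreprocessConfig | None = None,
) -> float:
    """Ground-truth peak value: the peak-picking operator applied to the
    ideal signal on the cropped analysis window."""
    cfg = crop or PreprocessConfig()
    return pick_peak(crop_eem(ideal_qsu_eem(spec, t), cfg.crop_ex, cfg.crop_em), peak)


# ---------------------------------------------------------------------------
# Six-condition dataset
# ---------------------------------------------------------------------------

#: t=0 fluorescence baselines (QSU) shared by all conditions.
BASELINE_QSU = {"T": 2.2, "C": 0.9, "C+": 0.6}

#: 48 h plateau amplitudes (QSU) per condition, emulating the measured
#: endpoint intensities of the six nutrient x DOC conditions.
CONDITION_AMPLITUDES = {
    "SFW0": {"T": 6.5, "C": 14.8, "C+": 6.2},
    "SFW1": {"T": 11.3, "C": 21.5, "C+": 28.6},
    "SFW2": {"T": 56.0, "C": 81.5, "C+": 599.7},
    "SFW3": {"T": 51.8, "C": 162.7, "C+": 1215.8},
    "SFW4": {"T": 45.5, "C": 449.0, "C+": 592.0},
    "SFW5": {"T": 58.0, "C": 332.6, "C+": 612.7},
}

#: Carrying capacities (CFU ml^-1) by DOC dose: none, limited, excess.
CONDITION_CAPACITY = {
    "SFW0": 5e6, "SFW1": 5e6,
    "SFW2": 1e7, "SFW3": 1e7,
    "SFW4": 5e7, "SFW5": 5e7,
}

#: Amplitude ramp window (h): production rises linearly between these times.
RAMP_START_H = 4.0
RAMP_END_H = 16.0

_PEAK_SHAPES = {  # center_ex, center_em, sigma_ex, sigma_em (nm)
    "T": (275.0, 340.0, 15.0, 20.0),
    "C": (340.0, 445.0, 15.0, 20.0),
    "C+": (400.0, 487.5, 15.0, 20.0),
}


def ramp_kinetics(base: float, plateau: float,
                  start_h: float = RAMP_START_H, end_h: float = RAMP_END_H) -> dict[float, float]:
    """Flat at ``base`` until ``start_h``, linear rise to ``plateau`` at
    ``end_h``, flat thereafter."""
    return {0.0: base, start_h: base, end_h: plateau, 48.0: plateau}


def condition_spec(
    label: str,
    seed: int = 0,
    grid: str = "reduced",
    amplitude_scale: dict[str, float] | None = None,
) -> SimulationSpec:
    """Default SimulationSpec for one SFW condition label."""
    if label not in CONDITION_AMPLITUDES:
        raise ParameterError(f"unknown condition label {label!r}")
    ex, em = reduced_grid() if grid == "reduced" else instrument_grid()
    scale = amplitude_scale or {}
    fluors = []
    for p, (cx, cm, sx, sm) in _PEAK_SHAPES.items():
        kin = ramp_kinetics(BASELINE_QSU[p], CONDITION_AMPLITUDES[label][p])
        fl = FluorophoreSpec(p, cx, cm, sx, sm, kin)
        fluors.append(fl.scaled(scale.get(p, 1.0)))
    cap = CONDITION_CAPACITY[label]
    rate = (math.log10(cap) - 5.0) / 6.0  # inoculum 1e5 at 6 h -> capacity at 12 h
    growth = GrowthSpec(capacity_cfu_per_ml=cap, max_rate_log10_per_h=rate)
    return SimulationSpec(
        excitation=ex, emission=em, fluorophores=tuple(fluors), growth=growth, seed=seed
    )


def phase_recovery_experiment(
    n_curves: int = 100,
    seed: int = 0,
    lag_range_h: tuple[float, float] = (4.0, 8.0),
    rate_range: tuple[float, float] = (0.2, 0.45),
    capacity_log10_range: tuple[float, float] = (6.5, 7.5),
) -> float:
    """Fraction of simulated three-phase curves whose change points are
    recovered within one sampling interval.

    Draws ``n_curves`` growth parameter sets, simulates each at the
    standard schedule with the default observation noise, classifies
    phases, and checks both the lag->exponential and the
    exponential->stationary boundary against the generating values. The
    tolerance at each boundary is the width of the sampling interval
    containing the true change point.
    """
    from .growth import classify_phases

    times = np.array(SAMPLING_SCHEDULE)

    def within_one_interval(detected: float, true: float) -> bool:
        i = int(np.searchsorted(times, true))
        if i == 0:
            spacing = times[1] - times[0]
        elif i >= times.size:
            spacing = times[-1] - times[-2]
        else:
            spacing = times[i] - times[i - 1]
        return abs(detected - true) <= spacing + 1e-9

    rng = np.random.default_rng([seed, 501])
    recovered = 0
    for _ in range(n_curves):
        growth = GrowthSpec(
            lag_h=rng.uniform(*lag_range_h),
            max_rate_log10_per_h=rng.uniform(*rate_range),
            capacity_cfu_per_ml=10.0 ** rng.uniform(*capacity_log10_range),
        )
        spec = SimulationSpec(growth=growth, seed=int(rng.integers(2**31)))
        phases = classify_phases(simulate_growth(spec))
        if (
            len(phases) == 3
            and within_one_interval(phases[0].interval[1], growth.lag_h)
            and within_one_interval(phases[2].interval[0], growth.capacity_time_h)
        ):
            recovered += 1
    return recovered / n_curves


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _fmt_time(t: float) -> str:
    return f"t{t:05.2f}"


def simulate_condition_set(
    out_dir: str | Path,
    master_seed: int = 0,
    presets: dict[str, SimulationSpec] | None = None,
    replicates: int = 3,
    jitter_cv: float = 0.05,
    grid: str = "reduced",
) -> Path:
    """Write the full six-condition synthetic dataset to disk.

    Layout: ``<out>/<condition>/rep<k>/`` holds ``growth.csv`` and
    per-time ``eem_<t>.csv`` / ``blank_<t>.csv`` / ``absorbance_<t>.csv``
    files (a fresh blank accompanies every measurement);
    ``<out>/dataset.yaml`` records run inputs (QS reference
    intensity, schedule) and ``<out>/manifest.json`` the ground truth
    (per-replicate amplitude jitter, noise-free growth, true peak values,
    and the fraction table each condition should reproduce). Replicate
    variability enters as a lognormal per-peak amplitude jitter under
    seeds derived from the master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if presets is None:
        presets = {
            label: condition_spec(label, grid=grid) for label in CONDITION_ORDER
        }
    missing = [l for l in CONDITION_ORDER if l not in presets]
    if missing:
        raise ParameterError(f"presets missing condition label(s) {missing}")

    peaks = standard_peaks()
    manifest: dict = {"master_seed": master_seed, "replicates": replicates,
                      "times_h": list(SAMPLING_SCHEDULE), "conditions": {}}
    ref_intensity = None
    for ci, label in enumerate(CONDITION_ORDER):
        base = presets[label]
        ref_intensity = base.qs_reference_intensity
        cond_truth: dict = {
            "growth": {
                "inoculum_cfu_per_ml": base.growth.inoculum_cfu_per_ml,
                "lag_h": base.growth.lag_h,
                "max_rate_log10_per_h": base.growth.max_rate_log10_per_h,
                "capacity_cfu_per_ml": base.growth.capacity_cfu_per_ml,
                "capacity_time_h": base.growth.capacity_time_h,
            },
            "replicates": {},
        }
        times = np.array(base.times_h)
        true_cfu = base.growth.cfu_at(times)
        cond_truth["growth"]["cfu_per_ml"] = list(true_cfu)
        # replicate-mean per-cell fluorescence truth, built alongside generation
        mean_f = {p.name: np.zeros(times.size) for p in peaks}
        for ri in range(1, replicates + 1):
            rep_seed = _derived_seed(master_seed, ci, ri)
            rng_j = np.random.default_rng([master_seed, ci, ri, 7])
            sigma = math.sqrt(math.log(1.0 + jitter_cv**2)) if jitter_cv > 0 else 0.0
            jitter = {
                p.name: float(np.exp(rng_j.normal(0.0, sigma))) if sigma else 1.0
                for p in peaks
            }
            spec = replace(
                base,
                seed=rep_seed,
                fluorophores=tuple(
                    fl.scaled(jitter[fl.name]) for fl in base.fluorophores
                ),
            )
            rep_dir = out / label / f"rep{ri}"
            rep_dir.mkdir(parents=True, exist_ok=True)
            curve = simulate_growth(spec)
            curve.replicate = f"rep{ri}"
            curve.condition = label
            write_growth_curve(curve, rep_dir / "growth.csv")
            true_peaks = {p.name: [] for p in peaks}
            for t in spec.times_h:
                sample, blank, abs_spec = simulate_eem(spec, t)
                sample.meta.update(condition=label, replicate=f"rep{ri}")
                write_eem(sample, rep_dir / f"eem_{_fmt_time(t)}.csv")
                write_absorbance(abs_spec, rep_dir / f"absorbance_{_fmt_time(t)}.csv")
                # a fresh blank accompanies every measurement
                blank.meta.update(condition=label, replicate=f"rep{ri}")
                write_eem(blank, rep_dir / f"blank_{_fmt_time(t)}.csv")
                for p in peaks:
                    true_peaks[p.name].append(ideal_peak_qsu(spec, t, p))
            for p in peaks:
                mean_f[p.name] += np.array(true_peaks[p.name]) * 1e6 / true_cfu
            cond_truth["replicates"][f"rep{ri}"] = {
                "seed": rep_seed,
                "amplitude_jitter": jitter,
                "true_peak_qsu": true_peaks,
            }
        for p in mean_f:
            mean_f[p] /= replicates
        ft = peak_fraction_table(
            float(np.max(mean_f["T"])),
            float(np.max(mean_f["C"])),
            float(np.max(mean_f["C+"])),
        )
        cond_truth["fraction_table"] = {
            "f": ft.f, "percent": ft.percent, "f_total": ft.f_total,
        }
        manifest["conditions"][label] = cond_truth

    (out / "dataset.yaml").write_text(
        yaml.safe_dump(
            {
                "qs_reference_intensity": ref_intensity,
                "times_h": list(SAMPLING_SCHEDULE),
                "conditions": list(CONDITION_ORDER),
                "replicates": replicates,
                "master_seed": master_seed,
            },
            sort_keys=True,
        )
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
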