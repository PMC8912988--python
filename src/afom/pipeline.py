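"""Run orchestration: dataset-level preprocess and analyze passes.

These functions operate on the on-disk dataset layout that
:func:`afom.synth.simulate_condition_set` emits (and that instrument
exports can be arranged into):

    <dataset>/
      dataset.yaml              # qs_reference_intensity, schedule, labels
      <condition>/rep<k>/
        growth.csv              # time_h, cfu_per_ml
        eem_t<tt.tt>.csv        # raw sample EEM per time point
        blank_t<tt.tt>.csv      # fresh blank per time point
                                # (or a single shared blank.csv)
        absorbance_t<tt.tt>.csv # paired absorbance spectrum

The CLI and the numbered analysis drivers are thin wrappers over these.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import yaml

from .eem import read_absorbance, read_eem, write_eem
from .errors import ConfigError, InputError
from .growth import read_growth_curves
from .peaks import PeakDefinition, extract_series, standard_peaks
from .preprocess import PreprocessConfig, QsReference, preprocess_pipeline
from .summary import condition_report, write_report

logger = logging.getLogger(__name__)

_EEM_RE = re.compile(r"eem_t(\d+\.\d+)\.csv$")


def _dataset_config(dataset_dir: Path) -> dict:
    cfg_path = dataset_dir / "dataset.yaml"
    if not cfg_path.exists():
        raise ConfigError(f"dataset config not found: {cfg_path}")
    return yaml.safe_load(cfg_path.read_text())


def _replicate_dirs(root: Path) -> list[tuple[str, str, Path]]:
    out = []
    for cond_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for rep_dir in sorted(p for p in cond_dir.iterdir() if p.is_dir()):
            out.append((cond_dir.name, rep_dir.name, rep_dir))
    if not out:
        raise InputError(f"no condition/replicate directories under {root}")
    return out


def run_preprocess(
    dataset_dir: str | Path,
    out_dir: str | Path,
    config: PreprocessConfig | None = None,
    qs_reference_intensity: float | None = None,
) -> list[Path]:
    """Correct every raw EEM in a dataset and write QSU EEMs mirroring the
    input layout. Growth files are copied through unchanged."""
    dataset_dir = Path(dataset_dir)
    out_root = Path(out_dir)
    ref_val = qs_reference_intensity
    if ref_val is None:
        ref_val = _dataset_config(dataset_dir).get("qs_reference_intensity")
        if ref_val is None:
            raise ConfigError("qs_reference_intensity missing from dataset.yaml")
    ref = QsReference(float(ref_val))
    written = []
    for cond, rep, rep_dir in _replicate_dirs(dataset_dir):
        shared_blank = None
        if (rep_dir / "blank.csv").exists():
            shared_blank = read_eem(rep_dir / "blank.csv")
        dest = out_root / cond / rep
        dest.mkdir(parents=True, exist_ok=True)
        for eem_path in sorted(rep_dir.glob("eem_t*.csv")):
            m = _EEM_RE.search(eem_path.name)
            if not m:
                continue
            abs_path = rep_dir / f"absorbance_t{m.group(1)}.csv"
            if not abs_path.exists():
                raise ConfigError(f"absorbance file not found: {abs_path}")
            blank_path = rep_dir / f"blank_t{m.group(1)}.csv"
            if blank_path.exists():
                blank = read_eem(blank_path)
            elif shared_blank is not None:
                blank = shared_blank
            else:
                raise ConfigError(
                    f"blank EEM not found: {blank_path} (and no shared blank.csv)"
                )
            sample = read_eem(eem_path)
            corrected = preprocess_pipeline(
                sample, blank, read_absorbance(abs_path), ref, config
            )
            out_path = dest / eem_path.name
            write_eem(corrected, out_path)
            written.append(out_path)
        growth = rep_dir / "growth.csv"
        if growth.exists():
            (dest / "growth.csv").write_text(growth.read_text())
    logger.info("preprocessed %d EEMs into %s", len(written), out_root)
    return written


def run_analyze(
    corrected_dir: str | Path,
    out_dir: str | Path,
    peaks: list[PeakDefinition] | None = None,
    mode: str = "max",
    endpoint_time_h: float = 48.0,
) -> dict:
    """Extract peak series and growth data from a corrected dataset and
    emit the per-condition report tables."""
    corrected_dir = Path(corrected_dir)
    peaks = peaks or standard_peaks()
    fluorescence: dict[str, list] = {}
    growth: dict[str, list] = {}
    for cond, rep, rep_dir in _replicate_dirs(corrected_dir):
        eems = []
        for eem_path in sorted(rep_dir.glob("eem_t*.csv")):
            m = _EEM_RE.search(eem_path.name)
            if not m:
                continue
            eem = read_eem(eem_path)
            t = float(eem.meta.get("time_h", m.group(1)))
            eems.append((t, eem))
        if not eems:
            raise InputError(f"no corrected EEMs under {rep_dir}")
        series = extract_series(eems, peaks, replicate=rep, condition=cond)
        fluorescence.setdefault(cond, []).append(series)
        growth_path = rep_dir / "growth.csv"
        if not growth_path.exists():
            raise InputError(f"condition {cond!r}: growth file missing for {rep}")
        curves = read_growth_curves(growth_path)
        if len(curves) != 1:
            raise InputError(f"{growth_path}: expected exactly one growth curve")
        growth.setdefault(cond, []).append(curves[0])
    report = condition_report(
        fluorescence, growth, mode=mode, endpoint_time_h=endpoint_time_h
    )
    write_report(report, out_dir)
    return report
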