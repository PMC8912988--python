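"""Per-condition summary tables: endpoint intensities and f_QSU/CFU fractions.

The six simulated-freshwater (SFW) conditions cross two nutrient regimes
(low: 0.3 mg L^-1 NO3-, 0 mg L^-1 PO4^3-; high: 50 mg L^-1 NO3-,
0.1 mg L^-1 PO4^3-) with three glucose-DOC doses (0, 5, 800 mg L^-1).
Summaries report, per condition: mean +/- sample SD peak intensities at the
endpoint time, and the fraction table -- per-peak fluorescence per 10^6 CFU
(f), its sum f_total over Peaks T, C and C+, and each peak's integer
percent share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedFractionError
from .growth import GrowthCurve, per_cell_series
from .peaks import STANDARD_PEAK_NAMES, PeakSeries


@dataclass(frozen=True)
class Condition:
    """One SFW condition: nutrient and DOC concentrations with its label."""

    label: str
    nitrate_mg_per_l: float
    phosphate_mg_per_l: float
    doc_mg_per_l: float
    description: str = ""


#: The fixed label -> (NO3-, PO4^3-, DOC) mapping, all mg L^-1.
CONDITIONS: dict[str, Condition] = {
    "SFW0": Condition("SFW0", 0.3, 0.0, 0.0, "low nutrient, no DOC"),
    "SFW1": Condition("SFW1", 50.0, 0.1, 0.0, "high nutrient, no DOC"),
    "SFW2": Condition("SFW2", 0.3, 0.0, 5.0, "low nutrient, limited DOC"),
    "SFW3": Condition("SFW3", 50.0, 0.1, 5.0, "high nutrient, limited DOC"),
    "SFW4": Condition("SFW4", 0.3, 0.0, 800.0, "low nutrient, excess DOC"),
    "SFW5": Condition("SFW5", 50.0, 0.1, 800.0, "high nutrient, excess DOC"),
}

CONDITION_ORDER = tuple(CONDITIONS)


@dataclass(frozen=True)
class FractionTable:
    """Per-peak f_QSU/CFU, integer percent shares, and their sum f_total."""

    f: dict[str, float]
    percent: dict[str, int]
    f_total: float


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def peak_fraction_table(f_T: float, f_C: float, f_Cplus: float) -> FractionTable:
    """Fraction table from the three per-peak f_QSU/CFU values.

    ``f_total`` is the exact pre-rounding sum; percents are nearest-integer
    with ties rounded half-up, so they sum to 100 +/- 1.
    """
    f = {"T": float(f_T), "C": float(f_C), "C+": float(f_Cplus)}
    if any(v < 0 for v in f.values()):
        raise InputError(f"peak f values must be non-negative, got {f}")
    f_total = sum(f.values())
    if f_total == 0:
        raise UndefinedFractionError("fraction table undefined for all-zero peaks")
    percent = {p: _round_half_up(100.0 * v / f_total) for p, v in f.items()}
    return FractionTable(f=f, percent=percent, f_total=f_total)


def endpoint_table(series: list[PeakSeries], time_h: float = 48.0) -> pd.DataFrame:
    """Per-peak mean and sample SD (n-1) across replicates at one time.

    Requires at least two replicates; a replicate missing the time point is
    an error naming it.
    """
    if len(series) < 2:
        raise InputError(f"endpoint table needs >= 2 replicates, got {len(series)}")
    rows = {}
    for s in series:
        if not np.any(np.isclose(s.times_h, time_h, rtol=0, atol=1e-9)):
            raise InputError(
                f"replicate {s.replicate!r} has no observation at {time_h:g} h"
            )
        rows[s.replicate] = {p: s.value(p, time_h) for p in s.peak_names}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    out = pd.DataFrame({"mean": frame.mean(axis=0), "sd": frame.std(axis=0, ddof=1)})
    out.index.name = "peak"
    return out


def condition_fraction_table(
    series: list[PeakSeries],
    curves: list[GrowthCurve],
    mode: str = "max",
    endpoint_time_h: float = 48.0,
) -> FractionTable:
    """Fraction table for one condition from replicate fluorescence + growth.

    Per replicate, f_QSU/CFU is computed at every time; replicates are
    averaged per time, then each peak contributes either its time-course
    maximum f (``mode="max"``, the default, reflecting peak per-cell
    production) or its value at ``endpoint_time_h`` (``mode="endpoint"``).
    """
    if mode not in ("max", "endpoint"):
        raise InputError(f"unknown fraction mode {mode!r}")
    if len(series) != len(curves) or not series:
        raise InputError("need matched, non-empty fluorescence and growth replicates")
    frames = [per_cell_series(s, c) for s, c in zip(series, curves)]
    mean_f = sum(frames[1:], start=frames[0].copy()) / len(frames)
    if mode == "max":
        f = mean_f.max(axis=0)
    else:
        hits = np.flatnonzero(
            np.isclose(mean_f.index.to_numpy(float), endpoint_time_h, rtol=0, atol=1e-9)
        )
        if hits.size == 0:
            raise InputError(f"no observation at endpoint time {endpoint_time_h:g} h")
        f = mean_f.iloc[hits[0]]
    return peak_fraction_table(f["T"], f["C"], f["C+"])


def condition_report(
    fluorescence: dict[str, list[PeakSeries]],
    growth: dict[str, list[GrowthCurve]],
    conditions: dict[str, Condition] | None = None,
    mode: str = "max",
    endpoint_time_h: float = 48.0,
) -> dict:
    """Assemble the full per-condition report.

    Returns a dict with keys ``conditions`` (metadata frame), ``endpoint``
    (peaks x condition mean/sd at the endpoint time), ``fractions``
    (f / percent / f_total per condition) and ``percell_series``
    (per-condition replicate-mean f_QSU/CFU time courses). Conditions are
    ordered SFW0 -> SFW5; a label absent from the mapping is a config
    error, a condition without growth data an input error naming it.
    """
    cond_map = conditions or CONDITIONS
    labels = sorted(fluorescence, key=lambda l: list(cond_map).index(l) if l in cond_map else -1)
    for label in labels:
        if label not in cond_map:
            raise InputError(
                f"condition label {label!r} not in the condition mapping "
                f"({list(cond_map)})"
            )
        if label not in growth or not growth[label]:
            raise InputError(f"condition {label!r} has no growth data")

    meta = pd.DataFrame(
        [
            {
                "condition": cond_map[l].label,
                "description": cond_map[l].description,
                "nitrate_mg_per_l": cond_map[l].nitrate_mg_per_l,
                "phosphate_mg_per_l": cond_map[l].phosphate_mg_per_l,
                "doc_mg_per_l": cond_map[l].doc_mg_per_l,
            }
            for l in labels
        ]
    ).set_index("condition")

    endpoint = {}
    fractions = {}
    percell = {}
    for label in labels:
        endpoint[label] = endpoint_table(fluorescence[label], endpoint_time_h)
        ft = condition_fraction_table(
            fluorescence[label], growth[label], mode=mode, endpoint_time_h=endpoint_time_h
        )
        fractions[label] = ft
        frames = [
            per_cell_series(s, c)
            for s, c in zip(fluorescence[label], growth[label])
        ]
        percell[label] = sum(frames[1:], start=frames[0].copy()) / len(frames)

    ep = pd.concat(endpoint, axis=1)  # columns: (condition, mean|sd)
    fr_rows = []
    for label in labels:
        ft = fractions[label]
        for p in STANDARD_PEAK_NAMES:
            fr_rows.append(
                {"condition": label, "peak": p, "f": ft.f[p], "percent": ft.percent[p]}
            )
        fr_rows.append(
            {"condition": label, "peak": "f_total", "f": ft.f_total, "percent": 100}
        )
    fr = pd.DataFrame(fr_rows).set_index(["condition", "peak"])
    return {
        "conditions": meta,
        "endpoint": ep,
        "fractions": fr,
        "fraction_tables": fractions,
        "percell_series": percell,
    }


def write_report(report: dict, out_dir: str | Path) -> list[Path]:
    """Write report tables as delimited text under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("conditions", "endpoint", "fractions"):
        p = out / f"{name}.tsv"
        report[name].to_csv(p, sep="\t", float_format="%.10g")
        written.append(p)
    for label, frame in report["percell_series"].items():
        p = out / f"percell_{label}.tsv"
        frame.to_csv(p, sep="\t", float_format="%.10g")
        written.append(p)
    return written
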