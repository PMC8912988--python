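import json

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from afom.eem import EEMatrix, WavelengthAxis
from afom.pipeline import run_analyze, run_preprocess
from afom.synth import simulate_condition_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_grid():
    """A coarse grid whose analysis window covers all standard peak regions."""
    ex = WavelengthAxis.from_range(200.0, 600.0, 5.0)
    em = WavelengthAxis.from_range(247.88, 829.85, 4.64)
    return ex, em


@pytest.fixture
def uniform_eem(small_grid):
    def make(value: float = 1.0, unit: str = "QSU") -> EEMatrix:
        ex, em = small_grid
        return EEMatrix(ex, em, np.full((len(em), len(ex)), value), unit=unit)

    return make


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """The default six-condition dataset run through the full pipeline once.

    Returns (dataset root, analyze report, ground-truth manifest).
    """
    root = tmp_path_factory.mktemp("afom_dataset")
    simulate_condition_set(root / "raw", master_seed=1)
    run_preprocess(root / "raw", root / "corrected")
    report = run_analyze(root / "corrected", root / "tables")
    manifest = json.loads((root / "raw" / "manifest.json").read_text())
    return root, report, manifest
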