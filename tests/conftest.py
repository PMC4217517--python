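import json
from pathlib import Path

import numpy as np
import pytest

import forksim as fs

CASES_DIR = Path(__file__).parent / "cases"


def load_oracle_cases():
    """Stochastic cross-validation scenarios stored as JSON in tests/cases."""
    cases = []
    for path in sorted(CASES_DIR.glob("*.json")):
        with open(path) as fh:
            spec = json.load(fh)
        spec["name"] = path.stem
        cases.append(spec)
    return cases


def build_landscape(spec: dict) -> fs.Landscape:
    spec = dict(spec)
    kind = spec.pop("kind")
    n_bins = spec.pop("n_bins")
    return fs.synthetic_landscape(kind, n_bins, **spec)


def engine_mean_sem(record):
    """Per-bin mean replication sweep and its standard error."""
    n = record.n_cycles
    mean = record.timing_sum / n
    var = record.timing_sumsq / n - mean**2
    return mean, np.sqrt(np.maximum(var, 0) / n)


def run_engine_case(case: dict, seed: int):
    """Run the engine under an oracle case's conditions."""
    landscape = build_landscape(case["landscape"])
    eng = case["engine"]
    config = fs.SimulationConfig(
        ncells=eng["ncells"],
        nfork=case["nfork"],
        ntherm=eng["ntherm"],
        nmeas=eng["nmeas"],
        stepsize=eng["stepsize"],
        pprogress=case.get("pprogress", 1.0),
        prelease=case.get("prelease", 0.0),
        initiation_mode=case.get("initiation_mode", "per_pair"),
        seed=seed,
    )
    return fs.run_simulation(config, landscape)


def run_oracle_case(case: dict, seed: int, n_cycles: int | None = None):
    """Run the independent reference simulator under the same conditions."""
    landscape = build_landscape(case["landscape"])
    return fs.oracle.reference_simulate(
        landscape,
        n_cycles if n_cycles is not None else case["n_cycles"],
        nfork=case["nfork"],
        pprogress=case.get("pprogress", 1.0),
        prelease=case.get("prelease", 0.0),
        initiation_mode=case.get("initiation_mode", "per_pair"),
        seed=seed,
    )


@pytest.fixture
def delta10():
    return fs.synthetic_landscape("delta", 10, origin=0)


@pytest.fixture
def uniform4():
    return fs.synthetic_landscape("uniform", 4, p=1.0)


@pytest.fixture
def quick_config():
    """Small but non-trivial population run."""
    return fs.SimulationConfig(
        ncells=20, nfork=4, ntherm=10, nmeas=5, stepsize=20, seed=42
    )
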