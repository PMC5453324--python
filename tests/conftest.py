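import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chemopair.pipeline import RunConfig, run_pipeline
from chemopair import synthetic_data as sd


@pytest.fixture(scope="session")
def default_truth():
    return sd.simulate_patient(sd.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_reads(default_truth):
    return sd.simulate_reads(default_truth)


def _run(scenario, seed, **kw):
    return run_pipeline(
        RunConfig(scenario=scenario, seed=seed, outdir=None, **kw)
    )


@pytest.fixture(scope="session")
def near_sync_result():
    return _run("near_synchronous", 11, run_signatures=True)


@pytest.fixture(scope="session")
def before_result():
    return _run("before", 12, run_signatures=False)


@pytest.fixture(scope="session")
def after_result():
    return _run("after", 13, run_signatures=False)


@pytest.fixture(scope="session")
def recent_result():
    return _run("recent", 14, run_signatures=False)


@pytest.fixture(scope="session")
def private_loh_result():
    return _run("private_loh", 15, run_signatures=False)
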