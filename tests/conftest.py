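import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from apmskit import Dataset, ProteinRecord, PurificationRun

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_run(run_id, bait, counts, *, replicate=1, condition="untreated", intensities=None):
    return PurificationRun(
        run_id=run_id,
        bait_id=bait,
        replicate_index=replicate,
        condition=condition,
        counts=counts,
        intensities=intensities or {},
    )


@pytest.fixture
def tiny_dataset():
    """Two baits x two replicates over five proteins plus two mock controls.

    CONT1 is an abundant contaminant present everywhere; PREYA binds BAIT1
    only, PREYB binds both baits.
    """
    proteins = {
        "BAIT1": ProteinRecord("BAIT1", 500, True),
        "BAIT2": ProteinRecord("BAIT2", 400, True),
        "PREYA": ProteinRecord("PREYA", 300),
        "PREYB": ProteinRecord("PREYB", 200),
        "CONT1": ProteinRecord("CONT1", 250),
    }
    runs = [
        make_run("b1r1", "BAIT1", {"BAIT1": 50, "PREYA": 30, "PREYB": 10, "CONT1": 20}, replicate=1),
        make_run("b1r2", "BAIT1", {"BAIT1": 60, "PREYA": 24, "PREYB": 12, "CONT1": 18}, replicate=2),
        make_run("b2r1", "BAIT2", {"BAIT2": 40, "PREYB": 16, "CONT1": 22}, replicate=1),
        make_run("b2r2", "BAIT2", {"BAIT2": 44, "PREYB": 14, "CONT1": 25}, replicate=2),
    ]
    controls = [
        make_run("c1", "CONTROL:GFP", {"CONT1": 30, "BAIT1": 1}, replicate=1),
        make_run("c2", "CONTROL:GFP", {"CONT1": 28}, replicate=2),
    ]
    return Dataset(proteins=proteins, runs=runs, control_runs=controls)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
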