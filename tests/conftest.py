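import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ischemap.recording import FiducialTable
from ischemap.synth import (
    SimulationConfig,
    VFHazardModel,
    make_trajectory,
    simulate_animal,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: reference-beat instant used by the generator (ms from trace start)
QRS_TIME = 150.0
FS = 4000.0


@pytest.fixture(scope="session")
def control_trajectory():
    return make_trajectory(group="control")


@pytest.fixture(scope="session")
def melatonin_trajectory():
    return make_trajectory(group="melatonin")


@pytest.fixture(scope="session")
def no_vf_hazard():
    """Hazard with probability zero everywhere (full 11-minute protocols)."""
    return VFHazardModel(intercept=-np.inf)


@pytest.fixture(scope="session")
def signal_animal(control_trajectory, no_vf_hazard):
    """One noiseless control animal with full waveform recordings (seed 1)."""
    return simulate_animal(
        "A1",
        "control",
        control_trajectory,
        no_vf_hazard,
        seed=1,
        config=SimulationConfig(signals=True),
    )


@pytest.fixture(scope="session")
def recording(signal_animal):
    """The baseline (minute 0) recording of the seed-1 animal."""
    return signal_animal.recordings[0]


def make_fiducial_table(rows: list[dict], rr_ms: float = 600.0, minute: float = 0.0):
    """Assemble a FiducialTable from minimal row dicts (test helper)."""
    defaults = {"flag": "ok", "reason": ""}
    full = []
    for i, row in enumerate(rows):
        entry = {
            "lead_id": row.get("lead_id", f"L{i:02d}"),
            "wall": row.get("wall", "LV"),
            "level": row.get("level", "apex"),
            "zone": row.get("zone", "ischemic"),
            "at_ms": row["at_ms"],
            "rt_ms": row["rt_ms"],
            "ari_ms": row["rt_ms"] - row["at_ms"],
            **defaults,
        }
        entry.update({k: v for k, v in row.items() if k in ("flag", "reason")})
        full.append(entry)
    return FiducialTable(frame=pd.DataFrame(full), rr_ms=rr_ms, minute=minute)
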