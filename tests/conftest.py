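import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from schwannoma.cohort import (
    ACTIVE,
    AUDIO_FREQS_KHZ,
    WAS,
    CheckupRecord,
    Cohort,
    PatientHistory,
)

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def flat_audiogram(level: float) -> dict:
    return {f: level for f in AUDIO_FREQS_KHZ}


def make_checkup(pid="P1", t=0.0, vs=40.0, h=20.0, **kw) -> CheckupRecord:
    """A complete checkup with flat audiograms at the given levels."""
    defaults = dict(
        pta_vs=flat_audiogram(vs),
        pta_h=flat_audiogram(h),
        srt=35.0,
        sds=90.0,
        mdl=60.0,
        mdr=85.0,
        size_mm=10.0,
        koos=2,
        decision=WAS,
    )
    defaults.update(kw)
    return CheckupRecord(patient_id=pid, t=t, **defaults)


@pytest.fixture
def small_cohort() -> Cohort:
    """Two patients: one wait-and-scan (2 checkups), one active (3 checkups)."""
    p1 = PatientHistory("P1", (
        make_checkup("P1", 0.0),
        make_checkup("P1", 300.0, size_mm=10.2),
    ))
    p2 = PatientHistory("P2", (
        make_checkup("P2", 0.0, koos=2, size_mm=14.0),
        make_checkup("P2", 350.0, koos=2, size_mm=18.0),
        make_checkup("P2", 700.0, koos=3, size_mm=22.0, decision=ACTIVE),
    ))
    return Cohort((p1, p2), provenance="fixture")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
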