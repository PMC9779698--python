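import numpy as np
import pytest

from motornorms import (PocoSegment, PocoTruth, SasTruth, SipTruth,
                        TandemTruth, WalkTruth, gen_poco_recording,
                        gen_sas_recording, gen_sip_recording,
                        gen_tandem_recording, gen_walk_recording, preprocess)


@pytest.fixture(scope="session")
def scsw_rec():
    """Noise-free comfortable-speed walk with the default study-like truth."""
    return gen_walk_recording(
        WalkTruth(speed=1.2, cadence=110, step_width=0.10,
                  arm_amplitude_left=26.0, arm_amplitude_right=26.0, seed=1)
    )


@pytest.fixture(scope="session")
def scsw_prep(scsw_rec):
    return preprocess(scsw_rec)


@pytest.fixture(scope="session")
def sip_rec():
    return gen_sip_recording(SipTruth(seed=4, stride_cov=0.0))


@pytest.fixture(scope="session")
def sip_prep(sip_rec):
    return preprocess(sip_rec)


@pytest.fixture(scope="session")
def sas_rec():
    return gen_sas_recording(SasTruth(seed=5))


@pytest.fixture(scope="session")
def poco_rec():
    return gen_poco_recording(PocoTruth(
        open_segment=PocoSegment(pitch_amplitude=0.5, pitch_freq=0.25,
                                 roll_amplitude=0.4, roll_freq=0.2),
        closed_segment=PocoSegment(pitch_amplitude=0.75, pitch_freq=0.25,
                                   roll_amplitude=0.6, roll_freq=0.2),
        seed=6,
    ))


@pytest.fixture(scope="session")
def slw_rec():
    return gen_tandem_recording(TandemTruth(
        speed=0.35, speed_cov=0.0, roll_amplitude=2.5, roll_freq=0.5,
        cadence=72, seed=3,
    ))


def assert_close(measured, expected, rel=None, abs_=None, label=""):
    if rel is not None:
        assert measured == pytest.approx(expected, rel=rel), \
            f"{label}: {measured} vs {expected} (rel {rel})"
    else:
        assert measured == pytest.approx(expected, abs=abs_), \
            f"{label}: {measured} vs {expected} (abs {abs_})"
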