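import pytest

from covisa.simulate import (
    Hrf,
    ScanProtocol,
    build_cue_schedule,
    default_noise,
    default_phantom,
)


@pytest.fixture(scope="session")
def toy_protocol() -> ScanProtocol:
    return ScanProtocol().toy()


@pytest.fixture(scope="session")
def toy_schedule(toy_protocol):
    return build_cue_schedule(toy_protocol, seed=1)


@pytest.fixture(scope="session")
def toy_phantom(toy_protocol):
    return default_phantom(toy_protocol.matrix)


@pytest.fixture(scope="session")
def hrf(toy_protocol) -> Hrf:
    return Hrf.canonical(toy_protocol.tr_seconds)


@pytest.fixture(scope="session")
def localizer_volumes(toy_protocol, toy_schedule, toy_phantom, hrf):
    """Localizer-phase volumes of the default synthetic session (seed 1)."""
    from covisa.simulate import OnlineSynthesizer

    synth = OnlineSynthesizer(toy_protocol, toy_phantom, hrf, default_noise(1))
    return [synth.next_volume(s) for s in toy_schedule.states()]


@pytest.fixture(scope="session")
def localizer_result(localizer_volumes, toy_schedule, toy_protocol, hrf):
    from covisa.pipeline import run_localizer

    return run_localizer(localizer_volumes, toy_schedule, toy_protocol, hrf, seed=1)
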