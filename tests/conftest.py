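import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from melodylearn.melodies import acquisition_melody
from melodylearn.performance_model import NoteEvent, Performance

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def melody():
    return acquisition_melody()


@pytest.fixture
def perfect_performance(melody):
    """Metronomically exact, pitch-perfect rendition of the study melody."""
    return Performance(
        events=tuple(NoteEvent(p, t) for p, t in zip(melody.pitches, melody.grid_onsets))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def render(melody, onsets=None, pitches=None) -> Performance:
    """Build a performance from explicit onsets/pitches (defaults: exact)."""
    pitches = melody.pitches if pitches is None else tuple(pitches)
    onsets = melody.grid_onsets if onsets is None else tuple(onsets)
    return Performance(events=tuple(NoteEvent(p, t) for p, t in zip(pitches, onsets)))
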