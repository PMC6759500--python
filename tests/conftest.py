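import numpy as np
import pytest

from emochimera import (
    CorpusConfig,
    RespondentConfig,
    Waveform,
    build_stimulus_set,
    generate_corpus,
    score_responses,
    simulate_responses,
)

RATE = 44100.0


def make_tone(freq=440.0, duration_s=1.0, rate=RATE, amp=1.0, label="none", id="tone"):
    t = np.arange(int(duration_s * rate)) / rate
    return Waveform(amp * np.cos(2 * np.pi * freq * t), rate, label=label, id=id)


@pytest.fixture
def tone():
    return make_tone


@pytest.fixture
def am_tone():
    """(1 + depth·cos(2π f_mod t))·cos(2π f_c t)."""

    def _make(f_mod=4.0, depth=0.5, f_c=440.0, duration_s=2.0, rate=RATE):
        t = np.arange(int(duration_s * rate)) / rate
        return Waveform(
            (1 + depth * np.cos(2 * np.pi * f_mod * t)) * np.cos(2 * np.pi * f_c * t),
            rate, id="am",
        )

    return _make


def interior(x, frac=0.9):
    """Central ``frac`` of the samples (edge transients excluded)."""
    n = len(x)
    cut = int(n * (1 - frac) / 2)
    return x[cut: n - cut]


@pytest.fixture(scope="session")
def tiny_corpus():
    """2 excerpts (1 happy + 1 sad), the smallest balanced corpus."""
    waves, manifest = generate_corpus(CorpusConfig(n_per_emotion=1, seed=11))
    return waves, manifest


@pytest.fixture(scope="session")
def tiny_manifest(tiny_corpus):
    waves, _ = tiny_corpus
    return build_stimulus_set(waves, write_audio=False)


@pytest.fixture(scope="session")
def tiny_scored(tiny_manifest):
    rt = simulate_responses(tiny_manifest, RespondentConfig(seed=7))
    return score_responses(rt)
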