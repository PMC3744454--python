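import numpy as np
import pytest

from larksong import synth
from larksong.segment import Waveform


@pytest.fixture(scope="session")
def zero_jitter_params():
    """Ascending-phase settings with deterministic timing (no jitter)."""
    return synth.PhaseParams(
        phase="ascending",
        mean_syllable_duration_ms=140.0,
        mean_gap_ms=48.0,
        peak_freq_hz=4074.0,
        bandwidth_hz=1755.0,
        target_sylver=8.0,
        jitter_cv=0.0,
    )


@pytest.fixture(scope="session")
def small_repertoire():
    return synth.generate_repertoire(n_types=12, n_group_sequences=0, seed=11)


@pytest.fixture(scope="session")
def rendered_song(zero_jitter_params, small_repertoire):
    """A 50-syllable zero-jitter song with its ground-truth annotations."""
    seq = synth.generate_label_sequence(
        small_repertoire, zero_jitter_params, n_syllables=50, seed=7
    )
    wav, truth = synth.render_song(seq, zero_jitter_params, sample_rate=44100, seed=3)
    return wav, truth, seq


def tone(freq_hz: float, duration_s: float, rate: int = 44100, amp: float = 0.5) -> Waveform:
    t = np.arange(int(duration_s * rate)) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq_hz * t), rate)
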