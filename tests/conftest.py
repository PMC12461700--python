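import numpy as np
import pytest

import rhythmsync as rs


@pytest.fixture(scope="session")
def stimuli_full():
    """Default study stimuli: five tempi, >= 90-s blocks."""
    return rs.pipeline.build_stimuli()


@pytest.fixture(scope="session")
def stimuli_small():
    """Scaled-down blocks (>= 36 s) for cohort-level tests."""
    return rs.pipeline.build_stimuli(min_block_s=36.0)


@pytest.fixture(scope="session")
def kernel():
    return rs.canonical_kernel()


@pytest.fixture(scope="session")
def oscillator_outputs(stimuli_full):
    return rs.pipeline.run_oscillator(stimuli_full)


@pytest.fixture(scope="session")
def evoked_outputs(stimuli_full, kernel):
    return rs.pipeline.run_evoked(stimuli_full, kernel)


@pytest.fixture(scope="session")
def oscillator_pcm(oscillator_outputs, stimuli_full):
    return rs.pipeline.model_pcm(
        oscillator_outputs, stimuli_full.envelopes, source="oscillator")


@pytest.fixture(scope="session")
def evoked_pcm(evoked_outputs, stimuli_full):
    return rs.pipeline.model_pcm(
        evoked_outputs, stimuli_full.envelopes, source="evoked")


@pytest.fixture(scope="session")
def evoked_power_table(evoked_outputs, stimuli_full):
    return rs.pipeline.model_power_table(evoked_outputs, stimuli_full.fsets)


@pytest.fixture(scope="session")
def oscillator_power_table(oscillator_outputs, stimuli_full):
    return rs.pipeline.model_power_table(
        oscillator_outputs, stimuli_full.fsets)


def isochronous_onsets(period_s, duration_s, sample_rate=512.0):
    """Helper: an isochronous onset train with pattern markers at every
    onset."""
    times = np.arange(0.0, duration_s, period_s)
    idx = np.round(times * sample_rate).astype(int)
    n = int(round(duration_s * sample_rate))
    values = np.zeros(n)
    values[idx] = 1.0
    return rs.OnsetSeries(sample_rate=sample_rate, values=values,
                          onset_times=idx, pattern_onsets=idx)
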