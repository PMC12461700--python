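"""End-to-end runs: stimuli -> models -> analyses -> comparison.

These helpers wire the modules together for the common study layout:
five tempo conditions (grid intervals 150/200/300/400/600 ms), >=90-s
blocks of the duple-meter pattern, an oscillator and an evoked forward
model, and the spectral / phase analyses applied identically to data and
models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import compare, phase, spectral
from .core import OnsetSeries, Envelope
from .evoked import ResponseKernel, convolve_evoked
from .oscillator import WCParams, simulate_oscillator
from .simulate import SimParams, canonical_kernel, simulate_eeg
from .stimulus import (GRID_INTERVALS_MS, RhythmSpec, frequency_set,
                       make_block, make_envelope, synth_woodblock)


@dataclass
class Stimuli:
    """Per-tempo stimulus bundle."""

    specs: dict       # tempo_ms -> RhythmSpec
    onsets: dict      # tempo_ms -> OnsetSeries
    envelopes: dict   # tempo_ms -> Envelope
    fsets: dict       # tempo_ms -> FrequencySet


def build_stimuli(tempos_ms=GRID_INTERVALS_MS, pattern=(1, 0, 1, 1),
                  attack_ms: float = 5.0, decay_ms: float = 50.0,
                  playback_delay_ms: float = 0.0,
                  min_block_s: float | None = None) -> Stimuli:
    """Blocks, envelopes, and frequency tables for each tempo condition."""
    event_env = synth_woodblock(attack_ms, decay_ms)
    specs, onsets, envelopes, fsets = {}, {}, {}, {}
    for tempo in tempos_ms:
        spec = RhythmSpec(tempo, pattern=pattern,
                          playback_delay_ms=playback_delay_ms)
        if min_block_s is not None:
            n_rep = int(np.ceil(min_block_s * 1000.0
                                / spec.repetition_duration_ms))
            spec = RhythmSpec(tempo, pattern=pattern,
                              n_repetitions=n_rep,
                              playback_delay_ms=playback_delay_ms)
        specs[tempo] = spec
        onsets[tempo] = make_block(spec)
        envelopes[tempo] = make_envelope(onsets[tempo], event_env)
        fsets[tempo] = frequency_set(tempo)
    return Stimuli(specs=specs, onsets=onsets, envelopes=envelopes,
                   fsets=fsets)


def run_oscillator(stimuli: Stimuli, params: WCParams | None = None) -> dict:
    """Oscillator-model output per tempo."""
    params = params or WCParams()
    return {t: simulate_oscillator(env, params)
            for t, env in stimuli.envelopes.items()}


def run_evoked(stimuli: Stimuli, kernel: ResponseKernel | dict) -> dict:
    """Evoked-model output per tempo.

    ``kernel`` is a single post-processed kernel or a {tempo_ms: kernel}
    mapping (e.g. from the cross-tempo control).
    """
    out = {}
    for t, onsets in stimuli.onsets.items():
        k = kernel[t] if isinstance(kernel, dict) else kernel
        out[t] = convolve_evoked(onsets, k)
    return out


def model_power_table(models: dict, fsets: dict) -> pd.DataFrame:
    """Tidy (tempo_ms, category, z) table of model spectral power."""
    rows = {t: spectral.model_power(m, fsets[t]) for t, m in models.items()}
    return compare.tidy_power_table(rows)


def model_pcm(models: dict, envelopes: dict,
              source: str = "model") -> phase.PhaseStats:
    """PCM of a forward model across the tempo conditions."""
    return phase.pcm_pipeline(models, envelopes, mode="model", source=source)


def simulate_participant(stimuli: Stimuli, generator: str,
                         kernel: ResponseKernel | None,
                         oscillator_outputs: dict | None,
                         noise_amp: float, seed: int,
                         evoked_jitter_sd: float = 0.1) -> dict:
    """Synthetic EEG blocks for one participant, one per tempo.

    ``generator='evoked'`` builds each block from the response kernel
    (with per-event amplitude jitter); ``generator='oscillator'`` adds
    channel noise to precomputed oscillator outputs.
    """
    eegs = {}
    for i, tempo in enumerate(sorted(stimuli.onsets)):
        onsets = stimuli.onsets[tempo]
        block_seed = seed * 1000 + i
        if generator == "evoked":
            params = SimParams(kernel=kernel, evoked_jitter_sd=evoked_jitter_sd,
                               noise_amp=noise_amp, seed=block_seed)
            eegs[tempo] = simulate_eeg(onsets, params,
                                       condition={"tempo_ms": tempo})
        elif generator == "oscillator":
            base = oscillator_outputs[tempo]
            rng = np.random.default_rng(block_seed)
            from .core import CLUSTER_CHANNELS, EEGRecording
            from .simulate import _pink_noise_multi
            data = np.tile(base.values, (len(CLUSTER_CHANNELS), 1))
            if noise_amp > 0:
                data += noise_amp * _pink_noise_multi(
                    base.n_samples, 1.0, rng, len(CLUSTER_CHANNELS))
            eegs[tempo] = EEGRecording(
                sample_rate=base.sample_rate, channels=CLUSTER_CHANNELS,
                data=data, events=base.pattern_onsets,
                condition={"tempo_ms": tempo, "seed": block_seed},
            )
        else:
            raise ValueError(f"unknown generator: {generator!r}")
    return eegs


def cohort_power_table(stimuli: Stimuli, generator: str, n_participants: int,
                       seed: int, noise_amp: float = 0.5,
                       kernel: ResponseKernel | None = None,
                       oscillator_outputs: dict | None = None,
                       condition: str = "attended") -> pd.DataFrame:
    """Tidy EEG power table for a synthetic cohort.

    Every participant gets one block per tempo generated from the chosen
    model plus pink channel noise; the full EEG frequency-tagging
    pipeline is applied to each block.
    """
    if generator == "evoked" and kernel is None:
        kernel = canonical_kernel()
    if generator == "oscillator" and oscillator_outputs is None:
        oscillator_outputs = run_oscillator(stimuli)
    tables = []
    for p in range(n_participants):
        eegs = simulate_participant(
            stimuli, generator, kernel, oscillator_outputs,
            noise_amp, seed=seed * 10_000 + p,
        )
        rows = {t: spectral.eeg_power(eeg, stimuli.fsets[t])
                for t, eeg in eegs.items()}
        tables.append(compare.tidy_power_table(
            rows, participant=p, condition=condition))
    return pd.concat(tables, ignore_index=True)


def run_study(seed: int = 0, n_participants: int = 6,
              noise_amp: float = 0.5,
              wc_params: WCParams | None = None,
              kernel: ResponseKernel | None = None,
              tempos_ms=GRID_INTERVALS_MS) -> dict:
    """Full synthetic study: stimuli, both models, cohort EEG, comparisons.

    Returns a dict with the stimuli, model outputs, model power tables
    and PCMs, the cohort EEG power table, per-participant MSEs, and PCM
    errors — the inputs of the external inferential statistics.
    """
    stimuli = build_stimuli(tempos_ms)
    kernel = kernel or canonical_kernel()
    osc = run_oscillator(stimuli, wc_params)
    evo = run_evoked(stimuli, kernel)
    osc_table = model_power_table(osc, stimuli.fsets)
    evo_table = model_power_table(evo, stimuli.fsets)
    osc_pcm = model_pcm(osc, stimuli.envelopes, source="oscillator")
    evo_pcm = model_pcm(evo, stimuli.envelopes, source="evoked")
    eeg_table = cohort_power_table(
        stimuli, "evoked", n_participants, seed=seed,
        noise_amp=noise_amp, kernel=kernel,
    )
    mse_osc = compare.power_mse(eeg_table, osc_table)
    mse_evo = compare.power_mse(eeg_table, evo_table)
    participant_pcms = {}
    for p in range(n_participants):
        eegs = simulate_participant(
            stimuli, "evoked", kernel, None, noise_amp,
            seed=seed * 10_000 + p,
        )
        stats = phase.pcm_pipeline(eegs, stimuli.envelopes, mode="eeg",
                                   source="eeg")
        participant_pcms[p] = stats.pcm
    pcm_table = compare.pcm_errors(
        participant_pcms, osc_pcm.pcm, evo_pcm.pcm)
    return {
        "stimuli": stimuli,
        "oscillator_outputs": osc,
        "evoked_outputs": evo,
        "oscillator_power": osc_table,
        "evoked_power": evo_table,
        "oscillator_pcm": osc_pcm,
        "evoked_pcm": evo_pcm,
        "eeg_power": eeg_table,
        "mse_oscillator": mse_osc,
        "mse_evoked": mse_evo,
        "pcm_table": pcm_table,
    }
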