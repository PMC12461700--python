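"""Rhythmic stimulus construction.

The stimulus is a four-position duple-meter pattern — a sound, a silence,
and two sounded grid points — repeated into blocks of at least 90 s, at
grid intervals of 150, 200, 300, 400 and 600 ms. The grid frequency
(1/grid interval) and its first and second subharmonics are the
meter-related frequencies; the meter-related frequencies of the *other*,
non-nested tempo family (200/400 ms vs. 150/300/600 ms) serve as the
meter-unrelated control frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import SAMPLE_RATE, Envelope, OnsetSeries

#: Grid intervals (ms) of the five tempo conditions.
GRID_INTERVALS_MS = (150.0, 200.0, 300.0, 400.0, 600.0)

#: The two mutually non-nested metrical families.
TEMPO_FAMILIES = ((150.0, 300.0, 600.0), (200.0, 400.0))

DEFAULT_PATTERN = (1, 0, 1, 1)
MIN_BLOCK_S = 90.0

#: Relative tolerance for frequency identity / disjointness checks.
FREQ_RTOL = 1e-3


def unrelated_family(grid_interval_ms: float) -> tuple:
    """Grid intervals of the opposite (non-nested) tempo family."""
    for fam, other in zip(TEMPO_FAMILIES, TEMPO_FAMILIES[::-1]):
        if any(math.isclose(grid_interval_ms, g, rel_tol=FREQ_RTOL) for g in fam):
            return other
    raise ValueError(f"unknown grid interval: {grid_interval_ms} ms")


@dataclass
class RhythmSpec:
    """Specification of one rhythmic block.

    Parameters
    ----------
    grid_interval_ms : spacing of the metrical grid in ms.
    pattern : binary occupancy of the four grid positions (three sounds,
        one silence); position 0 is the pattern onset and must be sounded
        so that pattern onsets coincide with sound onsets.
    n_repetitions : pattern repetitions per block; ``None`` derives the
        minimum count yielding a >= 90 s block.
    playback_delay_ms : constant gap appended after each repetition
        (models the small systematic audio-playback delay; default 0).
    """

    grid_interval_ms: float
    pattern: tuple = DEFAULT_PATTERN
    n_repetitions: int | None = None
    playback_delay_ms: float = 0.0

    def __post_init__(self):
        self.pattern = tuple(int(p) for p in self.pattern)
        if self.grid_interval_ms <= 0:
            raise ValueError("grid interval must be positive")
        if len(self.pattern) != 4:
            raise ValueError("pattern must have exactly 4 grid positions")
        if sorted(self.pattern) != [0, 1, 1, 1]:
            raise ValueError("pattern must contain 3 sounds and 1 silence")
        if self.n_repetitions is None:
            self.n_repetitions = math.ceil(
                MIN_BLOCK_S * 1000.0 / self.repetition_duration_ms
            )

    @property
    def pattern_duration_ms(self) -> float:
        return 4 * self.grid_interval_ms

    @property
    def repetition_duration_ms(self) -> float:
        """Pattern duration plus the per-repetition playback delay."""
        return self.pattern_duration_ms + self.playback_delay_ms

    @property
    def grid_hz(self) -> float:
        return 1000.0 / self.grid_interval_ms


@dataclass
class FrequencySet:
    """Frequencies of interest for one tempo condition.

    ``grid_hz`` with its first (grid/2) and second (grid/4) subharmonics
    are meter-related; ``unrelated_hz`` are the pooled meter-related
    frequencies of the opposite tempo family.
    """

    grid_hz: float
    sub1_hz: float
    sub2_hz: float
    unrelated_hz: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not math.isclose(self.sub1_hz, self.grid_hz / 2, rel_tol=FREQ_RTOL):
            raise ValueError("sub1 must equal grid/2")
        if not math.isclose(self.sub2_hz, self.grid_hz / 4, rel_tol=FREQ_RTOL):
            raise ValueError("sub2 must equal grid/4")
        for f in self.unrelated_hz:
            if any(
                math.isclose(f, g, rel_tol=FREQ_RTOL)
                for g in self.meter_related
            ):
                raise ValueError(
                    f"unrelated frequency {f} Hz overlaps a meter-related one"
                )

    @property
    def meter_related(self) -> tuple:
        return (self.grid_hz, self.sub1_hz, self.sub2_hz)

    @property
    def all_frequencies(self) -> tuple:
        return self.meter_related + tuple(self.unrelated_hz)

    @property
    def categories(self) -> dict:
        return {
            "grid": (self.grid_hz,),
            "sub1": (self.sub1_hz,),
            "sub2": (self.sub2_hz,),
            "unrelated": tuple(self.unrelated_hz),
        }


def frequency_set(grid_interval_ms: float,
                  unrelated_source=None) -> FrequencySet:
    """Build the frequency-of-interest table for one tempo.

    ``unrelated_source`` is a list of grid intervals (ms) whose
    meter-related frequencies define the meter-unrelated control set;
    defaults to the opposite tempo family. Sources whose metrical family
    overlaps the target's are rejected.
    """
    grid = 1000.0 / grid_interval_ms
    related = (grid, grid / 2, grid / 4)
    if unrelated_source is None:
        unrelated_source = unrelated_family(grid_interval_ms)

    pool = []
    for g_ms in unrelated_source:
        g = 1000.0 / g_ms
        for f in (g, g / 2, g / 4):
            if any(math.isclose(f, r, rel_tol=FREQ_RTOL) for r in related):
                raise ValueError(
                    f"source {g_ms} ms overlaps the metrical family of "
                    f"{grid_interval_ms} ms"
                )
            if not any(math.isclose(f, u, rel_tol=FREQ_RTOL) for u in pool):
                pool.append(f)
    return FrequencySet(
        grid_hz=grid,
        sub1_hz=grid / 2,
        sub2_hz=grid / 4,
        unrelated_hz=tuple(sorted(pool, reverse=True)),
    )


def make_block(spec: RhythmSpec, sample_rate: float = SAMPLE_RATE) -> OnsetSeries:
    """Render a block of repeated patterns as a binary onset train."""
    rep_ms = spec.repetition_duration_ms
    n_samples = int(round(spec.n_repetitions * rep_ms / 1000.0 * sample_rate))
    sounded = [i for i, p in enumerate(spec.pattern) if p]
    onset_ms = np.array(
        [
            r * rep_ms + i * spec.grid_interval_ms
            for r in range(spec.n_repetitions)
            for i in sounded
        ]
    )
    onset_idx = np.round(onset_ms / 1000.0 * sample_rate).astype(int)
    pattern_ms = np.arange(spec.n_repetitions) * rep_ms
    pattern_idx = np.round(pattern_ms / 1000.0 * sample_rate).astype(int)
    values = np.zeros(n_samples)
    values[onset_idx] = 1.0
    return OnsetSeries(
        sample_rate=sample_rate,
        values=values,
        onset_times=onset_idx,
        pattern_onsets=pattern_idx,
    )


def synth_woodblock(attack_ms: float = 5.0, decay_ms: float = 50.0,
                    sample_rate: float = SAMPLE_RATE) -> Envelope:
    """Synthetic percussive event envelope (linear attack, exponential decay).

    A stand-in for the envelope of a short percussive sound: linear rise
    over ``attack_ms`` to a peak of 1, then exponential decay with time
    constant ``decay_ms``, truncated where the amplitude falls below 1% of
    the peak.
    """
    if attack_ms <= 0 or decay_ms <= 0:
        raise ValueError("attack and decay must be positive")
    dt_ms = 1000.0 / sample_rate
    # decay support: amplitude < 1% of peak => t > decay * ln(100)
    decay_support_ms = decay_ms * math.log(100.0)
    t = np.arange(0.0, attack_ms + decay_support_ms + dt_ms, dt_ms)
    values = np.where(
        t <= attack_ms,
        t / attack_ms,
        np.exp(-(t - attack_ms) / decay_ms),
    )
    values = values[values >= 0.01 - 1e-12]
    values = values / values.max()
    return Envelope(sample_rate=sample_rate, values=values,
                    normalization="peak")


def make_envelope(onsets: OnsetSeries, event_env: Envelope) -> Envelope:
    """Continuous stimulus envelope: onset train convolved with the event
    envelope, peak-normalized."""
    if onsets.sample_rate != event_env.sample_rate:
        raise ValueError("sample-rate mismatch between onsets and event envelope")
    values = np.convolve(onsets.values, event_env.values)[: onsets.n_samples]
    peak = values.max()
    if peak > 0:
        values = values / peak
    return Envelope(
        sample_rate=onsets.sample_rate,
        values=values,
        normalization="peak",
        pattern_onsets=onsets.pattern_onsets,
    )
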