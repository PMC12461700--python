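"""Synthetic EEG and tapping data with the structure the analyses assume.

EEG blocks are generated directly at the 15 fronto-central cluster
channels as

    evoked_gain * (jittered onset train (*) response kernel)
    + osc_amp * cos(2*pi*osc_freq*(t - t_pattern0) + osc_phase)
    + noise_amp * 1/f noise (independent per channel)

i.e. a per-sound evoked component (with multiplicative log-normal
amplitude jitter per event, preserving evoked polarity), an optional
entrained sinusoid phase-locked to pattern onsets, and pink background
noise. Tapping records place taps at a chosen metrical level (grid,
first or second subharmonic period) with additive Gaussian motor noise.

One seeded generator per recording makes every output reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLUSTER_CHANNELS, SAMPLE_RATE, EEGRecording, OnsetSeries
from .evoked import ResponseKernel, half_hann_taper

#: Default three-component kernel: an early positive deflection, a larger
#: negative one, and a late slow positivity, emulating the P1-N1-P2 shape
#: of auditory evoked responses (dominant spectral energy in the delta
#: band, below 4 Hz).
DEFAULT_KERNEL_LATENCIES_MS = (50.0, 130.0, 300.0)
DEFAULT_KERNEL_AMPS = (0.5, -1.0, 0.8)
DEFAULT_KERNEL_WIDTHS_MS = (30.0, 60.0, 120.0)

METRICAL_LEVELS = {"grid": 1, "sub1": 2, "sub2": 4}


@dataclass
class SimParams:
    """Generative parameters of one synthetic EEG recording."""

    kernel: ResponseKernel
    evoked_gain: float = 1.0
    evoked_jitter_sd: float = 0.0  # sd of log amplitude per event
    osc_freq: float | None = None
    osc_amp: float = 0.0
    osc_phase: float = 0.0
    noise_exponent: float = 1.0
    noise_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.osc_freq is not None and self.osc_amp < 0:
            raise ValueError("osc_amp must be >= 0 when osc_freq is set")
        if self.evoked_gain < 0 or self.noise_amp < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass
class TapRecord:
    """Tap onsets (s, first tap at 0) at one tempo and metrical level."""

    tap_times: np.ndarray
    tempo_ms: float
    metrical_level: str
    motor_noise_sd_ms: float = 0.0

    def __post_init__(self):
        self.tap_times = np.sort(np.asarray(self.tap_times, dtype=float))
        if self.tap_times.size:
            self.tap_times = self.tap_times - self.tap_times[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.tap_times,
                             "value": np.ones_like(self.tap_times)})

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)


def canonical_kernel(
    component_latencies_ms=DEFAULT_KERNEL_LATENCIES_MS,
    component_amps=DEFAULT_KERNEL_AMPS,
    component_widths_ms=DEFAULT_KERNEL_WIDTHS_MS,
    lag_range_ms=(0.0, 1000.0),
    sample_rate: float = SAMPLE_RATE,
) -> ResponseKernel:
    """Smooth multi-component ground-truth response kernel.

    A sum of Gaussian bumps at the given latencies, baselined to 0 at lag
    0 and tapered to 0 at the final lag with the falling half-Hann window
    the kernel post-processing uses.
    """
    lats = np.asarray(component_latencies_ms, dtype=float)
    amps = np.asarray(component_amps, dtype=float)
    widths = np.asarray(component_widths_ms, dtype=float)
    lo, hi = lag_range_ms
    if np.any(lats < lo) or np.any(lats > hi):
        raise ValueError("component latency outside the lag range")
    lags_ms = (
        np.arange(int(round(lo / 1000 * sample_rate)),
                  int(round(hi / 1000 * sample_rate)) + 1)
        / sample_rate * 1000.0
    )
    w = np.zeros_like(lags_ms)
    for mu, a, sd in zip(lats, amps, widths, strict=True):
        w += a * np.exp(-((lags_ms - mu) ** 2) / (2 * sd**2))
    w = w - w[0]
    w = w * half_hann_taper(lags_ms)
    return ResponseKernel(
        sample_rate=sample_rate, lags_ms=lags_ms, weights=w,
        channels=None, provenance=("synthetic",),
    )


def pink_noise(n: int, exponent: float, seed) -> np.ndarray:
    """Zero-mean noise with average power ~ 1/f**exponent, unit variance.

    ``seed`` may be an integer or a numpy Generator.
    """
    return _pink_noise_multi(n, exponent, seed, n_series=1)[0]


def _pink_noise_multi(n: int, exponent: float, seed,
                      n_series: int) -> np.ndarray:
    """(n_series, n) independent 1/f noise rows from one generator."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    white = rng.standard_normal((n_series, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_eeg(onsets: OnsetSeries, params: SimParams,
                 channels=CLUSTER_CHANNELS,
                 condition: dict | None = None) -> EEGRecording:
    """Generate a synthetic EEG block at the cluster channels.

    The generative signal (evoked + optional oscillation) is identical on
    all channels; the 1/f noise is drawn independently per channel.
    Identical seeds give bit-identical recordings.
    """
    rng = np.random.default_rng(params.seed)
    n = onsets.n_samples
    fs = onsets.sample_rate
    kernel = params.kernel
    if kernel.weights.ndim != 1:
        raise ValueError("ground-truth kernel must be 1-D")
    train = onsets.values.copy()
    if params.evoked_jitter_sd > 0:
        jitter = np.exp(params.evoked_jitter_sd
                        * rng.standard_normal(onsets.onset_times.size))
        train[onsets.onset_times] = jitter
    signal = params.evoked_gain * np.convolve(train, kernel.weights)[:n]
    if params.osc_freq is not None and params.osc_amp > 0:
        t0 = onsets.pattern_onsets[0] if onsets.pattern_onsets.size else 0
        t = (np.arange(n) - t0) / fs
        signal = signal + params.osc_amp * np.cos(
            2 * np.pi * params.osc_freq * t + params.osc_phase
        )
    data = np.tile(signal, (len(channels), 1))
    if params.noise_amp > 0:
        data += params.noise_amp * _pink_noise_multi(
            n, params.noise_exponent, rng, len(channels))
    cond = dict(condition or {})
    cond.setdefault("seed", params.seed)
    return EEGRecording(
        sample_rate=fs, channels=tuple(channels), data=data,
        events=onsets.pattern_onsets, condition=cond,
    )


def simulate_tapping(tempo_ms: float, metrical_level: str,
                     motor_noise_sd_ms: float = 20.0,
                     duration_s: float = 30.0, seed: int = 0) -> TapRecord:
    """Tapping at a metrical level of the pattern with Gaussian timing noise.

    Taps fall every ``grid``, ``2*grid`` or ``4*grid`` ms (for levels
    'grid', 'sub1', 'sub2') with independent Gaussian jitter of
    ``motor_noise_sd_ms`` per tap, truncated to ``duration_s``.
    """
    if metrical_level not in METRICAL_LEVELS:
        raise ValueError(f"unknown metrical level: {metrical_level!r}")
    if duration_s < 25.0:
        raise ValueError("tapping trials must last at least 25 s")
    rng = np.random.default_rng(seed)
    period_s = tempo_ms * METRICAL_LEVELS[metrical_level] / 1000.0
    n_taps = int(np.floor(duration_s / period_s)) + 1
    times = (np.arange(n_taps) * period_s
             + rng.standard_normal(n_taps) * motor_noise_sd_ms / 1000.0)
    times = np.sort(times)
    times = times[(times >= 0) & (times <= duration_s)]
    return TapRecord(
        tap_times=times, tempo_ms=tempo_ms,
        metrical_level=metrical_level,
        motor_noise_sd_ms=motor_noise_sd_ms,
    )
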