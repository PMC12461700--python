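"""Frequency-tagging pipeline.

Phase-locked spectral power is measured on a fixed 0.042-Hz grid
(24-s FFT length) so tapping, EEG, and model spectra are directly
comparable:

* EEG: cluster-average, cut nonoverlapping 12-s epochs starting at
  pattern onsets, average the epochs, demean, zero-pad to 24 s, FFT;
  then local background subtraction (mean of the bins at offsets -2/+2),
  3-bin neighbor smoothing, and z-scoring over the frequencies of
  interest.
* Tapping: binary 512-Hz tap-onset series from the first tap at t=0,
  padded/truncated to 24 s; FFT -> smoothing -> z-scoring (no background
  subtraction — a binary train has no 1/f background).
* Models: the 2.4–26.4 s window of the block output (exactly the 24-s
  FFT length, skipping block-onset transients); FFT -> smoothing ->
  z-scoring.

z-scores are computed over the pooled frequency-of-interest set (grid,
first and second subharmonic, and the individual meter-unrelated
frequencies); the unrelated z-scores are averaged afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SAMPLE_RATE, as_signal
from .stimulus import FrequencySet

FFT_LEN_S = 24.0
FREQ_RESOLUTION_HZ = 1.0 / FFT_LEN_S  # 0.0417 Hz, printed as 0.042
EPOCH_LEN_S = 12.0
MODEL_WINDOW_S = (2.4, 26.4)
TAP_REFRACTORY_S = 0.050

CATEGORIES = ("unrelated", "sub2", "sub1", "grid")


@dataclass
class PowerSpectrum:
    """Power on the fixed 0.042-Hz frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    freq_resolution: float = FREQ_RESOLUTION_HZ
    source: str = "eeg"

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq": self.freqs, "power": self.power})


def epoch_average(obj, epoch_len_s: float = EPOCH_LEN_S,
                  start_pattern: int = 0) -> np.ndarray:
    """Average nonoverlapping epochs aligned to pattern onsets.

    The signal (cluster-averaged for EEG) is cut into ``epoch_len_s``
    epochs, each starting at a pattern onset: the first at pattern onset
    ``start_pattern``, each next one at the first pattern onset at or
    after the previous epoch's end. Epochs that would cross the end of
    the block are dropped. Returns the phase-locked average epoch.
    """
    signal, sample_rate, pattern_onsets = as_signal(obj)
    if pattern_onsets.size <= start_pattern:
        raise ValueError("not enough pattern onsets in block")
    n_ep = int(round(epoch_len_s * sample_rate))
    epochs = []
    next_allowed = int(pattern_onsets[start_pattern])
    for onset in pattern_onsets[start_pattern:]:
        if onset < next_allowed:
            continue
        if onset + n_ep > signal.size:
            break
        epochs.append(signal[onset:onset + n_ep])
        next_allowed = onset + n_ep
    if not epochs:
        raise ValueError("block shorter than one epoch")
    return np.mean(epochs, axis=0)


def fft_power(signal: np.ndarray, sample_rate: float = SAMPLE_RATE,
              pad_to_s: float = FFT_LEN_S, source: str = "eeg") -> PowerSpectrum:
    """Demean, zero-pad (or truncate) to the fixed FFT length, and return
    squared-magnitude spectral power on the 1/24-Hz grid."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    n_fft = int(round(pad_to_s * sample_rate))
    x = signal - signal.mean()
    if x.size >= n_fft:
        x = x[:n_fft]
    else:
        x = np.concatenate([x, np.zeros(n_fft - x.size)])
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    return PowerSpectrum(freqs=freqs, power=spec,
                         freq_resolution=1.0 / pad_to_s, source=source)


def subtract_noise(spec: PowerSpectrum, offset: int = 2) -> PowerSpectrum:
    """Remove broadband background: subtract from each bin the mean power
    of the bins ``offset`` steps below and above (the surrounding, but not
    directly neighboring, bins). Edge bins use the single available side."""
    p = spec.power
    n = p.size
    if n <= offset:
        raise ValueError("spectrum shorter than the subtraction offset")
    out = np.empty_like(p)
    out[offset:n - offset] = p[offset:n - offset] - 0.5 * (
        p[:n - 2 * offset] + p[2 * offset:]
    )
    out[:offset] = p[:offset] - p[offset:2 * offset]  # only +offset exists
    out[n - offset:] = p[n - offset:] - p[n - 2 * offset:n - offset]
    return PowerSpectrum(freqs=spec.freqs, power=out,
                         freq_resolution=spec.freq_resolution,
                         source=spec.source)


def smooth_neighbors(spec: PowerSpectrum) -> PowerSpectrum:
    """3-bin moving average (each bin averaged with its two immediate
    neighbors; edges use the neighbors that exist)."""
    p = spec.power
    if p.size < 3:
        raise ValueError("need at least 3 frequency bins")
    csum = np.concatenate([[0.0], np.cumsum(p)])
    out = np.empty_like(p)
    out[0] = p[:2].mean()
    out[-1] = p[-2:].mean()
    out[1:-1] = (csum[3:] - csum[:-3]) / 3.0
    return PowerSpectrum(freqs=spec.freqs, power=out,
                         freq_resolution=spec.freq_resolution,
                         source=spec.source)


def _foi_bins(spec: PowerSpectrum, freqs_hz) -> np.ndarray:
    res = spec.freq_resolution
    bins = np.round(np.asarray(freqs_hz) / res).astype(int)
    off_grid = np.abs(np.asarray(freqs_hz) - bins * res) > res / 2 + 1e-12
    if np.any(off_grid):
        raise ValueError("frequency of interest more than half a bin off-grid")
    return bins


def zscore_categories(spec: PowerSpectrum, fset: FrequencySet) -> pd.Series:
    """z-scored power at the four frequency categories.

    Power is pooled over the full frequency-of-interest set (the three
    meter-related frequencies plus each meter-unrelated frequency),
    z-scored (mean 0, sd 1 over the pool), and the unrelated z-scores are
    then averaged into a single value.
    """
    foi = list(fset.meter_related) + list(fset.unrelated_hz)
    bins = _foi_bins(spec, foi)
    p = spec.power[bins]
    sd = p.std()
    if sd == 0:
        raise ValueError("zero variance across frequencies of interest")
    z = (p - p.mean()) / sd
    n_rel = len(fset.meter_related)
    return pd.Series(
        {
            "grid": z[0],
            "sub1": z[1],
            "sub2": z[2],
            "unrelated": z[n_rel:].mean(),
        },
        name="z_power",
    )


def clean_taps(tap_times_s: np.ndarray,
               refractory_s: float = TAP_REFRACTORY_S) -> np.ndarray:
    """Drop taps following another tap within the refractory window
    (likely hardware bounce rather than a real tap)."""
    taps = np.sort(np.asarray(tap_times_s, dtype=float))
    kept = []
    for t in taps:
        if not kept or t - kept[-1] > refractory_s:
            kept.append(t)
    return np.asarray(kept)


def tapping_power(taps, fset: FrequencySet,
                  sample_rate: float = SAMPLE_RATE) -> pd.Series:
    """Tapping spectrum -> z-scored category powers.

    ``taps`` is a TapRecord or an array of tap times in seconds. Cleaned
    tap onsets are coded as 1 in a 512-Hz series starting with the first
    tap at time 0, padded/truncated to 24 s; FFT -> neighbor smoothing ->
    z-scoring (no background subtraction).
    """
    times = np.asarray(getattr(taps, "tap_times", taps), dtype=float)
    times = clean_taps(times)
    if times.size < 2:
        raise ValueError("need at least 2 valid taps")
    times = times - times[0]
    n = int(round(times[-1] * sample_rate)) + 1
    series = np.zeros(n)
    series[np.round(times * sample_rate).astype(int)] = 1.0
    spec = fft_power(series, sample_rate, source="tapping")
    return zscore_categories(smooth_neighbors(spec), fset)


def model_power(model, fset: FrequencySet,
                window_s: tuple = MODEL_WINDOW_S) -> pd.Series:
    """Model-output spectrum -> z-scored category powers.

    Uses the 2.4–26.4 s window of the block (exactly the 24-s FFT length,
    past the block-onset transient); FFT -> smoothing -> z-scoring.
    """
    signal, sample_rate, _ = as_signal(model)
    i0 = int(round(window_s[0] * sample_rate))
    i1 = int(round(window_s[1] * sample_rate))
    if signal.size < i1:
        raise ValueError("block too short for the model analysis window")
    spec = fft_power(signal[i0:i1], sample_rate, source="model")
    return zscore_categories(smooth_neighbors(spec), fset)


def eeg_power(eeg, fset: FrequencySet,
              epoch_len_s: float = EPOCH_LEN_S) -> pd.Series:
    """Full EEG frequency-tagging pipeline -> z-scored category powers.

    Epoch-average (12-s pattern-aligned epochs) -> zero-padded FFT ->
    background subtraction -> neighbor smoothing -> z-scoring.
    """
    avg = epoch_average(eeg, epoch_len_s=epoch_len_s)
    sample_rate = as_signal(eeg)[1]
    spec = fft_power(avg, sample_rate, source="eeg")
    return zscore_categories(smooth_neighbors(subtract_noise(spec)), fset)
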