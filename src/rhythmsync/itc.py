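"""Inter-trial phase coherence from a Morlet-wavelet decomposition.

The full block (cluster-averaged) is decomposed with 7-cycle complex
Morlet wavelets at a fixed list of 19 frequencies between 0.33 and
7.5 Hz. Epochs one pattern long are cut at every pattern onset, and ITC
at each (frequency, time-within-pattern) point is the modulus of the mean
unit-normalized complex coefficient across epochs:

    ITC(f, t) = | (1/n) sum_k F_k(f, t) / |F_k(f, t)| |

which is 0 for random phases and 1 when all epochs share the phase.
Patterns of different tempi are compared on a fixed grid of equally
spaced time points per pattern (default 16).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .core import as_signal
from .stimulus import FrequencySet

#: Wavelet frequencies (Hz) used for the time–frequency analysis.
ITC_FREQS = (0.33, 0.42, 0.52, 0.63, 0.73, 0.83, 1.04, 1.25, 1.46, 1.67,
             2.08, 2.50, 2.92, 3.33, 4.17, 5.00, 5.83, 6.67, 7.50)

#: Relative tolerance of the harmonic / meter-related frequency matching
#: (the listed frequencies are rounded to two decimals).
HARMONIC_RTOL = 0.02


@dataclass
class TFR:
    """Complex Morlet coefficients per (frequency, time) plus a validity
    mask flagging samples whose wavelet support fits inside the block."""

    freqs: np.ndarray
    sample_rate: float
    coefficients: np.ndarray  # (n_freqs, n_samples) complex
    valid: np.ndarray  # (n_freqs, n_samples) bool

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)


@dataclass
class ITCResult:
    """ITC per (frequency, time-within-pattern) across pattern epochs."""

    freqs: np.ndarray
    itc: np.ndarray  # (n_freqs, n_points) in [0, 1]
    n_epochs: np.ndarray  # (n_freqs,) epochs used per frequency

    def to_frame(self) -> pd.DataFrame:
        n_pts = self.itc.shape[1]
        rows = [
            (f, j / n_pts, self.itc[i, j])
            for i, f in enumerate(self.freqs)
            for j in range(n_pts)
        ]
        return pd.DataFrame(rows, columns=["freq", "time_frac", "itc"])


def morlet_tfr(obj, freqs=ITC_FREQS, n_cycles: float = 7.0) -> TFR:
    """Morlet time–frequency decomposition of the (cluster-averaged)
    signal at each listed frequency.

    Edge samples within half a wavelet length of either block boundary
    are flagged invalid. Raises if the block is shorter than one wavelet
    at the lowest frequency.
    """
    signal, sample_rate, _ = as_signal(obj)
    import mne

    freqs = np.asarray(freqs, dtype=float)
    wavelets = mne.time_frequency.morlet(sample_rate, freqs,
                                         n_cycles=n_cycles, zero_mean=True)
    n = signal.size
    coeffs = np.empty((freqs.size, n), dtype=complex)
    valid = np.zeros((freqs.size, n), dtype=bool)
    for i, w in enumerate(wavelets):
        if w.size > n:
            raise ValueError(
                f"block shorter than one wavelet at {freqs[i]} Hz"
            )
        coeffs[i] = scipy.signal.fftconvolve(signal, w, mode="same")
        half = w.size // 2
        valid[i, half:n - half] = True
    return TFR(freqs=freqs, sample_rate=sample_rate,
               coefficients=coeffs, valid=valid)


def compute_itc(tfr: TFR, pattern_onsets, pattern_len_samples: int,
                n_points: int = 16) -> ITCResult:
    """ITC across pattern-aligned epochs of the time–frequency transform.

    Epochs one pattern long are cut at each pattern onset and evaluated
    at ``n_points`` equally spaced within-pattern positions. Epochs whose
    wavelet support crosses a block boundary (invalid samples) are
    excluded at the affected frequencies; zero-magnitude coefficients are
    dropped pointwise.
    """
    onsets = np.asarray(pattern_onsets, dtype=int)
    if onsets.size < 2:
        raise ValueError("need at least 2 pattern epochs")
    rel = np.floor(
        np.arange(n_points) / n_points * pattern_len_samples
    ).astype(int)
    n_samples = tfr.coefficients.shape[1]
    onsets = onsets[onsets + pattern_len_samples <= n_samples]
    itc = np.zeros((tfr.freqs.size, n_points))
    n_epochs = np.zeros(tfr.freqs.size, dtype=int)
    for i in range(tfr.freqs.size):
        ok = onsets[
            tfr.valid[i, onsets] & tfr.valid[i, onsets + pattern_len_samples - 1]
        ]
        if ok.size < 2:
            raise ValueError(
                f"fewer than 2 valid epochs at {tfr.freqs[i]} Hz"
            )
        n_epochs[i] = ok.size
        samples = ok[:, None] + rel[None, :]
        c = tfr.coefficients[i, samples]  # (n_epochs, n_points)
        mag = np.abs(c)
        nonzero = mag > 0
        unit = np.where(nonzero, c / np.where(nonzero, mag, 1.0), 0.0)
        counts = nonzero.sum(axis=0)
        if np.any(counts == 0):
            raise ValueError("all coefficients zero at some epoch point")
        itc[i] = np.abs(unit.sum(axis=0)) / counts
    return ITCResult(freqs=tfr.freqs, itc=itc, n_epochs=n_epochs)


def categorize_frequencies(freqs, grid_hz: float,
                           rtol: float = HARMONIC_RTOL) -> dict:
    """Label each frequency: meter-related ('grid'/'sub1'/'sub2'),
    'harmonic' (integer multiple of the grid frequency, excluded from
    both categories), or 'unrelated'."""
    labels = {}
    related = {"grid": grid_hz, "sub1": grid_hz / 2, "sub2": grid_hz / 4}
    for f in freqs:
        label = "unrelated"
        for name, rf in related.items():
            if abs(f - rf) <= rtol * rf:
                label = name
                break
        else:
            ratio = f / grid_hz
            if ratio > 1 and abs(ratio - round(ratio)) <= rtol * round(ratio):
                label = "harmonic"
        labels[float(f)] = label
    return labels


def zscore_itc(result: ITCResult, fset: FrequencySet) -> pd.Series:
    """Time-averaged ITC -> z-scored category values.

    ITC is averaged over the within-pattern time points, z-scored over
    the frequencies of interest (the meter-related rows plus every
    unrelated row; harmonics of the grid frequency are excluded), and the
    unrelated z-scores are averaged.
    """
    mean_itc = result.itc.mean(axis=1)
    labels = categorize_frequencies(result.freqs, fset.grid_hz)
    order = ["grid", "sub1", "sub2"]
    idx = {name: [] for name in order + ["unrelated"]}
    for i, f in enumerate(result.freqs):
        lab = labels[float(f)]
        if lab in idx:
            idx[lab].append(i)
    for name in order:
        if len(idx[name]) != 1:
            raise ValueError(f"expected exactly one {name} frequency row")
    if not idx["unrelated"]:
        raise ValueError("no meter-unrelated frequency in the list")
    foi = [idx[name][0] for name in order] + idx["unrelated"]
    v = mean_itc[foi]
    sd = v.std()
    if sd == 0:
        raise ValueError("zero variance across frequencies of interest")
    z = (v - v.mean()) / sd
    return pd.Series(
        {
            "grid": z[0],
            "sub1": z[1],
            "sub2": z[2],
            "unrelated": z[3:].mean(),
        },
        name="z_itc",
    )
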