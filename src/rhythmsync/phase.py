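"""Phase concentration metric (PCM).

How stable is the phase lag between a neural (or model) signal and the
stimulus across tempi? Per tempo, the 12-s pattern-aligned average epoch
of the signal and of the stimulus envelope are band-filtered at the grid
frequency with a Gaussian frequency-domain filter (sd = 30% of the
center frequency), the instantaneous phase is read off the analytic
signal at every pattern onset, and the envelope phase is subtracted.
The per-tempo circular mean differences are represented as unit vectors;
the PCM is the length of their average:

    PCM = | (1/T) sum_tempo exp(i * mean_dphi_tempo) |    in [0, 1].

A self-sustaining oscillator keeps a near-constant phase lag across
tempi (PCM near 1); a fixed-latency evoked response produces a lag of
-2*pi*f_grid*L radians that disperses across tempi (low PCM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import as_signal
from .spectral import EPOCH_LEN_S, epoch_average

GAUSSIAN_REL_SD = 0.30
#: Epoch-edge guard, in filter time constants (sigma_t = 1/(2*pi*sigma_f)).
EDGE_GUARD_SIGMAS = 2.0
#: Models are epoched from the third pattern repetition to skip onset
#: transients; EEG epochs start at the first pattern onset.
MODEL_START_PATTERN = 2


@dataclass
class PhaseStats:
    """Per-tempo mean phase differences and the scalar PCM."""

    tempos_ms: tuple
    mean_diffs: np.ndarray  # circular mean signal-minus-envelope phase
    resultants: np.ndarray  # per-tempo resultant lengths (dispersion)
    pcm: float
    source: str = "model"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tempo_ms": self.tempos_ms,
                "mean_angle": self.mean_diffs,
                "resultant": self.resultants,
            }
        )

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "pcm": self.pcm,
            "per_tempo": self.to_frame().to_dict(orient="records"),
        }


def gaussian_bandpass(signal: np.ndarray, sample_rate: float,
                      center_hz: float,
                      rel_sd: float = GAUSSIAN_REL_SD) -> np.ndarray:
    """Complex analytic signal band-limited around ``center_hz``.

    The full spectrum is weighted by a Gaussian centered at +center_hz
    (sd = rel_sd * center_hz), the negative-frequency half is zeroed and
    the positive half doubled, and the result inverse-transformed. The
    angle of the output is the instantaneous phase at the grid frequency.
    """
    signal = np.asarray(signal, dtype=float)
    if center_hz >= sample_rate / 2:
        raise ValueError("center frequency at or above Nyquist")
    n = signal.size
    freqs = np.fft.fftfreq(n, 1.0 / sample_rate)
    sd = rel_sd * center_hz
    weight = np.exp(-((freqs - center_hz) ** 2) / (2 * sd**2))
    analytic_gate = np.zeros(n)
    analytic_gate[freqs > 0] = 2.0
    analytic_gate[freqs == 0] = 1.0
    return np.fft.ifft(np.fft.fft(signal) * weight * analytic_gate)


def phase_at_onsets(analytic: np.ndarray, pattern_onsets) -> np.ndarray:
    """Instantaneous phase (radians) at each pattern-onset sample."""
    onsets = np.asarray(pattern_onsets, dtype=int)
    if onsets.size and (onsets.min() < 0 or onsets.max() >= analytic.size):
        raise ValueError("onset outside the filtered segment")
    return np.angle(analytic[onsets])


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi)


def phase_difference(signal_phases, envelope_phases) -> np.ndarray:
    """Circular difference signal minus envelope, wrapped to (-pi, pi]."""
    sp = np.asarray(signal_phases, dtype=float)
    ep = np.asarray(envelope_phases, dtype=float)
    if sp.shape != ep.shape:
        raise ValueError("phase count mismatch")
    return wrap_phase(sp - ep)


def circular_mean(phases) -> float:
    """Angle of the resultant vector of the given phases."""
    return float(np.angle(np.mean(np.exp(1j * np.asarray(phases)))))


def resultant_length(phases) -> float:
    return float(np.abs(np.mean(np.exp(1j * np.asarray(phases)))))


def compute_pcm(per_tempo_mean_diffs, tempos_ms=None,
                resultants=None, source: str = "model") -> PhaseStats:
    """PCM from per-tempo circular-mean phase differences.

    Each tempo's mean difference becomes a unit vector; the PCM is the
    modulus of the arithmetic mean of those vectors.
    """
    diffs = np.asarray(per_tempo_mean_diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("need mean phase differences for at least 2 tempi")
    pcm = float(np.abs(np.mean(np.exp(1j * diffs))))
    return PhaseStats(
        tempos_ms=tuple(tempos_ms) if tempos_ms is not None
        else tuple(range(diffs.size)),
        mean_diffs=diffs,
        resultants=(np.asarray(resultants, dtype=float)
                    if resultants is not None else np.ones_like(diffs)),
        pcm=pcm,
        source=source,
    )


def _epoch_onsets(n_epoch_samples: int, pattern_len_samples: int,
                  sample_rate: float, center_hz: float,
                  rel_sd: float) -> np.ndarray:
    """Within-epoch pattern-onset samples, with phases too close to the
    epoch edges (within EDGE_GUARD_SIGMAS filter time constants) dropped."""
    onsets = np.arange(0, n_epoch_samples, pattern_len_samples)
    sigma_t = 1.0 / (2 * np.pi * rel_sd * center_hz)
    guard = int(np.ceil(EDGE_GUARD_SIGMAS * sigma_t * sample_rate))
    keep = (onsets >= guard) & (onsets < n_epoch_samples - guard)
    kept = onsets[keep]
    if kept.size == 0:
        raise ValueError("no pattern onsets survive the edge guard")
    return kept


def tempo_phase_diffs(signal_obj, envelope, grid_hz: float,
                      mode: str = "model",
                      epoch_len_s: float = EPOCH_LEN_S,
                      rel_sd: float = GAUSSIAN_REL_SD) -> np.ndarray:
    """Signal-minus-envelope phase differences at pattern onsets for one
    tempo, from matched 12-s average epochs.

    ``mode='model'`` starts epoching at the third pattern repetition (to
    skip the block-onset transient); ``mode='eeg'`` starts at the first.
    The envelope is epoched and filtered identically to the signal.
    """
    if mode not in ("model", "eeg"):
        raise ValueError("mode must be 'model' or 'eeg'")
    start = MODEL_START_PATTERN if mode == "model" else 0
    sig_epoch = epoch_average(signal_obj, epoch_len_s, start_pattern=start)
    env_epoch = epoch_average(envelope, epoch_len_s, start_pattern=start)
    _, sample_rate, pattern_onsets = as_signal(signal_obj)
    pattern_len = int(np.diff(pattern_onsets).min()) if pattern_onsets.size > 1 \
        else sig_epoch.size
    onsets = _epoch_onsets(sig_epoch.size, pattern_len, sample_rate,
                           grid_hz, rel_sd)
    sig_phase = phase_at_onsets(
        gaussian_bandpass(sig_epoch, sample_rate, grid_hz, rel_sd), onsets)
    env_phase = phase_at_onsets(
        gaussian_bandpass(env_epoch, sample_rate, grid_hz, rel_sd), onsets)
    return phase_difference(sig_phase, env_phase)


def pcm_pipeline(signals: dict, envelopes: dict, mode: str = "model",
                 epoch_len_s: float = EPOCH_LEN_S,
                 rel_sd: float = GAUSSIAN_REL_SD,
                 source: str | None = None) -> PhaseStats:
    """Full PCM pipeline over tempo conditions.

    ``signals`` and ``envelopes`` map grid interval (ms) ->
    EEGRecording / ModelOutput and stimulus Envelope. Per tempo: filter
    at the grid frequency, phases at pattern onsets, subtract envelope
    phases, circular mean; then PCM across tempi.
    """
    tempos = sorted(signals)
    missing = [t for t in tempos if t not in envelopes]
    if missing:
        raise ValueError(f"missing envelope for tempo {missing}")
    means, resultants = [], []
    for tempo in tempos:
        diffs = tempo_phase_diffs(
            signals[tempo], envelopes[tempo], 1000.0 / tempo,
            mode=mode, epoch_len_s=epoch_len_s, rel_sd=rel_sd,
        )
        means.append(circular_mean(diffs))
        resultants.append(resultant_length(diffs))
    return compute_pcm(
        means, tempos_ms=tempos, resultants=resultants,
        source=source or mode,
    )
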