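"""Evoked-response model: ridge-regression temporal response functions.

A response kernel (TRF) maps the binary sound-onset train to the EEG
signal through a lagged linear regression with an L2 (ridge) penalty on
the lag weights. The kernel spans lags 0–1000 ms after sound onset. The
evoked model's prediction for a block is the convolution of the onset
impulse train with the (post-processed) kernel.

Post-processing mirrors standard practice for this analysis: average over
the fronto-central cluster (and over conditions / participants when
several kernels are pooled), subtract the lag-0 value as a baseline, and
taper the second half of the kernel (lags >= 500 ms) with the falling
half of a Hann window so the kernel ends at exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.signal

from .core import CLUSTER_CHANNELS, EEGRecording, ModelOutput, OnsetSeries

DEFAULT_LAG_RANGE_MS = (0.0, 1000.0)
DEFAULT_LAMBDA = 1.0

#: The two non-nested tempo families used for the cross-tempo kernel control.
_FAMILIES = ((150.0, 300.0, 600.0), (200.0, 400.0))


@dataclass
class ResponseKernel:
    """Lag-domain response function.

    ``weights`` is (n_channels, n_lags) for a raw fitted kernel or
    (n_lags,) after cluster averaging / post-processing. ``provenance``
    records which sessions (tempo / condition labels) it was trained on.
    """

    sample_rate: float
    lags_ms: np.ndarray
    weights: np.ndarray
    channels: tuple | None = None
    ridge_lambda: float = DEFAULT_LAMBDA
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim == 2 and self.channels is not None:
            if self.weights.shape[0] != len(self.channels):
                raise ValueError("weight rows must match channels")

    @property
    def n_lags(self) -> int:
        return self.lags_ms.size

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            sample_rate=self.sample_rate,
            lags_ms=self.lags_ms,
            weights=self.weights,
            channels=np.array(self.channels or ()),
            ridge_lambda=self.ridge_lambda,
            provenance=np.array(self.provenance, dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ResponseKernel":
        with np.load(path, allow_pickle=True) as f:
            channels = tuple(f["channels"].tolist()) or None
            return cls(
                sample_rate=float(f["sample_rate"]),
                lags_ms=f["lags_ms"],
                weights=f["weights"],
                channels=channels,
                ridge_lambda=float(f["ridge_lambda"]),
                provenance=tuple(f["provenance"].tolist()),
            )


def bandpass_filter(data: np.ndarray, sample_rate: float,
                    low_hz: float = 0.1, high_hz: float = 30.0,
                    order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = scipy.signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=sample_rate,
        output="sos",
    )
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def _lagged_design(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Design matrix X[t, l] = x[t - l] for lags 0..n_lags-1."""
    xp = np.concatenate([np.zeros(n_lags - 1), x])
    # sliding windows give [x[t-L+1], ..., x[t]]; reverse to lag order
    win = np.lib.stride_tricks.sliding_window_view(xp, n_lags)
    return win[:, ::-1]


def _accumulate_normal_eqs(pairs, n_lags, prefilter):
    """Accumulate X'X and X'Y over blocks (with an unpenalized intercept)."""
    n_cols = n_lags + 1
    gram = np.zeros((n_cols, n_cols))
    n_ch = None
    xty = None
    total_onsets = 0
    for onsets, eeg in pairs:
        if onsets.sample_rate != eeg.sample_rate:
            raise ValueError("onsets and EEG must share a sample rate")
        if onsets.onset_times.size == 0:
            raise ValueError("degenerate design: no onsets")
        total_onsets += onsets.onset_times.size
        n = min(onsets.n_samples, eeg.n_samples)
        y = eeg.data[:, :n]
        if prefilter:
            y = bandpass_filter(y, eeg.sample_rate)
        if n_ch is None:
            n_ch = y.shape[0]
            xty = np.zeros((n_cols, n_ch))
        x_lag = _lagged_design(onsets.values[:n], n_lags)
        design = np.column_stack([x_lag, np.ones(n)])
        gram += design.T @ design
        xty += design.T @ y.T
    if total_onsets == 0:
        raise ValueError("degenerate design: no onsets")
    return gram, xty, n_ch


def estimate_trf(onsets, eeg, ridge_lambda: float = DEFAULT_LAMBDA,
                 lag_range_ms: tuple = DEFAULT_LAG_RANGE_MS,
                 prefilter: bool = True,
                 provenance: tuple = ()) -> ResponseKernel:
    """Fit a per-channel response kernel by ridge regression.

    ``onsets`` / ``eeg`` may be single objects or equal-length sequences
    of blocks; blocks are pooled into one set of normal equations. The
    EEG is band-pass filtered 0.1–30 Hz before fitting unless
    ``prefilter=False`` (pass pre-filtered data in that case). An
    intercept is included in the regression (unpenalized) and discarded
    from the kernel.
    """
    if isinstance(onsets, OnsetSeries):
        pairs = [(onsets, eeg)]
    else:
        pairs = list(zip(onsets, eeg, strict=True))
    sample_rate = pairs[0][0].sample_rate
    lo, hi = lag_range_ms
    lags = np.arange(
        int(round(lo / 1000.0 * sample_rate)),
        int(round(hi / 1000.0 * sample_rate)) + 1,
    )
    n_lags = lags.size
    gram, xty, _ = _accumulate_normal_eqs(pairs, n_lags, prefilter)
    penalty = np.eye(n_lags + 1) * ridge_lambda
    penalty[-1, -1] = 0.0  # intercept unpenalized
    coef = scipy.linalg.solve(gram + penalty, xty, assume_a="pos")
    weights = coef[:-1].T  # (n_channels, n_lags)
    return ResponseKernel(
        sample_rate=sample_rate,
        lags_ms=lags / sample_rate * 1000.0,
        weights=weights,
        channels=pairs[0][1].channels,
        ridge_lambda=ridge_lambda,
        provenance=tuple(provenance),
    )


def half_hann_taper(lags_ms: np.ndarray, split_ms: float = 500.0) -> np.ndarray:
    """Falling half-Hann window: 1 up to ``split_ms``, cos^2 taper to 0 at
    the final lag (value 0.5 at the taper midpoint)."""
    end = lags_ms[-1]
    w = np.ones_like(lags_ms)
    tail = lags_ms >= split_ms
    w[tail] = np.cos(np.pi / 2 * (lags_ms[tail] - split_ms) / (end - split_ms)) ** 2
    return w


def postprocess_kernel(kernel, cluster=CLUSTER_CHANNELS) -> ResponseKernel:
    """Average kernel(s) over the fronto-central cluster, baseline to the
    lag-0 value, and taper lags >= 500 ms with a falling half-Hann window.

    ``kernel`` may be a single fitted :class:`ResponseKernel` or a
    sequence (e.g. per participant / attention condition); sequences are
    averaged first.
    """
    kernels = [kernel] if isinstance(kernel, ResponseKernel) else list(kernel)
    averaged = []
    provenance = []
    for k in kernels:
        w = k.weights
        if w.ndim == 2:
            if k.channels is None:
                raise ValueError("per-channel kernel lacks channel labels")
            missing = set(cluster) - set(k.channels)
            if missing:
                raise ValueError(f"missing cluster channels: {sorted(missing)}")
            idx = [k.channels.index(ch) for ch in cluster]
            w = w[idx].mean(axis=0)
        averaged.append(w)
        provenance.extend(k.provenance)
    ref = kernels[0]
    w = np.mean(averaged, axis=0)
    w = w - w[0]
    w = w * half_hann_taper(ref.lags_ms)
    return ResponseKernel(
        sample_rate=ref.sample_rate,
        lags_ms=ref.lags_ms,
        weights=w,
        channels=None,
        ridge_lambda=ref.ridge_lambda,
        provenance=tuple(provenance),
    )


def convolve_evoked(onsets: OnsetSeries, kernel: ResponseKernel) -> ModelOutput:
    """Evoked-model prediction: onset impulse train convolved with the
    kernel, truncated to the block length."""
    if onsets.sample_rate != kernel.sample_rate:
        raise ValueError("sample-rate mismatch between onsets and kernel")
    w = kernel.weights
    if w.ndim != 1:
        raise ValueError("kernel must be post-processed (1-D) before convolution")
    values = np.convolve(onsets.values, w)[: onsets.n_samples]
    return ModelOutput(
        sample_rate=onsets.sample_rate,
        values=values,
        pattern_onsets=onsets.pattern_onsets,
        source="evoked",
    )


def _family_of(tempo_ms: float):
    for fam in _FAMILIES:
        if any(abs(tempo_ms - g) < 1e-6 for g in fam):
            return fam
    raise ValueError(f"unknown tempo: {tempo_ms} ms")


def cross_tempo_kernels(sessions: dict, ridge_lambda: float = DEFAULT_LAMBDA,
                        lag_range_ms: tuple = DEFAULT_LAG_RANGE_MS,
                        prefilter: bool = True,
                        cluster=CLUSTER_CHANNELS) -> dict:
    """Kernels trained only on the opposite tempo family.

    ``sessions`` maps tempo (ms) -> list of (OnsetSeries, EEGRecording)
    blocks. The kernel returned for each tempo is fitted on the blocks of
    the other family only (e.g. the 400-ms kernel is trained on the
    150/300/600-ms blocks), then post-processed. Raises if a family has
    no data.
    """
    per_family = {}
    for fam in _FAMILIES:
        pairs = [p for t, blocks in sessions.items()
                 if _family_of(t) == _family_of(fam[0]) for p in blocks]
        if not pairs:
            raise ValueError(f"no sessions for tempo family {fam}")
        onsets, eegs = zip(*pairs)
        tempos = sorted({t for t in sessions if _family_of(t) == _family_of(fam[0])})
        raw = estimate_trf(
            list(onsets), list(eegs), ridge_lambda=ridge_lambda,
            lag_range_ms=lag_range_ms, prefilter=prefilter,
            provenance=tuple(f"{t:g}ms" for t in tempos),
        )
        per_family[fam] = postprocess_kernel(raw, cluster=cluster)
    out = {}
    for tempo in sessions:
        own = _family_of(tempo)
        other = _FAMILIES[1] if own == _FAMILIES[0] else _FAMILIES[0]
        out[tempo] = per_family[other]
    return out


def cross_validate_lambda(sessions: dict, lambdas,
                          exclude_tempo_ms: float = 150.0,
                          prefilter: bool = True) -> dict:
    """Leave-one-block-out cross-validation of the ridge parameter.

    ``sessions`` maps tempo (ms) -> list of (onsets, eeg) blocks. Blocks
    at ``exclude_tempo_ms`` are excluded from the folds (their intervals
    are shared across the nested family and would favor overfitting).
    Returns {lambda: mean squared prediction error} on held-out blocks,
    using cluster-averaged, post-processed kernels.
    """
    blocks = [p for t, bl in sessions.items()
              if abs(t - exclude_tempo_ms) > 1e-6 for p in bl]
    if len(blocks) < 2:
        raise ValueError("need at least two blocks for cross-validation")
    scores = {}
    for lam in lambdas:
        errs = []
        for i, (on_te, eeg_te) in enumerate(blocks):
            train = [b for j, b in enumerate(blocks) if j != i]
            onsets, eegs = zip(*train)
            k = postprocess_kernel(
                estimate_trf(list(onsets), list(eegs), ridge_lambda=lam,
                             prefilter=prefilter)
            )
            pred = convolve_evoked(on_te, k).values
            y = eeg_te.cluster_average()[: pred.size]
            if prefilter:
                y = bandpass_filter(y, eeg_te.sample_rate)
            errs.append(float(np.mean((y - pred[: y.size]) ** 2)))
        scores[float(lam)] = float(np.mean(errs))
    return scores
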