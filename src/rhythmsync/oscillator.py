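"""Wilson–Cowan oscillator driven by the stimulus envelope.

Two coupled neural populations (excitatory E, inhibitory I) with a
logistic squashing nonlinearity:

    tau' dE/dt = -E + S(rho_E + wEE*E - wIE*I + kappa*u(t))
    tau' dI/dt = -I + S(rho_I + wEI*E - wII*I)

where u(t) is the normalized stimulus envelope injected into the
excitatory population with gain kappa, and S(x) = 1/(1+exp(-x)).

The time constant is expressed in implementation units: tau' =
tau * TAU_UNIT_S seconds. TAU_UNIT_S is a calibration constant fixed so
that the unforced model with the default tau = 6.25 settles on a limit
cycle at ~1.33 Hz, the preferred beat rate. (The default parameterization
wEE = wIE = wEI = 10, wII = 0, rho_E = 2.3, rho_I = -3.2 oscillates at
0.2277 cycles per tau-unit of time.)

Integration is fixed-step classical Runge–Kutta (RK4) at dt = 1/2048 s,
downsampled to the 512 Hz analysis rate: deterministic, convergent, cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SAMPLE_RATE, Envelope, ModelOutput

#: Seconds per tau implementation unit (calibrated, see module docstring).
TAU_UNIT_S = 0.0273283


class NoLimitCycleError(RuntimeError):
    """The unforced model relaxed to a fixed point instead of oscillating."""


@dataclass
class WCParams:
    """Wilson–Cowan parameters.

    kappa : stimulus coupling gain into the excitatory population.
    tau : time constant in implementation units (tau * TAU_UNIT_S seconds).
    w_ee, w_ie : recurrent excitation and inhibition onto E.
    w_ei, w_ii : excitation onto I and recurrent inhibition of I.
    rho_e, rho_i : constant background drives.
    sigmoid_gain, sigmoid_threshold : S(x) = 1/(1+exp(-gain*(x-threshold))).
    dt : integration step in seconds (must divide 1/512 s).
    init : initial (E, I) state.
    """

    kappa: float = 10.0
    tau: float = 6.25
    w_ee: float = 10.0
    w_ie: float = 10.0
    w_ei: float = 10.0
    w_ii: float = 0.0
    rho_e: float = 2.3
    rho_i: float = -3.2
    sigmoid_gain: float = 1.0
    sigmoid_threshold: float = 0.0
    dt: float = 1.0 / 2048.0
    init: tuple = (0.1, 0.1)

    def __post_init__(self):
        if self.dt > 1.0 / SAMPLE_RATE + 1e-15:
            raise ValueError("dt must be <= 1/512 s")
        ratio = (1.0 / SAMPLE_RATE) / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt must divide the 1/512 s output step")

    @property
    def tau_seconds(self) -> float:
        return self.tau * TAU_UNIT_S


def _integrate(u_half: np.ndarray, n_steps: int, p: WCParams) -> np.ndarray:
    """RK4 integration; u_half is the input sampled at dt/2 (2*n_steps+1)."""
    g, th = p.sigmoid_gain, p.sigmoid_threshold
    tau_s = p.tau_seconds
    dt = p.dt
    e, i = float(p.init[0]), float(p.init[1])
    out = np.empty(n_steps + 1)
    out[0] = e
    w_ee, w_ie, w_ei, w_ii = p.w_ee, p.w_ie, p.w_ei, p.w_ii
    rho_e, rho_i, kappa = p.rho_e, p.rho_i, p.kappa
    from math import exp

    def f(e, i, uu):
        xe = g * (rho_e + w_ee * e - w_ie * i + kappa * uu - th)
        xi = g * (rho_i + w_ei * e - w_ii * i - th)
        de = (-e + 1.0 / (1.0 + exp(-xe))) / tau_s
        di = (-i + 1.0 / (1.0 + exp(-xi))) / tau_s
        return de, di

    h2 = dt / 2.0
    h6 = dt / 6.0
    for k in range(n_steps):
        u0 = u_half[2 * k]
        u1 = u_half[2 * k + 1]
        u2 = u_half[2 * k + 2]
        k1e, k1i = f(e, i, u0)
        k2e, k2i = f(e + h2 * k1e, i + h2 * k1i, u1)
        k3e, k3i = f(e + h2 * k2e, i + h2 * k2i, u1)
        k4e, k4i = f(e + dt * k3e, i + dt * k3i, u2)
        e += h6 * (k1e + 2 * k2e + 2 * k3e + k4e)
        i += h6 * (k1i + 2 * k2i + 2 * k3i + k4i)
        out[k + 1] = e
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("Wilson–Cowan integration blew up "
                                 "(non-finite state); reduce dt or gains")
    return out


def simulate_oscillator(envelope: Envelope, params: WCParams | None = None) -> ModelOutput:
    """Integrate the driven Wilson–Cowan model and return excitatory
    activity resampled to 512 Hz.

    The envelope must be peak-normalized (max 1); it is injected into the
    excitatory population scaled by kappa.
    """
    p = params or WCParams()
    if envelope.n_samples and envelope.values.max() > 1.0 + 1e-9:
        raise ValueError("envelope must be normalized to max 1")
    n_out = envelope.n_samples
    step = int(round((1.0 / envelope.sample_rate) / p.dt))
    n_steps = (n_out - 1) * step if n_out else 0
    # input resampled onto the half-step grid the RK4 stages need
    t_env = np.arange(n_out) / envelope.sample_rate
    t_half = np.arange(2 * n_steps + 1) * (p.dt / 2.0)
    u_half = np.interp(t_half, t_env, envelope.values)
    e = _integrate(u_half, n_steps, p)
    values = e[::step]
    onsets = (
        envelope.pattern_onsets
        if envelope.pattern_onsets is not None
        else np.empty(0, dtype=int)
    )
    return ModelOutput(
        sample_rate=envelope.sample_rate,
        values=values,
        pattern_onsets=onsets,
        source="oscillator",
    )


def resting_frequency(params: WCParams | None = None, duration_s: float = 60.0,
                      discard_s: float = 10.0) -> float:
    """Dominant frequency (Hz) of the unforced model's limit cycle.

    Simulates with zero input for ``duration_s``, discards the initial
    transient, and returns the frequency of the largest spectral peak of
    the excitatory activity. Raises :class:`NoLimitCycleError` if the
    state relaxes to a fixed point.
    """
    if duration_s < 30.0:
        raise ValueError("duration must be >= 30 s")
    p = params or WCParams()
    n = int(round(duration_s * SAMPLE_RATE))
    silent = Envelope(sample_rate=SAMPLE_RATE, values=np.zeros(n),
                      pattern_onsets=np.empty(0, dtype=int))
    out = simulate_oscillator(silent, p)
    x = out.values[int(round(discard_s * SAMPLE_RATE)):]
    x = x - x.mean()
    if x.std() < 1e-6:
        raise NoLimitCycleError("no oscillation detected (fixed point)")
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / SAMPLE_RATE)
    return float(freqs[np.argmax(power[1:]) + 1])
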