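# Methods

## Stimuli

The rhythmic pattern occupies four positions of an isochronous grid with
one silent position: the default order is `[1, 0, 1, 1]` with position 0
(the pattern onset) sounded, so that pattern onsets coincide with sound
onsets — a requirement of the phase analysis, which reads phases at
pattern onsets. The pattern order is configurable. Blocks repeat the
pattern until they reach 90 s (e.g. 38 repetitions at the 600-ms grid);
an optional constant per-repetition playback delay models the small gap a
real audio player inserts between repetitions, and analyses always use
the recorded pattern-onset markers rather than nominal arithmetic.

The continuous stimulus envelope convolves the binary onset train with a
synthetic percussive event envelope (linear 5-ms attack, exponential
50-ms decay, truncated at 1% of peak) and renormalizes to a peak of 1.
This envelope stands in for the envelope of a recorded percussion sample;
its attack/decay are exposed as parameters. Grid intervals of 150, 200,
300, 400 and 600 ms form two non-nested families (150/300/600 and
200/400); the meter-related frequencies of one family are the
meter-unrelated controls of the other, deduplicated at a relative
tolerance of 1e-3.

## Oscillator model

The Wilson–Cowan pair uses the logistic sigmoid `S(x) = 1/(1+e^{-x})`,
couplings `w_EE = w_IE = w_EI = 10`, `w_II = 0`, and background drives
`ρ_E = 2.3`, `ρ_I = −3.2` — a standard two-population parameterization
that places the system on a stable limit cycle. The stimulus envelope
enters only the excitatory population, scaled by κ = 10 (a high input
gain suited to transient percussive envelopes).

The time constant is quoted in implementation units, τ = 6.25. Its
physical scale is fixed by a calibration constant, `TAU_UNIT_S =
0.0273283` s per unit, chosen once so that the unforced model with
τ = 6.25 oscillates at 1.33 Hz. The calibration was measured from zero
crossings of a long dimensionless run (the default parameterization
produces 0.2277 cycles per τ-unit of time); because the equations rescale
time exactly with τ, halving τ doubles every frequency, and the printed
resting frequency is the binding constraint rather than any particular
unit convention.

Integration is fixed-step classical Runge–Kutta (RK4) at `dt = 1/2048` s
from the fixed initial state `(E, I) = (0.1, 0.1)`, with the envelope
linearly interpolated onto the half-step grid and the excitatory activity
returned every fourth step (512 Hz). The integrator is deterministic;
halving `dt` changes a 10-s trajectory by less than 1e-3 RMS. Non-finite
states abort with a diagnostic. A fixed point instead of a limit cycle
(e.g. all couplings zero) raises an explicit no-limit-cycle error from
`resting_frequency`. Phase analyses start epochs at the third pattern
repetition, which suppresses sensitivity to the initial transient.

## Evoked model

The response kernel spans lags 0–1000 ms at 512 Hz. `estimate_trf` solves
the lagged ridge regression per channel from the onset impulse train to
the EEG, with an unpenalized intercept that is discarded from the kernel;
the penalty is the identity on lag weights with λ = 1 by default. Blocks
may be pooled (normal equations are accumulated), and
`cross_validate_lambda` re-runs the leave-one-block-out optimization on
synthetic data, excluding the 150-ms blocks whose intervals are shared
across the nested family. The EEG is band-pass filtered 0.1–30 Hz
(zero-phase Butterworth) before fitting unless the caller passes
pre-filtered data.

Post-processing averages kernels over the 15-channel fronto-central
cluster (and over multiple kernels when given several), subtracts the
lag-0 value as baseline, and multiplies lags ≥ 500 ms by the falling half
of a Hann window (1 at 500 ms, 0.5 at 750 ms, 0 at 1000 ms) so
predictions have no jump at the kernel's end. When kernels from several
participants/conditions are combined, averaging happens first, then
baseline and taper. The evoked prediction for a block is the linear
convolution of the onset train with the processed kernel, truncated to
the block length. The cross-tempo control fits each family's kernel only
on the other family's blocks and carries provenance labels.

## Frequency tagging

All spectra live on the 1/24-Hz grid (24-s FFT at 512 Hz; 0.0417 Hz,
printed as 0.042). Frequencies of interest are mapped to the nearest bin
(they are never more than half a bin off; the ±1-bin smoothing absorbs
the residual mismatch, e.g. 1.6667 Hz → bin 40).

* **EEG**: cluster-average; nonoverlapping 12-s epochs, each starting at a
  pattern onset (the next epoch starts at the first onset at or after the
  previous epoch's end; partial epochs at the block end are dropped);
  epochs averaged (phase-locked average); demean; zero-pad to 24 s; FFT;
  background subtraction (each bin minus the mean of the bins ±2 steps
  away — edge bins use the single available side, irrelevant in practice
  since frequencies of interest sit far from the edges); 3-bin neighbor
  smoothing; z-scoring.
* **Tapping**: taps within 50 ms of the preceding tap are discarded as
  hardware bounce; the remainder become a binary 512-Hz series starting
  at the first tap, padded/truncated to 24 s; FFT → smoothing →
  z-scoring. No background subtraction — a binary train has no 1/f
  background.
* **Models**: the 2.4–26.4-s window of the block output (exactly the FFT
  length, past onset transients); FFT → smoothing → z-scoring.

z-scores are computed over the pooled frequency-of-interest set — the
three meter-related frequencies plus each individual meter-unrelated
frequency — giving mean 0 and sd 1 over the pool; the unrelated z-scores
are then averaged into one category value. Pooling individually and
averaging afterwards (rather than averaging powers first) keeps the EEG,
tapping and model tables on an identical footing. A degenerate pool with
zero variance raises.

## Inter-trial phase coherence

The full block is decomposed with 7-cycle complex Morlet wavelets at 19
fixed frequencies between 0.33 and 7.5 Hz. Samples within half a wavelet
of a block boundary are flagged; epochs (one pattern long, cut at every
pattern onset) touching flagged samples are excluded at the affected
frequencies. ITC is the modulus of the mean unit-normalized coefficient
across epochs, evaluated at 16 equally spaced time points per pattern so
different tempi are comparable; zero-magnitude coefficients are dropped
pointwise. For category assignment, a listed frequency is meter-related
if it matches the grid frequency or a subharmonic within 2% (the list is
rounded to two decimals), excluded if it is an integer multiple of the
grid frequency within 2% (e.g. 3.33 Hz under the 600-ms grid), and
meter-unrelated otherwise. Time-averaged ITC is z-scored over this
frequency-of-interest subset, mirroring the FFT procedure.

## Phase concentration

Signals and stimulus envelopes are epoched identically (12-s
pattern-aligned averages; models start at the third pattern repetition,
EEG at the first), then filtered with a frequency-domain Gaussian
centered at the grid frequency with sd = 30% of it (2.5 Hz and 0.75 Hz in
the 400-ms condition). The negative-frequency half is zeroed and the
positive half doubled, so the inverse transform is an analytic signal
whose angle is the instantaneous phase. The filter is applied to the raw
spectrum — there is no demeaning step; the Gaussian's tail determines how
much near-DC content survives. This choice follows the filter's
definition and matters only where the signal has almost no energy at the
grid frequency (the oscillator at the 150-ms grid), where the extracted
phase is dominated by whatever leaks through the filter.

Phases are read at the pattern onsets inside the averaged epoch,
excluding onsets within two filter time constants
(`σ_t = 1/(2π·0.3·f_g)`) of the epoch edges. Envelope phases are
subtracted (wrapped to (−π, π]), averaged per tempo with the circular
mean — arithmetic averaging of angles is ill-defined — and the PCM is the
resultant length of the five per-tempo unit vectors. Per-tempo resultant
lengths are reported alongside as a dispersion diagnostic. Participant
EEG gets one PCM per participant; model PCMs are computed once.

Mixtures of the two model signals do **not** interpolate the PCM
monotonically: each tempo's mixture phase moves along the shorter arc
between the pure models' phases, but the across-tempo resultant of
intermediate configurations can dip below both endpoints. The tests
assert the per-tempo arc property, which is the real mechanism.

## Model comparison

Power-domain fit is the per-participant mean squared error between
z-scored EEG and model power over the 5 tempi × 4 categories (EEG
averaged over attention conditions first); phase-domain fit is the
squared error of each participant's PCM against each model's PCM.
Inferential statistics (mixed models, Bayesian t-tests) are deliberately
not re-implemented; `export_stats_tables` writes tidy CSVs keyed by
participant/tempo/condition/category for external statistics software.

## Synthetic data

The generator produces exactly the structure the analyses assume: a
per-sound evoked component (onset train convolved with a ground-truth
kernel, with multiplicative log-normal amplitude jitter per event —
multiplicative so evoked polarity is preserved), an optional sinusoid
phase-locked to pattern onsets, and 1/f background noise drawn
independently per channel from one seeded generator per recording
(identical seeds give bit-identical data). EEG is generated directly at
the 15 fronto-central cluster channels, since every analysis averages
that cluster; full-scalp topography is out of scope. Tapping places taps
at the grid, first- or second-subharmonic period with independent
Gaussian timing noise (default sd 20 ms, a typical sensorimotor
synchronization jitter).

The default ground-truth kernel is a sum of three Gaussian components —
a small positivity near 50 ms, a larger negativity near 130 ms, and a
slow positivity near 300 ms (widths 30/60/120 ms) — baselined and tapered
like every other kernel. The component widths were chosen so the kernel's
spectral energy is concentrated below 4 Hz, as for real slow auditory
evoked responses; this delta-band dominance is what produces the
subharmonic enhancement at fast tempi, so the generator reproduces the
phenomenon for the mechanistic reason, not by construction of the
spectrum directly.

What passing tests do **not** show: real EEG has non-stationary artifacts,
channel-specific topographies, habituating evoked amplitudes and possibly
genuinely mixed oscillatory/evoked dynamics, none of which the generator
emulates. Parameter-recovery and discrimination results on this synthetic
cohort therefore validate the pipeline's correctness and sensitivity, not
any claim about real recordings.

## Numerical and design choices

* Pipeline closure: EEG simulated noiselessly from the evoked model and
  pushed through the EEG branch reproduces the model branch's z-scored
  power table to within |Δz| < 0.05 and the PCM to < 0.01 — not to
  machine precision, because the EEG branch zero-pads 12-s averages to
  24 s (Dirichlet leakage on off-harmonic bins, largest for the 400-ms
  condition whose 1.6-s pattern does not divide 12 s) while models use a
  true 24-s window.
* Epochs that would cross a block end are dropped, never padded.
* The z-score uses the population sd (ddof 0) over the frequency pool.
* The ITC within-pattern grid uses floor-rounding so the last sample
  stays inside the pattern.
* Test and cohort simulations use scaled problem sizes chosen as the
  smallest that leave the measured effects far from their decision
  thresholds: 36-s blocks and 2 participants per cohort for the 100-cohort
  discrimination check, 30–46-s blocks for kernel recovery and
  cross-validation. Headline quantities (resting frequency, model PCMs,
  model power tables) always use the full ≥ 90-s blocks.

## Known limitations

* The Wilson–Cowan auxiliary constants are a calibrated standard
  parameterization, not measurements; only the resting frequency (and
  the qualitative entrainment behavior) is constrained.
* The woodblock envelope is synthetic; absolute phase lags of the
  oscillator model (and hence the exact PCM value) inherit some
  dependence on its attack/decay parameters.
* Multivariate (spectrogram-feature) TRFs, amplitude modulation of evoked
  responses by inter-onset interval, habituation, and networks of
  oscillators are out of scope, as is statistical inference on the
  exported tables.
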