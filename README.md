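# rhythmsync

Does the brain synchronize to musical rhythm through genuine *entrainment* —
a self-sustaining neural oscillation that locks its phase to the beat — or
does the appearance of synchronization emerge from a passive succession of
*evoked responses* to the individual sounds? `rhythmsync` implements, as a
tested pipeline on synthetic EEG and tapping data, the two competing forward
models and the analyses that adjudicate between them:

* **Stimuli** — a four-position duple-meter rhythmic pattern (a sound, a
  silence, two sounded grid points) repeated into ≥ 90-s blocks at grid
  intervals of 150, 200, 300, 400 and 600 ms. The grid frequency
  `f_g = 1/grid` and its subharmonics `f_g/2`, `f_g/4` are the meter-related
  frequencies; the meter-related frequencies of the non-nested tempo family
  (200/400 ms vs. 150/300/600 ms) serve as within-spectrum controls.
* **Oscillator model** — a Wilson–Cowan excitatory/inhibitory pair

  `τ′ dE/dt = −E + S(ρ_E + w_EE·E − w_IE·I + κ·u(t))`
  `τ′ dI/dt = −I + S(ρ_I + w_EI·E − w_II·I)`

  with logistic `S`, stimulus envelope `u(t)` injected into the excitatory
  population with gain κ = 10 and a time constant (τ = 6.25 implementation
  units) calibrated so the unforced model rests at ≈ 1.33 Hz, the preferred
  beat rate.
* **Evoked model** — a lag-domain response kernel (temporal response
  function, 0–1000 ms) estimated from onset impulses to EEG by ridge
  regression (λ = 1), baselined, half-Hann tapered, and convolved with the
  onset train.
* **Analyses** — frequency tagging (12-s pattern-locked epoch averages,
  24-s zero-padded FFT at 0.042-Hz resolution, ±2-bin background
  subtraction, 3-bin smoothing, z-scores over the frequencies of interest),
  inter-trial phase coherence from a 7-cycle Morlet decomposition
  (`ITC(f,t) = |n⁻¹ Σ_k F_k(f,t)/|F_k(f,t)||`), tapping spectra, and the
  phase concentration metric `PCM = |T⁻¹ Σ_tempo exp(i·Δφ_tempo)|`, the
  resultant length of the per-tempo mean signal-minus-envelope phase
  differences at pattern onsets.

A fixed-latency evoked response produces a phase lag of `−2π·f_g·L` that
disperses across tempi (low PCM); an entrained oscillator keeps a stable
lag (high PCM). A `synthetic_data` generator (evoked kernels with amplitude
jitter, optional pattern-locked oscillations, 1/f noise, noisy tapping)
makes every stage testable without real recordings; a loader hook
(`load_raw_eeg`) accepts preprocessed BDF/EDF/FIF recordings.

## Worked example

```python
import rhythmsync as rs

f_rest = rs.resting_frequency()
print(f"resting frequency: {f_rest:.2f} Hz")

stimuli = rs.pipeline.build_stimuli()           # five tempi, >= 90-s blocks
kernel = rs.canonical_kernel()                  # synthetic P1-N1-P2 kernel
osc = rs.pipeline.run_oscillator(stimuli)
evo = rs.pipeline.run_evoked(stimuli, kernel)

table = rs.pipeline.model_power_table(evo, stimuli.fsets)
print(table.pivot(index="tempo_ms", columns="category", values="z").round(2))

pcm_osc = rs.pipeline.model_pcm(osc, stimuli.envelopes, source="oscillator")
pcm_evo = rs.pipeline.model_pcm(evo, stimuli.envelopes, source="evoked")
print(f"PCM oscillator: {pcm_osc.pcm:.2f}")
print(f"PCM evoked:     {pcm_evo.pcm:.2f}")
```

prints

```
resting frequency: 1.34 Hz
category  grid  sub1  sub2  unrelated
tempo_ms
150.0    -0.10  0.28  2.31      -0.62
200.0     1.28  0.99  1.56      -0.77
300.0     2.27  0.26 -0.16      -0.59
400.0     2.61 -0.02 -0.24      -0.47
600.0     2.44 -0.39 -0.47      -0.39
PCM oscillator: 0.87
PCM evoked:     0.30
```

The z-scored power table shows the evoked model's tempo shift: at the
slowest tempo (600 ms) the grid frequency dominates, while at the fastest
(150 ms) the second subharmonic does — low metrical frequencies emerge from
overlapping evoked responses alone, because the kernel's energy is
concentrated in the delta band. The PCM contrast shows the phase
signature that separates the accounts: the entrained oscillator keeps a far
more stable phase lag across tempi than the fixed-latency evoked chain.

A thin CLI wraps the same pipeline: `rhythmsync run-all --out results/`
runs a full synthetic study, `rhythmsync oscillator`, `rhythmsync trf-fit`
and `rhythmsync trf-predict` expose the individual stages.

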