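# eitproc

A software pipeline for parallel-electrode, multi-frequency **electrical
impedance tomography (EIT)**: from raw amplitude-modulated voltage
recordings to boundary-voltage measurements, quality-control metrics and
conductivity-change images.

## The problem

An EIT instrument injects a sinusoidal current of amplitude *I* and
frequency *f* through a pair of electrodes and records the voltages on all
electrodes in parallel with an EEG-style 24-bit amplifier. A *measurement*
is the demodulated amplitude (modulus) of the carrier on one electrode,
averaged over a chosen number of sine-wave periods; repeating over an
ordered sequence of injection pairs (the *protocol*) yields one *frame* of
`n_pairs × n_electrodes` boundary voltages. Systems built this way store
the continuous modulated signal and do all demodulation in software, which
makes four operating modes possible from one instrument: time-difference
imaging, stimulus-triggered coherent averaging, multi-frequency
(frequency-difference) imaging, and frequency-sweep impedance
characterisation.

`eitproc` implements that whole software layer, plus a sample-level
simulator of the raw recordings, so every stage is testable without
hardware:

| module | role |
| --- | --- |
| `protocol` | injection protocols, per-frequency period rules (32/64/128), frame timing, measurement counting, reciprocal-pair matching |
| `simulator` | synthetic raw recordings: carriers switched across pairs, anti-aliasing gain, white noise, random-walk drift, dispersive loads, stimulus-locked impedance transients; binary+JSON raw container |
| `triggers` | coded trigger-channel events (encode/decode) and segmentation of recordings into per-(frame, frequency, pair) windows |
| `demod` | zero-phase IIR band-pass + Hilbert-transform envelope/phase; low-pass extraction of the simultaneous EEG |
| `frames_qc` | frame assembly, rejection (injection electrodes, low-amplitude channels), noise/SNR/drift/reciprocity-error/frequency-response metrics |
| `triggered` | epoch extraction and coherent averaging with the 3σ significance rule |
| `multifrequency` | per-frequency frame blocks, gain-corrected frequency differences, sweep spectra |
| `reconstruction` | 2D FEM forward model, adjoint Jacobian, zeroth-order Tikhonov inverse with cross-validated λ, noise-based image correction |
| `cli` | `eitproc simulate / process / triggered / spectrum / reconstruct` |

## The methods, briefly

**Demodulation.** Each injection window is band-pass filtered around the
carrier with a forward–backward (zero-phase) Butterworth filter, and the
analytic signal `x + i·H[x]` gives envelope and phase. The measurement is
the mean envelope over the trimmed window. For white noise of per-sample
SD σ averaged over *N* samples, the demodulated amplitude SD is
`σ·√(2/N)`, which is how simulator noise is calibrated to a target
measurement noise.

**QC metrics.** Per retained channel with mean *m* and across-frame SD *s*:
noise `s` (volts), `100·s/m` (%), and `SNR = 20·log₁₀(m/s)` (dB); drift is
the change in channel means between the first and last 100-frame block;
reciprocity error for injections (i,j)/(k,l) with disjoint electrodes is
`100·|V_ab − V_ba| / max(|V_ab|,|V_ba|)`.

**Triggered averaging.** Epochs of the continuously demodulated amplitude
are cut around each stimulus, averaged, and baseline-corrected; a channel
is significant when the peak post-stimulus change exceeds 3× the SD of the
averaged pre-stimulus baseline, and the triggered SNR is `peak|δz|/σ_pre`.

**Reconstruction.** On a 2D triangular mesh, `∇·(σ∇u) = 0` is solved with
point electrodes (linear FEM); the sensitivity of measurement *m* to
element *e* is the adjoint-field integral
`J[m,e] = −∫_e ∇u_drive·∇u_meas dA`. Images solve
`min ‖Jδσ − δv‖² + λ‖δσ‖²` with λ chosen by k-fold cross-validation over
measurement rows, then a noise-based correction converts δσ to z-scores by
propagating the per-measurement noise covariance through the inverse
operator and zeroes elements with |z| < 3.

## Worked example

Simulate the bench characterisation experiment — a 34-pair, 16-electrode
resistor-box-like phantom, 100 μA at 2 kHz, 100 ms per injection, 100
frames — with per-sample noise calibrated to a 0.356 μV demodulated SD,
then run the full pipeline:

```python
from eitproc import phantoms
from eitproc.protocol import FrequencyPlan, TimingPlan
from eitproc.simulator import (AmplifierModel, NoiseModel,
                               simulate_recording, white_sd_for_demodulated_sd)
from eitproc.pipeline import process_recording
from eitproc.frames_qc import noise_metrics

amp = AmplifierModel.biosemi_like()          # 16 kHz fs, 3.2 kHz anti-aliasing
protocol, phantom = phantoms.cardiff_like_phantom(amplifier=amp)
plan = FrequencyPlan.single(2000.0)          # 2 kHz carrier
timing = TimingPlan(0.100)                   # 100 ms per injection
noise = NoiseModel(white_sd_v=white_sd_for_demodulated_sd(0.356e-6, 1280))

recording, events = simulate_recording(
    protocol, phantom, amp, plan, timing, n_frames=100, noise=noise, seed=1)
frames = process_recording(recording, protocol, plan)[2000.0]
print(noise_metrics(frames).summary())
```

prints

```
channels retained : 363
frames            : 100
amplitude         : 2.648 mV +/- 0.237 mV
noise             : 0.355 uV +/- 0.025 uV
noise (%)         : 0.0135 +/- 0.0017
SNR               : 77.4 dB +/- 1.07 dB
```

Of the 544 single-ended measurements, 363 survive rejection of the
injection electrodes and of channels below 250 μV; the recovered noise
matches the calibrated 0.356 μV, i.e. 0.013 % of the 2.66 mV mean, an SNR
of 77.5 dB.

The same flow drives the CLI: write a YAML config and run
`eitproc simulate --config cfg.yaml && eitproc process --config cfg.yaml`;
`eitproc reconstruct` adds a 2D disc-mesh time-difference image and
`eitproc spectrum` a sweep-mode impedance spectrum.

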