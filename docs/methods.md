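# Methods

This note records the models, numerical choices and limitations behind
`eitproc`, in the spirit of a package's own methods documentation. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model

During the injection of pair *p* at frequency *f*, the voltage sampled on
electrode *e* is

```
v_e(t) = I(f) · |Z(p, e)| · d(f) · g(f) · sin(2πf·t) + b_e(t) + w(t)
```

with `I` the injected current, `|Z|` the transfer-impedance magnitude of
the load, `d(f)` an optional dispersion gain, `g(f)` the amplifier's
anti-aliasing magnitude response, `b_e` a slowly drifting channel baseline
and `w` white Gaussian noise. Carrier phase resets to zero at every pair
switch (current sources re-triggered on switching behave this way), and the
zero-phase instant coincides with the PAIR_SWITCH trigger event.

Design choices worth stating:

- **Anti-aliasing as an analytic gain.** The amplifier's low-pass is
  applied as a per-frequency gain on the carrier amplitude, not as a
  sample-domain filter; a sample-domain Butterworth option
  (`apply_antialias_iir`) exists for studies of transient effects. The
  analytic form is exact for a steady-state carrier and is what
  frequency-response correction must undo anyway.
- **Drift as a random walk.** Long-term voltage drift is modelled as a
  per-channel Gaussian random walk on the baseline transfer (SD
  `drift_rate·√Δt` between injection onsets). This is the simplest
  nonstationary model that reproduces the defining phenomenon: whole-record
  SNR degrades while consecutive-block SNR does not.
- **Noise calibration.** Averaging the envelope of carrier-plus-white-noise
  over *N* samples leaves amplitude noise of SD `σ·√(2/N)`: the two noise
  quadratures carry half the power each and only the in-phase part moves
  the amplitude to first order. `white_sd_for_demodulated_sd` inverts this
  to set a target measurement noise; a Monte-Carlo test verifies the
  mapping to 15 % and a scaling test verifies the −1/2 log-log slope.
- **Stimulus phase randomisation.** Stimulus times carry a uniform offset
  in [0, 1/f) relative to carrier zero-phase (drawn from a random stream
  independent of the noise stream, so a `dz_fraction = 0` triggered
  simulation is bit-identical to the untriggered one at the same seed). An
  ablation switch (`randomise_phase=False`) exists purely to demonstrate
  the carrier artefact that phase-locked stimulation leaves in averaged
  epochs.
- **Trigger encoding.** Events are coded 16-bit values (event class in the
  low byte, payload such as pair or frequency index in the high byte) held
  for 4 samples on a dedicated integer status channel, as BioSemi/
  BrainVision-style systems record triggers. The semantics (start/stop,
  pair switch, frequency change, stimulus, out-of-compliance) are fixed;
  the byte layout is this package's own convention.
- **Raw container.** Recordings round-trip through a plain binary int32
  file (data quantised to the amplifier's 24-bit step over its input
  range, e.g. 524 mV/2²⁴ ≈ 31.2 nV for a ±262 mV range) with a JSON
  sidecar and an events TSV. The container is deliberately trivial: the
  scientific content is the quantisation and the event stream, not the
  framing.

## Demodulation

Band-pass: Butterworth of order 5 (configurable), full bandwidth
`min(carrier/2, 1 kHz)` by default, run forward–backward (`sosfiltfilt`)
for zero net phase; stability of the one-pass design is checked at
construction. Envelope and phase come from the analytic signal. A
measurement is the mean envelope over the trimmed window; phase is the
circular mean relative to the zero-phase-at-switch carrier and is reported
but not used in imaging (images use the modulus only).

**Edge handling.** Segmentation trims a settle fraction (default 10 %) at
both ends of every injection window. On short windows a fractional trim
can be shorter than the ringing of a narrow band-pass, which biases the
mean envelope by a few tenths of a percent; `measure_segment` therefore
additionally excludes at least four filter time constants (4/bandwidth
seconds) per side whenever at least eight carrier periods remain. With
this rule the noise-free amplitude error is ≲0.05 % across 5 Hz–2 kHz,
which sets the demodulator's numerical floor quoted in the tests.

**Time resolution.** A 1 kHz demodulation bandwidth resolves amplitude
steps with a 10–90 % rise time on the millisecond scale (asserted at
order-of-magnitude level); no decimation is applied.

## QC metrics

Noise per retained channel is the SD across frames, reported in volts, as
`100·SD/mean` percent and as `20·log₁₀(mean/SD)` dB (capped at a 200 dB
sentinel for zero-SD channels); summaries are mean ± SD over channels.
Rejection (injection electrodes; channels whose across-frame mean falls
below the threshold, 250 μV by default) is computed from the mean across
frames so the channel set is stable over a recording — necessary for drift
and per-block SNR time series. Drift compares first/last 100-frame block
means. Reciprocity error uses the signed difference of single-ended
demodulated amplitudes as the four-terminal voltage and the
larger-magnitude direction as denominator, making the metric symmetric;
this |1−ratio| convention gives 0.990 % for a 1 % gain imbalance. For resistive, in-phase loads the signed difference of moduli
equals the signed four-terminal voltage provided all single-ended values
are positive, which the reciprocal phantom constructions guarantee via a
per-injection positive offset (constant within an injection, so it cancels
in every difference).

## Triggered averaging

Epochs (default −250…+250 ms) are cut from the continuously demodulated
amplitude around each stimulus event; epochs crossing segment boundaries
or lying in out-of-compliance segments are dropped and counted. The
average is baseline-corrected over the 10 ms pre-stimulus window; σ_pre is
the SD of the *averaged* trace in that window — the noise that actually
limits detection after averaging — and significance is `peak|δz| > 3σ_pre`
with the peak searched in 0–50 ms post-stimulus (both windows
configurable). Trials are never re-weighted; no artifact rejection is
applied by default.

## Multi-frequency and sweep modes

Multi-frequency frame sets share a rejection mask (the union over
frequencies) so channel sets match across frequency; frequency differences
divide out the modelled amplifier gain first, leaving only the load's
dispersion. Frequency blocks may nest within frames or frames within
frequency blocks; segmentation replays either ordering from the
FREQ_CHANGE payloads. Sweep mode averages per-electrode amplitudes over
repeated orderings (ascending/descending/random), normalises to the lowest
(or stated) frequency and reports the relative change with its standard
error across electrodes.

The dispersion generator is a single-dispersion magnitude curve
`1 − drop·(1 − 1/(1+(f/f_c)^α))`, normalised to unity at a declared
reference and calibratable to a stated end-to-end drop (e.g. 15 % between
5 and 250 Hz). It emulates the *shape* of soft-tissue spectra in the
sub-10 kHz band, not any particular tissue's parameters.

## Reconstruction

Linear P1 FEM on 2D triangular meshes with point electrodes at boundary
nodes; one node is grounded to remove the constant null space and
electrode voltages are mean-zero referenced. The Jacobian uses the adjoint
identity `J[m,e] = −∫_e ∇u_drive·∇u_meas dA`, verified against
finite-difference perturbation of every element (tolerance 1e−4 of the
Jacobian's scale) and against the sensitivity-sum identity
`J·σ = −V` for homogeneous σ. Reciprocity of the forward model holds to
1e−12 (FEM self-adjointness).

The inverse is zeroth-order Tikhonov via regularised normal equations; λ
comes from k-fold (default 10) cross-validation over measurement rows on a
20-point log grid spanning `[1e−8, 1]·trace(JᵀJ)/n_elements`, ties broken
toward stronger regularisation, fold assignment seeded. Amplitudes are
moduli, so time-difference data are mapped to signed voltage changes with
the forward model's baseline signs before inversion.

**Noise-based correction.** The per-measurement noise SDs (estimated from
the reference-frame scatter) are propagated through the linear inverse
operator `B = (JᵀJ+λI)⁻¹Jᵀ` to give each element's reconstruction-noise
SD; the image becomes a z-score map and elements with |z| < 3 are zeroed.
This z-score definition is this package's own interpretation of
"noise-based correction" (the literature describes the idea, not a
formula); it makes the null behaviour exactly testable — ~0.27 % of
elements exceed |z| = 3 under pure noise.

**Scale.** Everything runs at desk scale: ~200-element discs and 16–32
electrodes, versus millions of tetrahedra and layered head anatomy in
production head-EIT. The algorithmic content (FEM, adjoint Jacobian,
Tikhonov, CV, noise correction) is identical; the complete-electrode
model, 3D geometry and electrode registration are out of scope, so
absolute voltage magnitudes and achievable image resolution do not
transfer to head imaging.

## Constructed fixtures and what passing tests show

`phantoms.py` contains deterministic *constructed* tables, labelled
synthetic: a 34-pair/16-electrode table whose 544 measurements reduce to
exactly 363 above 250 μV at 100 μA with retained amplitudes ~2.66 ± 0.24
mV, and a 31-pair/32-electrode table with 540 of 930 above 1 mV at
160 μA. Amplitudes are *recorded* values (the constructors pre-compensate
the amplifier's anti-aliasing gain at the stated carrier). These mirror
the measurement-count structure and amplitude scale of real bench
characterisations so counting, rejection and SNR behaviour can be tested
end to end; they do not model electrode-skin electrochemistry, mains
interference, amplifier common-mode effects or any physical device's
reciprocity error, so tests passing on them say nothing about those
hardware-dependent quantities. Protocols are random distinct-pair draws at
the right sizes, not the optimised pair selections used experimentally.

## Problem sizes and defaults

The end-to-end phantom check simulates 100 frames of the 34-pair protocol
at 2 kHz/16 kHz sampling (~5.4 M samples, ~45 s of compute); property
suites use ~200-element discs, 16-pair protocols, and trials counts of
15–240. These are the sizes a laptop handles comfortably while leaving the
statistical assertions well-powered; all defaults (250 μV rejection,
10 % settle trim, 5th-order filters, 3σ thresholds, 10-fold CV) are stated
above and configurable at the call sites.

## Known limitations

- Point-electrode 2D FEM only; no complete-electrode model, no 3D meshes.
- Phase is measured but unused downstream; purely resistive analysis.
- The simulator's dispersion acts homogeneously on all channels rather
  than per-tissue-compartment.
- No real-time/streaming demodulation; processing is offline by design.
- Composite (multi-tone) injection waveforms are not generated.
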