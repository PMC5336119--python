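"""Synthetic raw EIT recordings with the statistical structure of real
parallel-electrode acquisitions.

The simulator synthesises, at sample level, the voltages an EEG-style
amplifier would record while a current source injects an amplitude-stable
sinusoidal carrier through successive electrode pairs: per-channel carrier
amplitudes set by a transfer-impedance phantom, anti-aliasing filter gain,
additive white noise, slow random-walk drift on the baseline transfer,
dispersive (frequency-dependent) loads, and stimulus-locked fractional
impedance transients for triggered-averaging experiments. A coded trigger
channel (see :mod:`eitproc.triggers`) carries the ground-truth event stream.

Carrier phase is reset to zero at every pair switch, mirroring controllers
that re-trigger the source on switching, and stimulus times carry a uniform
random offset relative to carrier phase so that carrier artefacts average
out of stimulus-locked epochs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .protocol import FrequencyPlan, InjectionProtocol, TimingPlan
from .triggers import PULSE_WIDTH, Event, EventCode, EventLog, encode_events

__all__ = [
    "AmplifierModel",
    "DispersionModel",
    "NoiseModel",
    "EvokedModel",
    "PhantomModel",
    "RawRecording",
    "gain_filter",
    "simulate_recording",
    "simulate_triggered",
    "white_sd_for_demodulated_sd",
    "write_recording",
    "read_recording",
]

EVENT_GUARD = 2 * PULSE_WIDTH  # samples reserved around boundary events


@dataclass(frozen=True)
class AmplifierModel:
    """EEG-amplifier front end: sampling rate, anti-aliasing gain model,
    input range and quantisation depth."""

    sampling_rate_hz: float
    antialias_type: Literal["first_order", "butterworth", "sinc_power", "none"] = "first_order"
    antialias_cutoff_hz: float = 3.2e3
    antialias_order: int = 1
    input_range_v: float = 0.262  # peak, i.e. +/- input_range_v
    resolution_bits: int = 24

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.antialias_type != "none" and not (
            0 < self.antialias_cutoff_hz < self.sampling_rate_hz / 2
        ):
            raise ValueError("anti-aliasing cutoff must lie below Nyquist")

    @property
    def quantisation_step_v(self) -> float:
        return 2 * self.input_range_v / 2**self.resolution_bits

    @classmethod
    def biosemi_like(cls, cutoff_hz: float = 3.2e3) -> "AmplifierModel":
        return cls(16e3, "first_order", cutoff_hz, 1, 0.262)

    @classmethod
    def actichamp_like(cls, cutoff_hz: float = 7.5e3) -> "AmplifierModel":
        return cls(25e3, "first_order", cutoff_hz, 1, 0.400)


def gain_filter(amplifier: AmplifierModel, f_hz: float | np.ndarray) -> np.ndarray | float:
    """Magnitude response of the amplifier's anti-aliasing filter at ``f_hz``.

    Unity at DC by construction; ``first_order`` is 3 dB down at the cutoff.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    fc = amplifier.antialias_cutoff_hz
    kind = amplifier.antialias_type
    if kind == "none":
        g = np.ones_like(f)
    elif kind == "first_order":
        g = 1.0 / np.sqrt(1.0 + (f / fc) ** 2)
    elif kind == "butterworth":
        g = 1.0 / np.sqrt(1.0 + (f / fc) ** (2 * amplifier.antialias_order))
    elif kind == "sinc_power":
        x = f / (2 * fc)
        g = np.abs(np.sinc(x)) ** amplifier.antialias_order
    else:
        raise ValueError(f"unknown anti-aliasing filter type {kind!r}")
    return float(g) if np.isscalar(f_hz) else g


@dataclass(frozen=True)
class DispersionModel:
    """Frequency-dependent relative magnitude of a dispersive load.

    ``raw(f) = 1 - drop_fraction * (1 - 1 / (1 + (f/corner)^exponent))`` falls
    from 1 at DC towards ``1 - drop_fraction`` well above the corner, a
    single-dispersion (Cole-type magnitude) shape adequate for soft-tissue
    spectra in the sub-10 kHz band. The gain is normalised to 1 at the
    declared reference frequency.
    """

    drop_fraction: float
    corner_hz: float
    exponent: float = 1.0
    reference_hz: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in [0, 1)")
        if self.corner_hz <= 0:
            raise ValueError("corner frequency must be positive")

    def _raw(self, f: np.ndarray) -> np.ndarray:
        x = (np.asarray(f, dtype=float) / self.corner_hz) ** self.exponent
        return 1.0 - self.drop_fraction * (1.0 - 1.0 / (1.0 + x))

    def gain(self, f_hz: float | np.ndarray) -> np.ndarray | float:
        g = self._raw(np.asarray(f_hz, dtype=float)) / self._raw(
            np.asarray(self.reference_hz, dtype=float)
        )
        return float(g) if np.isscalar(f_hz) else g

    @classmethod
    def from_drop_at(
        cls,
        drop_at: float,
        at_hz: float,
        corner_hz: float,
        exponent: float = 1.0,
        reference_hz: float = 0.0,
    ) -> "DispersionModel":
        """Calibrate ``drop_fraction`` so the *normalised* gain has fallen by
        ``drop_at`` (e.g. 0.15 for a 15 % drop) at ``at_hz`` relative to the
        declared reference frequency: ``raw(at)/raw(ref) = 1 - drop_at``."""

        def shape(f: float) -> float:
            x = (f / corner_hz) ** exponent
            return 1.0 - 1.0 / (1.0 + x)

        s_a, s_r = shape(at_hz), shape(reference_hz)
        denom = s_a - s_r * (1.0 - drop_at)
        if denom <= 0:
            raise ValueError("at_hz must exceed the reference for a finite drop")
        drop = drop_at / denom
        if not 0 <= drop < 1:
            raise ValueError("requested drop is not expressible by this model")
        return cls(drop, corner_hz, exponent, reference_hz)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise per sample and a per-channel random walk
    on the baseline transfer voltage (slow drift)."""

    white_sd_v: float = 0.0
    drift_rate_v_per_sqrt_s: float = 0.0

    def __post_init__(self) -> None:
        if self.white_sd_v < 0 or self.drift_rate_v_per_sqrt_s < 0:
            raise ValueError("noise parameters must be non-negative")


def white_sd_for_demodulated_sd(demod_sd_v: float, window_samples: int) -> float:
    """Per-sample white-noise SD giving a target demodulated-amplitude SD.

    Averaging the envelope of carrier-plus-white-noise over N samples leaves
    an in-phase noise component of variance ``2 * sigma^2 / N`` (the two
    quadratures each carry half the noise power, and only the in-phase part
    perturbs the amplitude to first order), so ``sigma = sd * sqrt(N / 2)``.
    """
    if window_samples < 1:
        raise ValueError("window must contain at least one sample")
    return demod_sd_v * np.sqrt(window_samples / 2.0)


@dataclass(frozen=True)
class EvokedModel:
    """Stimulus-locked fractional impedance transient.

    ``dz_fraction`` scales the transfer impedance of the affected electrodes
    by ``1 + dz_fraction * pulse(t - t_stim - latency)`` where the pulse is a
    half-sine of the given duration. Optionally a low-frequency evoked
    potential (damped sine) is added to the raw signal of the same channels,
    so the simultaneous EEG path can be exercised.
    """

    dz_fraction: float
    latency_s: float = 0.01
    duration_s: float = 0.02
    affected_electrodes: tuple[int, ...] = ()  # 1-based; empty = all
    stimulus_rate_hz: float = 2.0
    n_stimuli: int = 60
    ep_amplitude_v: float = 0.0
    ep_frequency_hz: float = 20.0
    # randomise stimulus times relative to carrier phase (ablation switch for
    # demonstrating why phase randomisation matters)
    randomise_phase: bool = True

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not abs(self.dz_fraction) < 1:
            raise ValueError("|dz_fraction| must be < 1")
        if self.stimulus_rate_hz <= 0 or self.n_stimuli < 1:
            raise ValueError("invalid stimulus train")

    def pulse(self, tau: np.ndarray) -> np.ndarray:
        """Unit-amplitude half-sine response at lag ``tau`` from the stimulus."""
        u = (np.asarray(tau) - self.latency_s) / self.duration_s
        out = np.sin(np.pi * np.clip(u, 0.0, 1.0))
        out[(u < 0) | (u > 1)] = 0.0
        return out

    def ep_waveform(self, tau: np.ndarray) -> np.ndarray:
        if self.ep_amplitude_v == 0:
            return np.zeros_like(np.asarray(tau, dtype=float))
        u = (np.asarray(tau) - self.latency_s) / self.duration_s
        env = np.sin(np.pi * np.clip(u, 0.0, 1.0))
        env[(u < 0) | (u > 1)] = 0.0
        return self.ep_amplitude_v * env * np.sin(
            2 * np.pi * self.ep_frequency_hz * (np.asarray(tau) - self.latency_s)
        )


@dataclass(frozen=True)
class PhantomModel:
    """Transfer-impedance table: |Z| in ohms per (injection pair, electrode).

    The recorded carrier amplitude on electrode ``e`` during injection ``p``
    at frequency ``f`` is ``I(f) * |Z[p, e]| * dispersion(f) * amp_gain(f)``.
    A dispersion model, when present, scales every entry by the same
    frequency-dependent factor (homogeneous dispersive load).
    """

    n_electrodes: int
    transfer_ohm: np.ndarray  # (n_pairs, n_electrodes), non-negative
    dispersion: DispersionModel | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.transfer_ohm, dtype=float)
        if t.ndim != 2 or t.shape[1] != self.n_electrodes:
            raise ValueError("transfer table must be (n_pairs, n_electrodes)")
        if np.any(t < 0):
            raise ValueError("transfer magnitudes must be non-negative")
        object.__setattr__(self, "transfer_ohm", t)

    @property
    def n_pairs(self) -> int:
        return self.transfer_ohm.shape[0]

    def transfer(self, pair_index: int, f_hz: float) -> np.ndarray:
        z = self.transfer_ohm[pair_index]
        if self.dispersion is not None:
            z = z * self.dispersion.gain(f_hz)
        return z

    @classmethod
    def from_resistance_matrix(
        cls,
        resistance: np.ndarray,
        protocol: InjectionProtocol,
        dispersion: DispersionModel | None = None,
        offset_margin: float = 0.1,
    ) -> "PhantomModel":
        """Build a reciprocal phantom from a symmetric transfer-resistance
        matrix ``R`` (ohms): electrode potentials per unit current are
        ``R[src] - R[sink]``, shifted per injection by a constant offset so
        all single-ended magnitudes are positive. The offset cancels in any
        electrode-pair difference, so reciprocity of the signed four-terminal
        voltages is preserved exactly.
        """
        R = np.asarray(resistance, dtype=float)
        if R.shape != (protocol.n_electrodes,) * 2:
            raise ValueError("resistance matrix shape must match electrode count")
        if not np.allclose(R, R.T):
            raise ValueError("resistance matrix must be symmetric")
        rows = []
        for src, sink in protocol.pairs:
            v = R[src - 1] - R[sink - 1]
            span = v.max() - v.min()
            rows.append(v - v.min() + offset_margin * (span if span > 0 else 1.0))
        return cls(protocol.n_electrodes, np.array(rows), dispersion)


@dataclass
class RawRecording:
    """Sampled multi-channel voltages plus the coded trigger channel."""

    data: np.ndarray  # (n_samples, n_electrodes), volts
    trigger: np.ndarray  # (n_samples,), int32 status codes
    sampling_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be (n_samples, n_channels)")
        if len(self.trigger) != len(self.data):
            raise ValueError("trigger length must match data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def _check_carrier(fs: float, f: float) -> None:
    if fs < 4 * f:
        raise ValueError(
            f"sampling rate {fs} Hz is below 4x the {f} Hz carrier; demodulation "
            "would be unreliable"
        )
    if fs < 8 * f:
        warnings.warn(
            f"sampling rate {fs} Hz is below 8x the {f} Hz carrier", stacklevel=3
        )


def _layout(
    protocol: InjectionProtocol,
    plan: FrequencyPlan,
    timing: TimingPlan | None,
    n_frames: int,
    fs: float,
    frequency_blocks: str,
    rng: np.random.Generator,
    start_silence_s: float,
):
    """Plan segment spans and boundary events.

    Returns (n_samples_total, events, segments) where each planned segment is
    (start, n_samples, frame, freq_index, pair_index).
    """
    multi = plan.n_frequencies > 1
    durations: dict[int, float] = {}
    for i, f in enumerate(plan.frequencies):
        fallback = None
        if timing is not None and np.isscalar(timing.injection_duration_s):
            fallback = float(timing.injection_duration_s)
        durations[i] = plan.duration_s(f, fallback)
    gap = timing.inter_injection_gap_s if timing is not None else 0.0
    gap_samples = int(round(gap * fs))

    events: list[Event] = []
    planned = []
    cursor = max(int(round(start_silence_s * fs)), EVENT_GUARD)
    events.append(Event(cursor, EventCode.INJ_START))
    cursor += EVENT_GUARD

    if frequency_blocks == "within_frame":
        blocks = [
            (frame, fi)
            for frame in range(n_frames)
            for fi in plan.order_for_frame(rng if plan.ordering == "random" else None)
        ]
    elif frequency_blocks == "between_frames":
        order = plan.order_for_frame(rng if plan.ordering == "random" else None)
        blocks = [(frame, fi) for fi in order for frame in range(n_frames)]
    else:
        raise ValueError("frequency_blocks must be 'within_frame' or 'between_frames'")

    for frame, fi in blocks:
        if multi:
            events.append(Event(cursor, EventCode.FREQ_CHANGE, fi))
            cursor += EVENT_GUARD
        n_seg = int(round(durations[fi] * fs))
        if n_seg < 2 * PULSE_WIDTH:
            raise ValueError("injection duration shorter than trigger pulse spacing")
        for p in range(protocol.n_pairs):
            events.append(Event(cursor, EventCode.PAIR_SWITCH, p))
            planned.append((cursor, n_seg, frame, fi, p))
            cursor += n_seg + gap_samples
    events.append(Event(cursor, EventCode.INJ_STOP))
    cursor += EVENT_GUARD
    return cursor, events, planned


def simulate_recording(
    protocol: InjectionProtocol,
    phantom: PhantomModel,
    amplifier: AmplifierModel,
    frequency_plan: FrequencyPlan | None = None,
    timing: TimingPlan | None = None,
    n_frames: int = 1,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    frequency_blocks: str = "within_frame",
    start_silence_s: float = 0.01,
    _evoked: EvokedModel | None = None,
    _stim_seed_seq: np.random.SeedSequence | None = None,
) -> tuple[RawRecording, EventLog]:
    """Synthesise a raw recording for a full multi-frame acquisition.

    Per-sample channel voltage during each injection is
    ``I(f) * |Z(pair, e)| * dispersion(f) * gain_filter(f) * sin(2*pi*f*t)``
    plus the channel's drift offset and white noise; carrier phase restarts
    at zero on every pair switch. The event log records injection start/stop,
    pair switches and frequency changes at exact sample indices, and is also
    encoded into the recording's trigger channel.
    """
    if phantom.n_pairs != protocol.n_pairs or phantom.n_electrodes != protocol.n_electrodes:
        raise ValueError("phantom dimensions do not match protocol")
    if frequency_plan is None:
        raise ValueError("a frequency plan (possibly single-frequency) is required")
    fs = amplifier.sampling_rate_hz
    for f in frequency_plan.frequencies:
        _check_carrier(fs, f)
    noise = noise or NoiseModel()

    ss = np.random.SeedSequence(seed)
    core_ss, stim_ss = ss.spawn(2)
    rng = np.random.default_rng(core_ss)
    stim_rng = np.random.default_rng(_stim_seed_seq or stim_ss)

    n_total, events, planned = _layout(
        protocol, frequency_plan, timing, n_frames, fs, frequency_blocks, rng,
        start_silence_s,
    )
    data = np.zeros((n_total, protocol.n_electrodes), dtype=np.float32)
    log = EventLog(list(events))

    drift = np.zeros(protocol.n_electrodes)
    last_t = 0.0
    mask_affected = np.ones(protocol.n_electrodes, dtype=bool)
    if _evoked is not None and _evoked.affected_electrodes:
        mask_affected = np.zeros(protocol.n_electrodes, dtype=bool)
        mask_affected[[e - 1 for e in _evoked.affected_electrodes]] = True

    for start, n_seg, frame, fi, p in planned:
        f = frequency_plan.frequencies[fi]
        amp_i = frequency_plan.amplitude_per_frequency.get(f, protocol.current_amplitude_a)
        t0 = start / fs
        if noise.drift_rate_v_per_sqrt_s > 0:
            dt = max(t0 - last_t, 0.0)
            drift = drift + rng.normal(
                0.0, noise.drift_rate_v_per_sqrt_s * np.sqrt(dt), protocol.n_electrodes
            )
        last_t = t0
        amp_e = amp_i * phantom.transfer(p, f) * gain_filter(amplifier, f) + drift
        tau = np.arange(n_seg) / fs  # time since switch; phase resets to 0
        carrier = np.sin(2 * np.pi * f * tau)
        block = carrier[:, None] * amp_e[None, :]
        if _evoked is not None:
            ev = _evoked
            n_fit = int(np.floor((n_seg / fs - 1.0 / ev.stimulus_rate_hz) * ev.stimulus_rate_hz))
            n_stim = min(ev.n_stimuli, max(n_fit, 0))
            t_stim = (1.0 + np.arange(n_stim)) / ev.stimulus_rate_hz
            if ev.randomise_phase:
                t_stim = t_stim + stim_rng.uniform(0.0, 1.0 / f, size=n_stim)
            mod = np.zeros(n_seg)
            ep = np.zeros(n_seg)
            for ts in t_stim:
                mod += ev.pulse(tau - ts)
                ep += ev.ep_waveform(tau - ts)
                log.add(start + int(round(ts * fs)), EventCode.STIM)
            block[:, mask_affected] *= (1.0 + ev.dz_fraction * mod)[:, None]
            block[:, mask_affected] += ep[:, None]
        data[start : start + n_seg] = block

    if noise.white_sd_v > 0:
        data += noise.white_sd_v * rng.standard_normal(data.shape, dtype=np.float32)

    trigger = encode_events(log, n_total)
    rec = RawRecording(
        data,
        trigger,
        fs,
        meta={
            "n_frames": n_frames,
            "frequencies_hz": list(frequency_plan.frequencies),
            "current_amplitude_a": protocol.current_amplitude_a,
            "seed": seed,
        },
    )
    return rec, log


def simulate_triggered(
    protocol: InjectionProtocol,
    phantom: PhantomModel,
    amplifier: AmplifierModel,
    evoked: EvokedModel,
    frequency_plan: FrequencyPlan | None = None,
    timing: TimingPlan | None = None,
    n_frames: int = 1,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    **kwargs,
) -> tuple[RawRecording, EventLog]:
    """Triggered-averaging acquisition: continuous injection with a repeated
    stimulus whose times are randomised relative to carrier phase.

    With ``dz_fraction = 0`` and no evoked potential the sampled voltages are
    bit-identical to :func:`simulate_recording` at the same seed (stimulus
    timing uses an independent random stream), so the stimulus machinery adds
    no signal by construction.
    """
    return simulate_recording(
        protocol,
        phantom,
        amplifier,
        frequency_plan,
        timing,
        n_frames,
        noise,
        seed,
        _evoked=evoked,
        **kwargs,
    )


def apply_antialias_iir(recording: RawRecording, amplifier: AmplifierModel) -> RawRecording:
    """Sample-domain alternative to the analytic per-frequency gain: run a
    Butterworth low-pass of the configured order over the data channels."""
    sos = sps.butter(
        max(amplifier.antialias_order, 1),
        amplifier.antialias_cutoff_hz,
        btype="low",
        fs=recording.sampling_rate_hz,
        output="sos",
    )
    filtered = sps.sosfilt(sos, recording.data, axis=0).astype(recording.data.dtype)
    return RawRecording(filtered, recording.trigger, recording.sampling_rate_hz, dict(recording.meta))


# ---------------------------------------------------------------------------
# Raw container: plain binary int32 samples + JSON sidecar + events TSV.
# Voltages are stored quantised to the amplifier's 24-bit step over its input
# range, so round-trips match real acquisition precision (1 LSB).


def write_recording(
    recording: RawRecording, eventlog: EventLog, path, input_range_v: float | None = None,
    resolution_bits: int = 24,
) -> None:
    path = str(path)
    rng_v = float(input_range_v if input_range_v is not None else recording.meta.get("input_range_v", 0.262))
    q = 2 * rng_v / 2**resolution_bits
    full = 2 ** (resolution_bits - 1)
    codes = np.clip(np.round(recording.data / q), -full, full - 1).astype(np.int32)
    frame = np.concatenate([codes, recording.trigger[:, None].astype(np.int32)], axis=1)
    frame.astype("<i4").tofile(path)
    sidecar = {
        "format": "eitproc-raw-v1",
        "sampling_rate_hz": recording.sampling_rate_hz,
        "n_samples": recording.n_samples,
        "n_electrodes": recording.n_electrodes,
        "input_range_v": rng_v,
        "resolution_bits": resolution_bits,
        "quantisation_step_v": q,
        "meta": {k: v for k, v in recording.meta.items() if _jsonable(v)},
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    eventlog.to_tsv(path + ".events.tsv")


def read_recording(path) -> tuple[RawRecording, EventLog]:
    path = str(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    if sidecar.get("format") != "eitproc-raw-v1":
        raise ValueError(f"{path}: not an eitproc raw container")
    n_s, n_e = sidecar["n_samples"], sidecar["n_electrodes"]
    raw = np.fromfile(path, dtype="<i4")
    if raw.size != n_s * (n_e + 1):
        raise ValueError(f"{path}: size does not match sidecar shape")
    frame = raw.reshape(n_s, n_e + 1)
    data = frame[:, :n_e].astype(np.float64) * sidecar["quantisation_step_v"]
    trigger = frame[:, n_e].astype(np.int32)
    meta = dict(sidecar.get("meta", {}))
    meta["input_range_v"] = sidecar["input_range_v"]
    rec = RawRecording(data, trigger, sidecar["sampling_rate_hz"], meta)
    log = EventLog.from_tsv(path + ".events.tsv")
    return rec, log


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
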