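"""Demodulation of amplitude-modulated carrier voltages.

Boundary voltages are recovered from the raw sampled signal by zero-phase
IIR band-pass filtering around the carrier followed by the Hilbert transform,
which yields the envelope (amplitude) and instantaneous phase of the
modulated signal. The simultaneous low-frequency physiological signal (EEG)
is obtained by zero-phase low-pass filtering of the original, unsegmented
signal. A single *measurement* is the demodulated amplitude (modulus)
averaged over the trimmed injection window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .triggers import Segment

__all__ = [
    "DemodConfig",
    "Measurement",
    "bandpass_zero_phase",
    "hilbert_envelope",
    "extract_eeg",
    "measure_segment",
    "demodulate",
]


@dataclass(frozen=True)
class DemodConfig:
    """Band-pass demodulation parameters.

    The default bandwidth ``min(carrier/2, 1 kHz)`` keeps the band inside
    (0, 2*carrier) for low carriers while capping the noise bandwidth at the
    value used for millisecond-resolution evoked work.
    """

    carrier_hz: float
    bandwidth_hz: float | None = None
    filter_order: int = 5
    eeg_cutoff_hz: float | None = None

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0:
            raise ValueError("carrier must be positive")
        bw = self.bandwidth_hz
        if bw is None:
            bw = min(self.carrier_hz / 2, 1000.0)
            object.__setattr__(self, "bandwidth_hz", bw)
        if not 0 < bw < 2 * self.carrier_hz:
            raise ValueError("bandwidth must be in (0, 2*carrier)")

    def band(self) -> tuple[float, float]:
        return (self.carrier_hz - self.bandwidth_hz / 2, self.carrier_hz + self.bandwidth_hz / 2)

    def sos(self, fs: float) -> np.ndarray:
        lo, hi = self.band()
        if not 0 < lo < hi < fs / 2:
            raise ValueError(
                f"band [{lo}, {hi}] Hz outside (0, Nyquist={fs / 2}) at fs={fs}"
            )
        sos = sps.butter(self.filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        # forward-backward application squares the magnitude response, so
        # stability of the one-pass design is what matters
        z, p, _ = sps.sos2zpk(sos)
        if np.any(np.abs(p) >= 1):
            raise ValueError("unstable band-pass design; reduce order or widen band")
        return sos

    @classmethod
    def for_segment(cls, segment: Segment, **kwargs) -> "DemodConfig":
        return cls(carrier_hz=segment.frequency_hz, **kwargs)


@dataclass(frozen=True)
class Measurement:
    """One demodulated boundary-voltage measurement set for a segment:
    per-electrode amplitude (modulus) and phase."""

    frame_index: int
    pair_index: int
    frequency_hz: float
    amplitude_v: np.ndarray  # (n_electrodes,)
    phase_rad: np.ndarray  # (n_electrodes,)
    valid: bool = True


def bandpass_zero_phase(x: np.ndarray, fs: float, config: DemodConfig) -> np.ndarray:
    """Forward-backward (zero net phase) IIR band-pass centred on the carrier."""
    sos = config.sos(fs)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def hilbert_envelope(filtered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Envelope and unwrapped instantaneous phase via the analytic signal.

    For a narrowband input ``A(t) sin(2 pi f t)`` the envelope is ``A(t)``
    and the phase advances at ``2 pi f`` per second.
    """
    analytic = sps.hilbert(np.asarray(filtered, dtype=float), axis=0)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic), axis=0)
    return amplitude, phase


def extract_eeg(x: np.ndarray, fs: float, eeg_cutoff_hz: float, carrier_hz: float | None = None,
                carrier_bandwidth_hz: float = 0.0, order: int = 5) -> np.ndarray:
    """Zero-phase low-pass of the raw (unsegmented) signal.

    The cutoff must sit below the carrier band so the carrier is rejected
    (>= 60 dB for any separation a practical protocol uses).
    """
    if not 0 < eeg_cutoff_hz < fs / 2:
        raise ValueError("EEG cutoff must be in (0, Nyquist)")
    if carrier_hz is not None and eeg_cutoff_hz >= carrier_hz - carrier_bandwidth_hz / 2:
        raise ValueError("EEG cutoff overlaps the carrier band")
    sos = sps.butter(order, eeg_cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def measure_segment(
    data: np.ndarray,
    fs: float,
    segment: Segment,
    config: DemodConfig | None = None,
    min_periods: int = 8,
) -> Measurement:
    """Demodulate one injection segment into per-electrode measurements.

    The band-pass and Hilbert transform run over the full segment span;
    amplitude is the mean envelope and phase the circular mean of the
    carrier-referenced phase over the trimmed measurement window, so filter
    warm-up at the span edges never enters the average. In addition to the
    segment's own settle trim, at least four filter time constants
    (4 / bandwidth seconds) are excluded at each end — narrow band-passes on
    short segments ring for longer than a fixed fractional trim covers —
    unless that would leave fewer than ``min_periods`` carrier periods, in
    which case the fractional trim alone applies.
    """
    if config is None:
        config = DemodConfig(carrier_hz=segment.frequency_hz)
    m_start, m_stop = segment.measurement_span
    need = int(np.ceil(min_periods * fs / config.carrier_hz))
    if m_stop - m_start < need:
        raise ValueError(
            f"segment window of {m_stop - m_start} samples is shorter than "
            f"{min_periods} carrier periods at {config.carrier_hz} Hz"
        )
    tc = int(np.ceil(4.0 * fs / config.bandwidth_hz))
    lo_abs = max(m_start, segment.start + tc)
    hi_abs = min(m_stop, segment.stop - tc)
    if hi_abs - lo_abs >= need:
        m_start, m_stop = lo_abs, hi_abs
    x = np.asarray(data[segment.start : segment.stop], dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    filt = bandpass_zero_phase(x, fs, config)
    amp, phase = hilbert_envelope(filt)
    lo, hi = m_start - segment.start, m_stop - segment.start
    amplitude = amp[lo:hi].mean(axis=0)
    # phase relative to a carrier that is zero-phase at the segment start
    t = np.arange(segment.n_samples)[lo:hi, None] / fs
    ref = 2 * np.pi * config.carrier_hz * t - np.pi / 2  # sin convention
    dphi = phase[lo:hi] - ref
    phase_mean = np.angle(np.exp(1j * dphi).mean(axis=0))
    return Measurement(
        frame_index=segment.frame_index,
        pair_index=segment.pair_index,
        frequency_hz=segment.frequency_hz,
        amplitude_v=amplitude,
        phase_rad=phase_mean,
        valid=segment.valid,
    )


def demodulate(
    data: np.ndarray, fs: float, config: DemodConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous demodulation of a (samples x channels) array: band-pass
    then Hilbert envelope/phase. Used for triggered-averaging, where the
    amplitude time course within an injection matters, not just its mean."""
    filt = bandpass_zero_phase(data, fs, config)
    return hilbert_envelope(filt)
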