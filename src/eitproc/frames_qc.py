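"""Frame assembly, measurement rejection and quality-control metrics.

Boundary voltages are organised as frames x pairs x electrodes arrays per
carrier frequency. Rejection removes measurements on the injecting
electrodes and channels whose mean amplitude falls below a threshold
(negligible boundary voltages carry no usable signal and would dominate
percentage noise). Noise is reported three ways per retained channel, to
ease comparison across instruments: the standard deviation across frames in
volts, as a percentage of the channel mean, and as SNR in dB
(``20 log10(mean / SD)``). Drift is the change in channel means between the
first and last block of frames. Reciprocity error compares each
four-terminal measurement against its current/voltage-swapped twin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .demod import DemodConfig, measure_segment
from .protocol import InjectionProtocol, reciprocal_pairs
from .simulator import AmplifierModel, RawRecording, gain_filter
from .triggers import Segment

__all__ = [
    "BoundaryVoltageFrameSet",
    "QCReport",
    "assemble_frames",
    "apply_rejection",
    "noise_metrics",
    "drift_metric",
    "snr_per_block",
    "reciprocity_error",
    "frequency_response",
    "compare_to_filter",
    "snr_db",
    "noise_percent",
]

SNR_CAP_DB = 200.0  # sentinel for zero-noise channels


def snr_db(mean_v: float | np.ndarray, sd_v: float | np.ndarray) -> float | np.ndarray:
    """Signal-to-noise ratio in dB, capped at a 200 dB sentinel where SD = 0."""
    mean_v = np.asarray(mean_v, dtype=float)
    sd_v = np.asarray(sd_v, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(sd_v > 0, 20.0 * np.log10(np.where(sd_v > 0, mean_v / sd_v, 1.0)), SNR_CAP_DB)
    out = np.minimum(out, SNR_CAP_DB)
    return float(out) if out.ndim == 0 else out


def noise_percent(mean_v: float | np.ndarray, sd_v: float | np.ndarray) -> float | np.ndarray:
    """Noise as a percentage of the channel mean: ``100 * SD / mean``."""
    out = 100.0 * np.asarray(sd_v, dtype=float) / np.asarray(mean_v, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class BoundaryVoltageFrameSet:
    """Demodulated boundary voltages for one carrier frequency.

    ``amplitudes``/``phases`` have shape (frames, pairs, electrodes); the
    rejection mask is per (pair, electrode) — True means rejected — and is
    uniform across frames so channel sets stay stable over a recording.
    """

    amplitudes: np.ndarray
    phases: np.ndarray
    frequency_hz: float
    rejection_mask: np.ndarray | None = None
    timestamps_s: np.ndarray | None = None
    valid_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        if a.ndim != 3:
            raise ValueError("amplitudes must be (frames, pairs, electrodes)")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        self.amplitudes = a
        self.phases = np.asarray(self.phases, dtype=float)
        if self.rejection_mask is None:
            self.rejection_mask = np.zeros(a.shape[1:], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def n_electrodes(self) -> int:
        return self.amplitudes.shape[2]

    @property
    def n_retained(self) -> int:
        return int((~self.rejection_mask).sum())

    def retained(self, frame_range: slice | None = None) -> np.ndarray:
        """(frames, retained_channels) amplitude matrix."""
        a = self.amplitudes if frame_range is None else self.amplitudes[frame_range]
        return a[:, ~self.rejection_mask]


def assemble_frames(
    recording: RawRecording,
    segments: Sequence[Segment],
    protocol: InjectionProtocol,
    demod_kwargs: dict | None = None,
) -> dict[float, BoundaryVoltageFrameSet]:
    """Demodulate every segment and gather measurements into per-frequency
    frame sets. Returns a dict keyed by carrier frequency."""
    demod_kwargs = demod_kwargs or {}
    by_freq: dict[float, list] = {}
    for seg in segments:
        by_freq.setdefault(seg.frequency_hz, []).append(seg)

    out: dict[float, BoundaryVoltageFrameSet] = {}
    for f, segs in by_freq.items():
        n_frames = max(s.frame_index for s in segs) + 1
        amps = np.full((n_frames, protocol.n_pairs, protocol.n_electrodes), np.nan)
        phases = np.zeros_like(amps)
        times = np.zeros(n_frames)
        valid = np.ones((n_frames, protocol.n_pairs), dtype=bool)
        config = DemodConfig(carrier_hz=f, **demod_kwargs)
        for seg in segs:
            m = measure_segment(recording.data, recording.sampling_rate_hz, seg, config)
            amps[seg.frame_index, seg.pair_index] = m.amplitude_v
            phases[seg.frame_index, seg.pair_index] = m.phase_rad
            valid[seg.frame_index, seg.pair_index] = m.valid
            if seg.pair_index == 0:
                times[seg.frame_index] = seg.start / recording.sampling_rate_hz
        if np.any(np.isnan(amps)):
            raise ValueError(f"missing segments for frequency {f} Hz")
        out[f] = BoundaryVoltageFrameSet(
            amps, phases, f, timestamps_s=times, valid_frames=valid.all(axis=1)
        )
    return out


def apply_rejection(
    frameset: BoundaryVoltageFrameSet,
    min_amplitude_v: float = 250e-6,
    exclude_injection: bool = True,
    protocol: InjectionProtocol | None = None,
) -> BoundaryVoltageFrameSet:
    """Mask injection-electrode measurements and low-amplitude channels.

    The threshold is applied to the mean amplitude across frames (not per
    frame), so the retained channel set is stable over the recording.
    """
    if min_amplitude_v < 0:
        raise ValueError("threshold must be non-negative")
    mask = np.zeros((frameset.n_pairs, frameset.n_electrodes), dtype=bool)
    if exclude_injection:
        if protocol is None:
            raise ValueError("exclude_injection requires the protocol")
        mask |= protocol.injection_mask()
    mean_amp = frameset.amplitudes.mean(axis=0)
    mask |= mean_amp < min_amplitude_v
    return replace(frameset, rejection_mask=mask)


@dataclass
class QCReport:
    """Summary of per-channel noise statistics (mean +/- SD over channels)."""

    n_channels: int
    n_frames: int
    amplitude_mean_v: float
    amplitude_sd_v: float
    noise_sd_v: tuple[float, float]
    noise_pct: tuple[float, float]
    snr_db: tuple[float, float]
    per_channel_mean_v: np.ndarray = field(repr=False, default=None)
    per_channel_sd_v: np.ndarray = field(repr=False, default=None)
    drift_v: tuple[float, float] | None = None
    drift_pct: tuple[float, float] | None = None
    reciprocity_error_pct: float | None = None

    def to_dict(self) -> dict:
        d = {
            "n_channels": self.n_channels,
            "n_frames": self.n_frames,
            "amplitude_mean_v": self.amplitude_mean_v,
            "amplitude_sd_v": self.amplitude_sd_v,
            "noise_sd_v": list(self.noise_sd_v),
            "noise_pct": list(self.noise_pct),
            "snr_db": list(self.snr_db),
        }
        if self.drift_v is not None:
            d["drift_v"] = list(self.drift_v)
            d["drift_pct"] = list(self.drift_pct)
        if self.reciprocity_error_pct is not None:
            d["reciprocity_error_pct"] = self.reciprocity_error_pct
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def summary(self) -> str:
        lines = [
            f"channels retained : {self.n_channels}",
            f"frames            : {self.n_frames}",
            f"amplitude         : {self.amplitude_mean_v * 1e3:.3f} mV "
            f"+/- {self.amplitude_sd_v * 1e3:.3f} mV",
            f"noise             : {self.noise_sd_v[0] * 1e6:.3f} uV "
            f"+/- {self.noise_sd_v[1] * 1e6:.3f} uV",
            f"noise (%)         : {self.noise_pct[0]:.4f} +/- {self.noise_pct[1]:.4f}",
            f"SNR               : {self.snr_db[0]:.1f} dB +/- {self.snr_db[1]:.2f} dB",
        ]
        if self.drift_v is not None:
            lines.append(
                f"drift             : {self.drift_v[0] * 1e6:.2f} uV "
                f"({self.drift_pct[0]:.3f} %)"
            )
        if self.reciprocity_error_pct is not None:
            lines.append(f"reciprocity error : {self.reciprocity_error_pct:.3f} %")
        return "\n".join(lines)


def noise_metrics(
    frameset: BoundaryVoltageFrameSet, frame_range: slice | None = None
) -> QCReport:
    """Per-channel noise over a frame range, summarised over retained channels."""
    a = frameset.retained(frame_range)
    if a.shape[0] < 2:
        raise ValueError("need at least two frames for noise metrics")
    means = a.mean(axis=0)
    sds = a.std(axis=0, ddof=1)
    pct = noise_percent(means, sds)
    snrs = snr_db(means, sds)
    return QCReport(
        n_channels=a.shape[1],
        n_frames=a.shape[0],
        amplitude_mean_v=float(means.mean()),
        amplitude_sd_v=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        noise_sd_v=(float(sds.mean()), float(sds.std(ddof=1)) if len(sds) > 1 else 0.0),
        noise_pct=(float(np.mean(pct)), float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0),
        snr_db=(float(np.mean(snrs)), float(np.std(snrs, ddof=1)) if len(snrs) > 1 else 0.0),
        per_channel_mean_v=means,
        per_channel_sd_v=sds,
    )


def drift_metric(
    frameset: BoundaryVoltageFrameSet, block_frames: int = 100
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-channel |mean(last block) - mean(first block)|, absolute and as a
    percentage of the first-block mean; summarised mean +/- SD over channels.
    """
    a = frameset.retained()
    if a.shape[0] < block_frames:
        raise ValueError(
            f"{a.shape[0]} frames is fewer than one block of {block_frames}"
        )
    first = a[:block_frames].mean(axis=0)
    last = a[-block_frames:].mean(axis=0)
    drift = np.abs(last - first)
    pct = 100.0 * drift / first
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return (
        (float(drift.mean()), sd(drift)),
        (float(pct.mean()), sd(pct)),
    )


def snr_per_block(
    frameset: BoundaryVoltageFrameSet, block_frames: int = 100
) -> np.ndarray:
    """Summary SNR (mean over channels, dB) for each consecutive block of
    frames; drifting baselines depress the whole-record SNR but not these."""
    if block_frames < 2:
        raise ValueError("block size must be at least 2")
    n_blocks = frameset.n_frames // block_frames
    if n_blocks == 0:
        raise ValueError("fewer frames than one block")
    out = np.empty(n_blocks)
    for b in range(n_blocks):
        rep = noise_metrics(frameset, slice(b * block_frames, (b + 1) * block_frames))
        out[b] = rep.snr_db[0]
    return out


def reciprocity_error(
    frameset: BoundaryVoltageFrameSet,
    protocol: InjectionProtocol,
    frame_range: slice | None = None,
) -> float:
    """Mean reciprocity error (%) over all reciprocal matches and frames.

    The four-terminal voltage for a match is the signed difference of the
    demodulated amplitudes on the two measurement electrodes. The error for
    a match is ``100 * |V_ab - V_ba| / max(|V_ab|, |V_ba|)`` — the |1 - ratio|
    convention with the larger magnitude in the denominator, which makes the
    metric symmetric in the two directions.
    """
    matches = reciprocal_pairs(protocol)
    if not matches:
        raise ValueError("protocol contains no reciprocal measurement structure")
    a = frameset.amplitudes if frame_range is None else frameset.amplitudes[frame_range]
    errs = []
    for pa, pb, _ in matches:
        k, l = protocol.pairs[pb]
        i, j = protocol.pairs[pa]
        v_ab = a[:, pa, k - 1] - a[:, pa, l - 1]
        v_ba = a[:, pb, i - 1] - a[:, pb, j - 1]
        denom = np.maximum(np.abs(v_ab), np.abs(v_ba))
        ok = denom > 0
        errs.append(100.0 * np.abs(v_ab - v_ba)[ok] / denom[ok])
    return float(np.concatenate(errs).mean())


def frequency_response(
    framesets: dict[float, BoundaryVoltageFrameSet], reference_hz: float = None
) -> dict[float, float]:
    """Normalised amplitude (%) per frequency relative to the reference
    frequency (default: lowest present), averaged over retained channels."""
    freqs = sorted(framesets)
    if reference_hz is None:
        reference_hz = freqs[0]
    if reference_hz not in framesets:
        raise ValueError(f"reference frequency {reference_hz} Hz not in data")
    ref = framesets[reference_hz]
    ref_mean = ref.retained().mean(axis=0)
    out = {}
    for f in freqs:
        fs_f = framesets[f]
        if fs_f.rejection_mask.shape != ref.rejection_mask.shape or not np.array_equal(
            fs_f.rejection_mask, ref.rejection_mask
        ):
            raise ValueError("framesets must share a common rejection mask")
        mean_f = fs_f.retained().mean(axis=0)
        out[f] = float(np.mean(100.0 * mean_f / ref_mean))
    return out


def compare_to_filter(
    response_pct: dict[float, float],
    amplifier: AmplifierModel,
    reference_hz: float | None = None,
) -> dict[float, float]:
    """Difference (percentage points) between a measured normalised response
    and the amplifier's modelled anti-aliasing gain curve."""
    freqs = sorted(response_pct)
    if reference_hz is None:
        reference_hz = freqs[0]
    g_ref = gain_filter(amplifier, reference_hz)
    return {
        f: response_pct[f] - 100.0 * gain_filter(amplifier, f) / g_ref for f in freqs
    }
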