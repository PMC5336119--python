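"""End-to-end processing chains tying the pipeline stages together.

These are the compositions the command-line interface and the tests run:
decode the trigger channel, segment, demodulate into frame sets, apply
rejection and QC, and reconstruct conductivity changes from time- or
frequency-difference boundary voltages.
"""

from __future__ import annotations

import numpy as np

from .frames_qc import (
    BoundaryVoltageFrameSet,
    apply_rejection,
    assemble_frames,
    noise_metrics,
)
from .protocol import FrequencyPlan, InjectionProtocol
from .reconstruction import ForwardModel, ReconResult, reconstruct
from .simulator import RawRecording
from .triggers import decode_trigger_channel, segment_recording

__all__ = ["process_recording", "process_triggered", "reconstruct_time_difference"]


def process_recording(
    recording: RawRecording,
    protocol: InjectionProtocol,
    frequency_plan: FrequencyPlan | None = None,
    settle_fraction: float = 0.1,
    min_amplitude_v: float = 250e-6,
    exclude_injection: bool = True,
    demod_kwargs: dict | None = None,
) -> dict[float, BoundaryVoltageFrameSet]:
    """Trigger decoding -> segmentation -> demodulation -> rejection.

    Returns per-frequency frame sets with rejection masks applied.
    """
    log = decode_trigger_channel(recording.trigger)
    segments = segment_recording(
        recording.n_samples, log, protocol, frequency_plan, settle_fraction
    )
    framesets = assemble_frames(recording, segments, protocol, demod_kwargs)
    return {
        f: apply_rejection(fs, min_amplitude_v, exclude_injection, protocol)
        for f, fs in framesets.items()
    }


def process_triggered(
    recording: RawRecording,
    protocol: InjectionProtocol,
    frequency_plan: FrequencyPlan,
    bandwidth_hz: float = 1000.0,
    window_s: tuple[float, float] = (-0.25, 0.25),
    baseline_window_s: float = 0.01,
    search_window_s: tuple[float, float] = (0.0, 0.05),
    eeg_cutoff_hz: float | None = None,
    settle_fraction: float = 0.02,
):
    """Triggered-averaging chain: continuous demodulation of each injection
    segment, epoch extraction around stimulus events, coherent averaging.

    Returns ``(trialset, evoked_result)``.
    """
    from .demod import DemodConfig, demodulate, extract_eeg
    from .triggered import coherent_average, epoch_extract
    from .triggers import EventCode

    fs = recording.sampling_rate_hz
    log = decode_trigger_channel(recording.trigger)
    segments = segment_recording(
        recording.n_samples, log, protocol, frequency_plan, settle_fraction
    )
    carrier = frequency_plan.frequencies[0]
    config = DemodConfig(carrier_hz=carrier, bandwidth_hz=bandwidth_hz)

    amp_full = np.full(recording.data.shape, np.nan)
    for seg in segments:
        amp, _ = demodulate(recording.data[seg.start : seg.stop], fs, config)
        amp_full[seg.start : seg.stop] = amp

    eeg_full = None
    if eeg_cutoff_hz is not None:
        eeg_full = extract_eeg(recording.data, fs, eeg_cutoff_hz, carrier, bandwidth_hz)

    stim = log.samples_of(EventCode.STIM)
    trials = epoch_extract(
        amp_full, fs, stim, window_s, eeg=eeg_full, segments=segments,
        baseline_window_s=baseline_window_s,
    )
    return trials, coherent_average(trials, search_window_s)


def reconstruct_time_difference(
    frameset: BoundaryVoltageFrameSet,
    forward_model: ForwardModel,
    reference_frames: slice,
    measurement_frames: slice,
    lambda_grid: np.ndarray | None = None,
    k_folds: int = 10,
    seed: int = 0,
    z_threshold: float = 3.0,
    noise_sd: np.ndarray | None = None,
) -> ReconResult:
    """Reconstruct the conductivity change between two frame ranges.

    Demodulated amplitudes are moduli; for small changes the change in
    modulus equals the signed voltage change times the sign of the baseline
    voltage, which the forward model provides. Rows follow the protocol's
    retained (pair, electrode) measurements. Per-measurement noise SDs
    default to the reference-range scatter scaled for the two averaging
    windows; they feed the noise-based image correction.
    """
    keep = ~frameset.rejection_mask.ravel()
    if not keep.any():
        raise ValueError("all measurements rejected")
    v_model = forward_model.boundary_voltages().ravel()[keep]
    signs = np.where(v_model >= 0, 1.0, -1.0)

    a = frameset.amplitudes.reshape(frameset.n_frames, -1)[:, keep]
    a_ref = a[reference_frames]
    a_meas = a[measurement_frames]
    if len(a_ref) < 1 or len(a_meas) < 1:
        raise ValueError("empty frame range")
    dv = signs * (a_meas.mean(axis=0) - a_ref.mean(axis=0))

    if noise_sd is None:
        if len(a_ref) >= 2:
            ch_sd = a_ref.std(axis=0, ddof=1)
            scale = np.sqrt(1.0 / len(a_ref) + 1.0 / len(a_meas))
            noise_sd = np.maximum(ch_sd * scale, 1e-15)
        # else: leave None — no noise correction possible

    J = forward_model.jacobian()[keep]
    return reconstruct(
        J, dv, noise_sd=noise_sd, lambda_grid=lambda_grid, k_folds=k_folds,
        seed=seed, z_threshold=z_threshold,
    )
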