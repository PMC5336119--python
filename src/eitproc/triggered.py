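"""Coherent averaging of stimulus-locked impedance transients.

During triggered-averaging experiments current is injected continuously
while a stimulus repeats; epochs of the continuously demodulated amplitude
(and of the simultaneously low-passed EEG signal) are cut around each
stimulus and averaged. Averaging N trials shrinks incoherent noise as
1/sqrt(N) while the stimulus-locked impedance change survives, so fractional
changes of ~0.1 % become resolvable at millisecond resolution.

SNR here follows the evoked-response convention: the ratio of the peak
post-stimulus voltage change to the standard deviation of the *averaged*
trace in the pre-stimulus baseline window, with changes above three baseline
standard deviations considered significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .triggers import EventCode, EventLog, Segment

__all__ = ["TrialSet", "EvokedResult", "epoch_extract", "coherent_average", "eeg_average"]

SIGMA_SENTINEL = np.inf  # snr sentinel when the baseline has zero variance


@dataclass
class TrialSet:
    """Stimulus-locked epochs: (trials, channels, time) arrays of demodulated
    amplitude and, optionally, of the low-passed EEG signal."""

    epochs: np.ndarray
    times_s: np.ndarray  # relative to stimulus, one per time sample
    sampling_rate_hz: float
    eeg_epochs: np.ndarray | None = None
    baseline_window_s: float = 0.01
    n_dropped: int = 0

    def __post_init__(self) -> None:
        e = np.asarray(self.epochs, dtype=float)
        if e.ndim != 3:
            raise ValueError("epochs must be (trials, channels, time)")
        if len(self.times_s) != e.shape[2]:
            raise ValueError("times axis does not match epoch length")
        if self.times_s[0] >= 0:
            raise ValueError("epoch window must start before the stimulus")
        self.epochs = e

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def baseline_mask(self) -> np.ndarray:
        """Time samples inside the pre-stimulus baseline window."""
        return (self.times_s >= -self.baseline_window_s) & (self.times_s < 0)


@dataclass
class EvokedResult:
    """Coherently averaged evoked impedance response."""

    dz_v: np.ndarray  # (channels, time) mean change from baseline, volts
    dz_pct: np.ndarray  # same, % of baseline amplitude
    times_s: np.ndarray
    baseline_v: np.ndarray  # (channels,) baseline amplitude
    sigma_pre_v: np.ndarray  # (channels,) SD of averaged trace in baseline
    peak_dz_v: np.ndarray  # (channels,) max |dz| in the search window
    snr_triggered: np.ndarray  # peak |dz| / sigma_pre
    significant: np.ndarray  # peak |dz| > 3 sigma_pre
    n_trials: int = 0


def epoch_extract(
    amplitude: np.ndarray,
    fs: float,
    stim_samples: np.ndarray,
    window_s: tuple[float, float] = (-0.25, 0.25),
    eeg: np.ndarray | None = None,
    segments: list[Segment] | None = None,
    baseline_window_s: float = 0.01,
) -> TrialSet:
    """Cut one epoch per stimulus from continuously demodulated channels.

    ``amplitude`` is (samples, channels). Epochs whose window crosses the
    containing segment's boundaries — or falls in a segment flagged invalid
    (e.g. an out-of-compliance interval) — are dropped and counted.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if amplitude.ndim == 1:
        amplitude = amplitude[:, None]
    pre = int(round(-window_s[0] * fs))
    post = int(round(window_s[1] * fs))
    if pre <= 0 or post <= 0:
        raise ValueError("window must span the stimulus")
    times = np.arange(-pre, post) / fs

    epochs, eeg_epochs = [], []
    dropped = 0
    for s in np.asarray(stim_samples, dtype=int):
        lo, hi = s - pre, s + post
        if lo < 0 or hi > amplitude.shape[0]:
            dropped += 1
            continue
        if segments is not None:
            seg = next((g for g in segments if g.start <= s < g.stop), None)
            if seg is None or not seg.valid or lo < seg.start or hi > seg.stop:
                dropped += 1
                continue
        epochs.append(amplitude[lo:hi].T)
        if eeg is not None:
            eeg_epochs.append(np.asarray(eeg[lo:hi]).T)
    if not epochs:
        raise ValueError("no usable epochs: every stimulus window was dropped")
    return TrialSet(
        np.stack(epochs),
        times,
        fs,
        eeg_epochs=np.stack(eeg_epochs) if eeg_epochs else None,
        baseline_window_s=baseline_window_s,
        n_dropped=dropped,
    )


def epochs_from_eventlog(
    amplitude: np.ndarray, fs: float, eventlog: EventLog, **kwargs
) -> TrialSet:
    return epoch_extract(amplitude, fs, eventlog.samples_of(EventCode.STIM), **kwargs)


def coherent_average(
    trialset: TrialSet, search_window_s: tuple[float, float] = (0.0, 0.05)
) -> EvokedResult:
    """Average trials and assess significance of the evoked change.

    The across-trial mean is baseline-corrected by the mean over the
    pre-stimulus baseline window; sigma_pre is the SD of the *averaged* trace
    in that window (the noise that remains after averaging, which is what
    limits detection). The peak is the largest |dz| inside the post-stimulus
    search window; channels with peak > 3 sigma_pre are significant.
    """
    if trialset.n_trials < 2:
        raise ValueError("need at least two trials to average")
    mean = trialset.epochs.mean(axis=0)  # (channels, time)
    base_mask = trialset.baseline_mask()
    if base_mask.sum() < 2:
        raise ValueError("baseline window contains fewer than two samples")
    baseline = mean[:, base_mask].mean(axis=1)
    dz = mean - baseline[:, None]
    sigma = dz[:, base_mask].std(axis=1, ddof=1)
    search = (trialset.times_s >= search_window_s[0]) & (
        trialset.times_s <= search_window_s[1]
    )
    peak = np.abs(dz[:, search]).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sigma > 0, peak / np.where(sigma > 0, sigma, 1.0), SIGMA_SENTINEL)
    return EvokedResult(
        dz_v=dz,
        dz_pct=100.0 * dz / baseline[:, None],
        times_s=trialset.times_s,
        baseline_v=baseline,
        sigma_pre_v=sigma,
        peak_dz_v=peak,
        snr_triggered=snr,
        significant=peak > 3 * sigma,
        n_trials=trialset.n_trials,
    )


def eeg_average(trialset: TrialSet) -> np.ndarray:
    """Mean evoked potential per channel from the low-passed signal epochs.

    No significance rule is applied: evoked potentials are read directly.
    """
    if trialset.eeg_epochs is None:
        raise ValueError("trial set carries no EEG epochs")
    return np.asarray(trialset.eeg_epochs, dtype=float).mean(axis=0)
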