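"""Multi-frequency frame handling and sweep-mode spectrum characterisation.

In multi-frequency operation the whole injection protocol is repeated per
carrier frequency; because the amplifier's anti-aliasing gain varies with
frequency it must be divided out before amplitudes at different frequencies
are compared, after which any residual frequency dependence reflects the
load's dispersion. Sweep mode steps a single injection pair through a dense
frequency list (ascending, descending and randomised orderings) and reports
the relative impedance change versus frequency, electrode-averaged, the way
an impedance analyser would.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np

from .frames_qc import BoundaryVoltageFrameSet
from .simulator import AmplifierModel, gain_filter

__all__ = ["SpectrumResult", "assemble_mf", "frequency_difference", "sweep_spectrum"]


def assemble_mf(
    framesets: dict[float, BoundaryVoltageFrameSet]
) -> dict[float, BoundaryVoltageFrameSet]:
    """Unify rejection across frequencies: the mask becomes the union of the
    per-frequency masks, so the retained channel set is identical at every
    frequency (required for frequency differencing)."""
    if not framesets:
        raise ValueError("no framesets supplied")
    shapes = {fs.rejection_mask.shape for fs in framesets.values()}
    if len(shapes) != 1:
        raise ValueError("framesets use inconsistent protocols")
    union = np.zeros(shapes.pop(), dtype=bool)
    for fs in framesets.values():
        union |= fs.rejection_mask
    out = {}
    for f, fs in framesets.items():
        from dataclasses import replace

        out[f] = replace(fs, rejection_mask=union.copy())
    return out


def frequency_difference(
    framesets: dict[float, BoundaryVoltageFrameSet],
    reference_hz: float,
    amplifier: AmplifierModel | None = None,
) -> dict[float, np.ndarray]:
    """Per-channel voltage difference ``A(f) - A(f_ref)`` for imaging.

    When an amplifier model is given, each frequency's amplitudes are first
    divided by the modelled anti-aliasing gain so the difference reflects
    the load's dispersion, not the instrument's frequency response.
    Returns per-frequency (pairs, electrodes) arrays of frame-mean
    differences with rejected channels set to NaN.
    """
    if reference_hz not in framesets:
        raise ValueError(f"reference frequency {reference_hz} Hz not present")
    unified = assemble_mf(framesets)

    def corrected_mean(f: float) -> np.ndarray:
        fs = unified[f]
        a = fs.amplitudes.mean(axis=0)
        if amplifier is not None:
            a = a / gain_filter(amplifier, f)
        a = a.copy()
        a[fs.rejection_mask] = np.nan
        return a

    ref = corrected_mean(reference_hz)
    return {f: corrected_mean(f) - ref for f in unified if f != reference_hz}


@dataclass
class SpectrumResult:
    """Relative impedance change versus frequency from a sweep."""

    frequencies_hz: np.ndarray
    relative_change_pct: np.ndarray  # pooled mean, 0 at the reference
    se_pct: np.ndarray  # standard error across electrodes
    per_electrode_pct: np.ndarray  # (electrodes, frequencies)
    reference_hz: float
    orderings: tuple[str, ...] = ()

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["freq_hz", "rel_change_pct", "se_pct", "n"])
            n = self.per_electrode_pct.shape[0]
            for f, r, s in zip(self.frequencies_hz, self.relative_change_pct, self.se_pct):
                writer.writerow([f, r, s, n])


def sweep_spectrum(
    runs: list[dict[float, np.ndarray]],
    reference_hz: float | None = None,
    orderings: tuple[str, ...] = (),
) -> SpectrumResult:
    """Combine repeated sweep runs into a relative impedance spectrum.

    Each run maps frequency -> per-electrode demodulated amplitudes (already
    gain-corrected if an amplifier model applies). Amplitudes are averaged
    over runs per electrode, the relative change is taken against the
    reference frequency (default: lowest common frequency), and the standard
    error across electrodes is reported. Frequencies missing from some run
    are dropped to the common intersection with a warning.
    """
    if not runs:
        raise ValueError("at least one sweep run is required")
    common = set(runs[0])
    for r in runs[1:]:
        common &= set(r)
    dropped = set().union(*runs) - common
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} frequencies missing from some orderings",
            stacklevel=2,
        )
    if not common:
        raise ValueError("no frequency common to all runs")
    freqs = np.array(sorted(common))
    if reference_hz is None:
        reference_hz = float(freqs[0])
    if reference_hz not in common:
        raise ValueError(f"reference frequency {reference_hz} Hz not common to runs")

    # (electrodes, frequencies) mean amplitude over runs
    amp = np.stack(
        [np.mean([np.asarray(r[f], dtype=float) for r in runs], axis=0) for f in freqs],
        axis=1,
    )
    ref_col = amp[:, list(freqs).index(reference_hz)][:, None]
    per_elec = 100.0 * (amp - ref_col) / ref_col
    pooled = per_elec.mean(axis=0)
    se = per_elec.std(axis=0, ddof=1) / np.sqrt(per_elec.shape[0]) if per_elec.shape[0] > 1 else np.zeros_like(pooled)
    return SpectrumResult(freqs, pooled, se, per_elec, reference_hz, orderings)
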