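"""Injection protocols, frequency plans and frame timing arithmetic.

An EIT *protocol* is the ordered sequence of electrode pairs through which
sinusoidal current is injected; one full pass over the sequence is a *frame*.
In multi-frequency operation the pass is repeated per carrier frequency, with
a per-frequency injection duration expressed in integer carrier periods so
that low frequencies are not disproportionately slow to acquire.

Electrode indices are 1-based throughout the public API (EEG-channel
convention); arrays internally are 0-based.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "InjectionProtocol",
    "FrequencyPlan",
    "TimingPlan",
    "ReciprocalMatch",
    "periods_for_frequency",
    "frame_period",
    "count_measurements",
    "frames_in_duration",
    "reciprocal_pairs",
    "amplitude_for_frequency",
]

PeriodsRule = Literal["two_band", "three_band"]


@dataclass(frozen=True)
class InjectionProtocol:
    """Ordered list of (source, sink) injection electrode pairs.

    Parameters
    ----------
    pairs
        Sequence of 1-based ``(source, sink)`` electrode index pairs.
    n_electrodes
        Total number of recording electrodes.
    current_amplitude_a
        Injected current amplitude in amperes (default 100 uA, a typical
        scalp-safe value in the low-kHz band).
    name
        Free-form label.
    """

    pairs: tuple[tuple[int, int], ...]
    n_electrodes: int
    current_amplitude_a: float = 100e-6
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise ValueError("protocol must contain at least one injection pair")
        object.__setattr__(self, "pairs", tuple((int(s), int(k)) for s, k in self.pairs))
        for i, (src, sink) in enumerate(self.pairs):
            if src == sink:
                raise ValueError(f"pair {i}: source equals sink ({src})")
            for e in (src, sink):
                if not 1 <= e <= self.n_electrodes:
                    raise ValueError(
                        f"pair {i}: electrode {e} outside [1, {self.n_electrodes}]"
                    )
        if self.current_amplitude_a <= 0:
            raise ValueError("current amplitude must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def injection_mask(self) -> np.ndarray:
        """Boolean array (n_pairs, n_electrodes); True where the electrode injects."""
        mask = np.zeros((self.n_pairs, self.n_electrodes), dtype=bool)
        for i, (src, sink) in enumerate(self.pairs):
            mask[i, src - 1] = True
            mask[i, sink - 1] = True
        return mask

    @classmethod
    def from_csv(
        cls,
        path,
        n_electrodes: int | None = None,
        current_amplitude_a: float = 100e-6,
        name: str = "",
    ) -> "InjectionProtocol":
        """Read a ``src,sink`` CSV (header row required)."""
        pairs = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"src", "sink"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected CSV header 'src,sink'")
            for row in reader:
                pairs.append((int(row["src"]), int(row["sink"])))
        if n_electrodes is None:
            n_electrodes = max(max(p) for p in pairs)
        return cls(tuple(pairs), n_electrodes, current_amplitude_a, name or str(path))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["src", "sink"])
            writer.writerows(self.pairs)

    def concat(self, other: "InjectionProtocol") -> "InjectionProtocol":
        if other.n_electrodes != self.n_electrodes:
            raise ValueError("electrode counts differ")
        return replace(self, pairs=self.pairs + other.pairs)


def periods_for_frequency(f_hz: float, rule: PeriodsRule = "two_band") -> int:
    """Number of carrier periods to average per injection at frequency ``f_hz``.

    The two-band rule uses 32 periods below 200 Hz and 64 at or above; the
    three-band rule additionally steps up to 128 periods above 1 kHz, keeping
    per-injection duration roughly balanced across a 5 Hz-20 kHz sweep.
    """
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    if rule == "two_band":
        return 32 if f_hz < 200 else 64
    if rule == "three_band":
        if f_hz < 200:
            return 32
        if f_hz <= 1000:
            return 64
        return 128
    raise ValueError(f"unknown periods rule {rule!r}")


def amplitude_for_frequency(f_hz: float, table: Sequence[tuple[float, float]]) -> float:
    """Look up an injection current for ``f_hz`` from a policy table.

    ``table`` is a list of ``(upper_frequency_hz, amplitude_a)`` rows sorted by
    frequency; the first row whose upper frequency is >= ``f_hz`` applies, and
    the last row is the default. This expresses safety-limit policies such as
    "IEC-limit current, halved below 200 Hz" as data rather than code.
    """
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    if not table:
        raise ValueError("empty amplitude table")
    for f_max, amp in table:
        if f_hz <= f_max:
            return float(amp)
    return float(table[-1][1])


@dataclass(frozen=True)
class FrequencyPlan:
    """Carrier frequencies with per-frequency periods and current amplitudes."""

    frequencies: tuple[float, ...]
    periods_per_injection: dict[float, int] = field(default_factory=dict)
    ordering: Literal["fixed", "ascending", "descending", "random"] = "fixed"
    amplitude_per_frequency: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        if len(self.frequencies) == 0:
            raise ValueError("frequency plan must contain at least one frequency")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")
        if any(p < 1 for p in self.periods_per_injection.values()):
            raise ValueError("periods per injection must be >= 1")
        if any(a <= 0 for a in self.amplitude_per_frequency.values()):
            raise ValueError("amplitudes must be positive")

    @classmethod
    def single(cls, f_hz: float, periods: int | None = None) -> "FrequencyPlan":
        plan = {f_hz: periods} if periods is not None else {}
        return cls((f_hz,), periods_per_injection=plan)

    @classmethod
    def from_rule(
        cls,
        frequencies: Iterable[float],
        rule: PeriodsRule = "two_band",
        amplitude_a: float | None = None,
        amplitude_table: Sequence[tuple[float, float]] | None = None,
        ordering: Literal["fixed", "ascending", "descending", "random"] = "fixed",
    ) -> "FrequencyPlan":
        freqs = tuple(float(f) for f in frequencies)
        periods = {f: periods_for_frequency(f, rule) for f in freqs}
        amps: dict[float, float] = {}
        if amplitude_table is not None:
            amps = {f: amplitude_for_frequency(f, amplitude_table) for f in freqs}
        elif amplitude_a is not None:
            amps = {f: amplitude_a for f in freqs}
        return cls(freqs, periods, ordering, amps)

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies)

    def periods(self, f_hz: float) -> int | None:
        return self.periods_per_injection.get(f_hz)

    def duration_s(self, f_hz: float, fallback_s: float | None = None) -> float:
        """Injection duration at ``f_hz``: periods/f when periods are planned."""
        p = self.periods(f_hz)
        if p is not None:
            return p / f_hz
        if fallback_s is not None:
            return fallback_s
        raise ValueError(f"no periods planned for {f_hz} Hz and no fallback duration")

    def order_for_frame(self, rng: np.random.Generator | None = None) -> list[int]:
        """Frequency indices in acquisition order for one frame."""
        idx = list(range(self.n_frequencies))
        if self.ordering == "ascending":
            return sorted(idx, key=lambda i: self.frequencies[i])
        if self.ordering == "descending":
            return sorted(idx, key=lambda i: -self.frequencies[i])
        if self.ordering == "random":
            if rng is None:
                raise ValueError("random ordering requires an rng")
            return list(rng.permutation(self.n_frequencies))
        return idx


@dataclass(frozen=True)
class TimingPlan:
    """Per-pair injection duration and inter-injection gap.

    ``injection_duration_s`` may be a scalar (same for every pair) or a
    sequence with one entry per pair. When the duration is derived from a
    periods rule it is ``periods / f`` exactly; rounding to an integer number
    of samples happens at simulation and segmentation, not here.
    """

    injection_duration_s: float | tuple[float, ...]
    inter_injection_gap_s: float = 0.0

    def __post_init__(self) -> None:
        d = self.injection_duration_s
        if not np.isscalar(d):
            object.__setattr__(self, "injection_duration_s", tuple(float(x) for x in d))
            d = self.injection_duration_s
            if any(x <= 0 for x in d):
                raise ValueError("durations must be positive")
        elif d <= 0:
            raise ValueError("durations must be positive")
        if self.inter_injection_gap_s < 0:
            raise ValueError("gap must be non-negative")

    def durations(self, n_pairs: int) -> np.ndarray:
        d = self.injection_duration_s
        if np.isscalar(d):
            return np.full(n_pairs, float(d))
        d = np.asarray(d, dtype=float)
        if len(d) != n_pairs:
            raise ValueError(f"{len(d)} durations for {n_pairs} pairs")
        return d

    @classmethod
    def from_periods(cls, f_hz: float, periods: int, gap_s: float = 0.0) -> "TimingPlan":
        return cls(periods / f_hz, gap_s)


def frame_period(protocol: InjectionProtocol, timing: TimingPlan) -> float:
    """Total duration of one frame: sum of per-pair durations plus gaps."""
    d = timing.durations(protocol.n_pairs)
    return float(d.sum() + timing.inter_injection_gap_s * protocol.n_pairs)


def count_measurements(protocol: InjectionProtocol, exclude_injection: bool = False) -> int:
    """Voltage measurements per frame: pairs x electrodes, optionally minus
    the two injecting electrodes of each pair."""
    per_pair = protocol.n_electrodes - (2 if exclude_injection else 0)
    return protocol.n_pairs * max(per_pair, 0)


def frames_in_duration(total_s: float, frame_period_s: float) -> int:
    """Complete frames acquired in ``total_s`` seconds."""
    if total_s <= 0 or frame_period_s <= 0:
        raise ValueError("durations must be positive")
    return int(np.floor(total_s / frame_period_s + 1e-12))


class ReciprocalMatch(NamedTuple):
    """Injection pair ``a`` measured across pair ``b``'s electrodes and vice versa."""

    pair_a: int
    pair_b: int
    voltage_pair: tuple[int, int]  # measurement electrodes for pair_a = pairs[b]


def reciprocal_pairs(protocol: InjectionProtocol) -> list[ReciprocalMatch]:
    """All reciprocal measurement matches within a protocol.

    With parallel voltage recording every electrode pair is a candidate
    measurement pair, so injections a=(i,j) and b=(k,l) form a reciprocal
    match whenever {i,j} and {k,l} are disjoint: the voltage across (k,l)
    while injecting through (i,j) should equal the voltage across (i,j)
    while injecting through (k,l), for any reciprocal (passive, symmetric)
    load. Matches are returned once with ``pair_a < pair_b``.
    """
    matches = []
    for a in range(protocol.n_pairs):
        sa = set(protocol.pairs[a])
        for b in range(a + 1, protocol.n_pairs):
            if sa.isdisjoint(protocol.pairs[b]):
                matches.append(ReciprocalMatch(a, b, protocol.pairs[b]))
    return matches


def plan_to_json(plan: FrequencyPlan, timing: TimingPlan | None = None) -> str:
    obj = {
        "frequencies_hz": list(plan.frequencies),
        "periods_per_injection": {str(f): p for f, p in plan.periods_per_injection.items()},
        "ordering": plan.ordering,
        "amplitude_per_frequency_a": {
            str(f): a for f, a in plan.amplitude_per_frequency.items()
        },
    }
    if timing is not None:
        obj["injection_duration_s"] = (
            timing.injection_duration_s
            if np.isscalar(timing.injection_duration_s)
            else list(timing.injection_duration_s)
        )
        obj["gap_s"] = timing.inter_injection_gap_s
    return json.dumps(obj, indent=2)
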