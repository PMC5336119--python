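"""Coded trigger-channel events and segmentation of recordings.

The acquisition controller marks the start/stop of current injection, pair
switches, frequency changes, stimulation triggers and current-source
out-of-compliance states as coded pulses on a dedicated integer status
channel, the way BioSemi/BrainVision-style EEG systems record their trigger
inputs. The code map here packs the event class in the low byte and an
optional payload (pair index, frequency index) in the high byte of a 16-bit
status value; each event is held for a fixed pulse width on an otherwise
zero channel.

Segmentation replays the protocol order against the decoded PAIR_SWITCH /
FREQ_CHANGE events to tag each injection window with its (frame, frequency,
pair), trimming a settle fraction at both ends to exclude switching
transients and filter edges.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "EventCode",
    "Event",
    "EventLog",
    "Segment",
    "encode_events",
    "decode_trigger_channel",
    "segment_recording",
    "SegmentationError",
]

PULSE_WIDTH = 4  # samples a status code is held for


class EventCode(IntEnum):
    INJ_START = 1
    INJ_STOP = 2
    PAIR_SWITCH = 3
    FREQ_CHANGE = 4
    STIM = 5
    OUT_OF_COMPLIANCE = 6
    ZERO_PHASE = 7


@dataclass(frozen=True, order=True)
class Event:
    sample: int
    code: int
    payload: int = 0

    @property
    def label(self) -> str:
        try:
            return EventCode(self.code).name
        except ValueError:
            return f"UNKNOWN_{self.code}"

    @property
    def status_value(self) -> int:
        return (self.code & 0xFF) | ((self.payload & 0xFF) << 8)


@dataclass
class EventLog:
    """Ordered list of events; sample indices must be non-decreasing."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events)
        samples = [e.sample for e in self.events]
        if any(s < 0 for s in samples):
            raise ValueError("negative event sample index")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def add(self, sample: int, code: int, payload: int = 0) -> None:
        self.events.append(Event(int(sample), int(code), int(payload)))
        self.events.sort()

    def of(self, code: int) -> list[Event]:
        return [e for e in self.events if e.code == code]

    def samples_of(self, code: int) -> np.ndarray:
        return np.array([e.sample for e in self.events if e.code == code], dtype=int)

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["sample", "code", "payload", "label"])
            for e in self.events:
                writer.writerow([e.sample, e.code, e.payload, e.label])

    @classmethod
    def from_tsv(cls, path) -> "EventLog":
        events = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                events.append(Event(int(row["sample"]), int(row["code"]), int(row["payload"])))
        return cls(events)


def encode_events(
    eventlog: EventLog, n_samples: int, pulse_width: int = PULSE_WIDTH
) -> np.ndarray:
    """Render an event log as an integer status channel.

    Each event's 16-bit status value is held for ``pulse_width`` samples on an
    otherwise-zero channel. Two events whose pulses would overlap are a hard
    error: the controller cannot emit simultaneous codes.
    """
    status = np.zeros(n_samples, dtype=np.int32)
    last_end = -1
    for e in eventlog.events:
        if e.sample + pulse_width > n_samples:
            raise ValueError(f"event at sample {e.sample} extends past recording end")
        if e.sample < last_end:
            raise ValueError(
                f"event collision: pulse at sample {e.sample} overlaps previous pulse"
            )
        status[e.sample : e.sample + pulse_width] = e.status_value
        last_end = e.sample + pulse_width
    return status


def decode_trigger_channel(status: np.ndarray, pulse_width: int = PULSE_WIDTH) -> EventLog:
    """Recover an event log from a status channel.

    An event is registered at every sample where the status value changes to
    a new non-zero value (rising edge or code change); a channel held non-zero
    from the first sample yields a single event there. Unknown code bytes are
    kept verbatim so downstream stages can report them.
    """
    status = np.asarray(status)
    if status.ndim != 1:
        raise ValueError("status channel must be 1-D")
    prev = np.concatenate(([0], status[:-1]))
    edges = np.nonzero((status != 0) & (status != prev))[0]
    events = [
        Event(int(i), int(status[i]) & 0xFF, (int(status[i]) >> 8) & 0xFF) for i in edges
    ]
    return EventLog(events)


@dataclass
class Segment:
    """One injection window: a half-open sample span tagged with its
    (frame, frequency, pair) position in the protocol."""

    pair_index: int
    frequency_hz: float
    frame_index: int
    start: int
    stop: int
    frequency_index: int = 0
    valid: bool = True
    settle_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("segment stop must exceed start")

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    @property
    def measurement_span(self) -> tuple[int, int]:
        """Span with the first and last settle fraction trimmed."""
        trim = int(np.floor(self.settle_fraction * self.n_samples))
        return self.start + trim, self.stop - trim


class SegmentationError(RuntimeError):
    pass


def segment_recording(
    n_samples: int,
    eventlog: EventLog,
    protocol,
    frequency_plan=None,
    settle_fraction: float = 0.1,
) -> list[Segment]:
    """Cut a recording into per-(frame, frequency, pair) segments.

    The protocol order is replayed against the decoded events: every
    PAIR_SWITCH opens a segment that closes at the next PAIR_SWITCH,
    FREQ_CHANGE or INJ_STOP event. PAIR_SWITCH payloads must follow the
    protocol's pair order cyclically; a divergence is a hard error naming the
    first offending frame and switch. FREQ_CHANGE payloads index into the
    frequency plan; each frequency block contains one full protocol pass, and
    the frame index of a block counts previous blocks at the same frequency,
    which supports both frequency-within-frame and frequency-between-frame
    orderings. OUT_OF_COMPLIANCE events invalidate the segment they fall in.
    """
    if not 0 <= settle_fraction < 0.5:
        raise ValueError("settle_fraction must be in [0, 0.5)")
    frequencies = (
        tuple(frequency_plan.frequencies) if frequency_plan is not None else None
    )

    boundary_codes = {EventCode.PAIR_SWITCH, EventCode.FREQ_CHANGE, EventCode.INJ_STOP}
    boundaries = [e for e in eventlog.events if e.code in boundary_codes]

    stop_samples = eventlog.samples_of(EventCode.INJ_STOP)
    default_stop = int(stop_samples[-1]) if len(stop_samples) else n_samples

    segments: list[Segment] = []
    freq_index = 0
    passes: dict[int, int] = {}  # completed protocol passes per frequency
    pos = 0  # position within the current pass

    for i, ev in enumerate(boundaries):
        if ev.code == EventCode.FREQ_CHANGE:
            if frequencies is None:
                raise SegmentationError(
                    "FREQ_CHANGE event found but no frequency plan supplied"
                )
            if pos:
                raise SegmentationError(
                    f"frequency change after {pos} of {protocol.n_pairs} switches "
                    f"in frame {passes.get(freq_index, 0)}"
                )
            if ev.payload >= len(frequencies):
                raise SegmentationError(
                    f"frequency index {ev.payload} outside plan of {len(frequencies)}"
                )
            freq_index = ev.payload
            continue
        if ev.code == EventCode.INJ_STOP:
            continue
        # PAIR_SWITCH
        frame_idx = passes.get(freq_index, 0)
        if ev.payload != pos:
            raise SegmentationError(
                f"protocol/event mismatch at frame {frame_idx}, switch {pos}: "
                f"event payload {ev.payload}"
            )
        stop = default_stop
        for nxt in boundaries[i + 1 :]:
            stop = nxt.sample
            break
        segments.append(
            Segment(
                pair_index=pos,
                frequency_hz=(
                    frequencies[freq_index] if frequencies is not None else float("nan")
                ),
                frame_index=frame_idx,
                start=ev.sample,
                stop=min(stop, n_samples),
                frequency_index=freq_index,
                settle_fraction=settle_fraction,
            )
        )
        pos += 1
        if pos == protocol.n_pairs:
            passes[freq_index] = frame_idx + 1
            pos = 0

    if pos:
        raise SegmentationError(
            f"incomplete frame {passes.get(freq_index, 0)}: {pos} of "
            f"{protocol.n_pairs} switches"
        )

    # out-of-compliance invalidation
    ooc = eventlog.samples_of(EventCode.OUT_OF_COMPLIANCE)
    if len(ooc):
        for seg in segments:
            if np.any((ooc >= seg.start) & (ooc < seg.stop)):
                seg.valid = False
    return segments
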