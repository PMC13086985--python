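"""Acquisition frame schedules and low-activity frame truncation.

A 90-min dynamic brain PET acquisition is binned into 31 contiguous frames
(8 x 15 s, 3 x 60 s, 5 x 120 s, 15 x 300 s).  Low-injected-activity
acquisitions are emulated from list-mode data by inserting a delay at the
start of every frame and keeping only the tail of the frame, so that a
fraction ``f`` of the events survives while the frame grid itself is
preserved.  The retained duration and delay for each (fraction, frame
duration) pair follow a fixed published lookup table which rounds
inconsistently across rows; the table is therefore stored verbatim rather
than derived from a rounding rule.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "FULL_SCHEDULE_BLOCKS",
    "SCHEME_LABELS",
    "FrameSchedule",
    "LowActivityScheme",
    "TruncatedFrame",
    "make_full_schedule",
    "make_scheme",
    "make_custom_scheme",
    "apply_scheme",
    "percent_label",
]

#: (number of frames, frame duration in seconds) blocks of the full schedule.
FULL_SCHEDULE_BLOCKS: tuple[tuple[int, float], ...] = (
    (8, 15.0),
    (3, 60.0),
    (5, 120.0),
    (15, 300.0),
)

#: Verbatim truncation lookup: label -> {original duration: (retained, delay)}.
#: Rounding is intentionally NOT uniform across rows (e.g. 15 s at 1/2 -> 7 s
#: but 15 s at 1/4 -> 4 s); the printed scheme is authoritative.
_TRUNCATION_TABLE: dict[str, dict[float, tuple[float, float]]] = {
    "1/2": {15.0: (7.0, 8.0), 60.0: (30.0, 30.0), 120.0: (60.0, 60.0), 300.0: (150.0, 150.0)},
    "1/3": {15.0: (5.0, 10.0), 60.0: (20.0, 40.0), 120.0: (40.0, 80.0), 300.0: (100.0, 200.0)},
    "1/4": {15.0: (4.0, 11.0), 60.0: (15.0, 45.0), 120.0: (30.0, 90.0), 300.0: (75.0, 225.0)},
    "1/5": {15.0: (3.0, 12.0), 60.0: (12.0, 48.0), 120.0: (24.0, 96.0), 300.0: (60.0, 240.0)},
    "1/6": {15.0: (2.0, 13.0), 60.0: (10.0, 50.0), 120.0: (20.0, 100.0), 300.0: (50.0, 250.0)},
    "1/10": {15.0: (1.0, 14.0), 60.0: (6.0, 54.0), 120.0: (12.0, 108.0), 300.0: (30.0, 270.0)},
    "1/15": {15.0: (1.0, 14.0), 60.0: (4.0, 56.0), 120.0: (8.0, 112.0), 300.0: (20.0, 280.0)},
}

#: Recognised scheme labels, ordered from full activity downwards.
SCHEME_LABELS: tuple[str, ...] = ("full", "1/2", "1/3", "1/4", "1/5", "1/6", "1/10", "1/15")

_MIDTIME_CONVENTIONS = ("retained_window", "original_frame")


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous list of acquisition frames.

    Parameters
    ----------
    frames :
        Sequence of ``(start_s, duration_s)`` pairs, contiguous and
        non-overlapping, starting wherever the acquisition starts.
    label :
        Free-text name of the schedule.
    """

    frames: tuple[tuple[float, float], ...]
    label: str = "schedule"

    def __post_init__(self) -> None:
        frames = tuple((float(s), float(d)) for s, d in self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise ValueError("a FrameSchedule needs at least one frame")
        for i, (start, dur) in enumerate(frames):
            if dur <= 0:
                raise ValueError(f"frame {i} has non-positive duration {dur}")
            if i and abs(start - (frames[i - 1][0] + frames[i - 1][1])) > 1e-9:
                raise ValueError(
                    f"frames must be contiguous: frame {i} starts at {start}, "
                    f"previous frame ends at {frames[i - 1][0] + frames[i - 1][1]}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> tuple[float, ...]:
        return tuple(s for s, _ in self.frames)

    @property
    def durations_s(self) -> tuple[float, ...]:
        return tuple(d for _, d in self.frames)

    @property
    def midtimes_s(self) -> tuple[float, ...]:
        return tuple(s + d / 2 for s, d in self.frames)

    @property
    def total_duration_s(self) -> float:
        return sum(self.durations_s)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame_index", "start_s", "duration_s"])
            for i, (s, d) in enumerate(self.frames):
                w.writerow([i, f"{s:g}", f"{d:g}"])

    @classmethod
    def from_csv(cls, path, label: str = "schedule") -> "FrameSchedule":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        frames = tuple((float(r["start_s"]), float(r["duration_s"])) for r in rows)
        return cls(frames=frames, label=label)


@dataclass(frozen=True)
class LowActivityScheme:
    """Retained-duration/delay lookup for one activity fraction.

    ``entries`` maps each original frame duration (s) to a
    ``(retained_duration_s, delay_s)`` pair with
    ``retained + delay == original``.
    """

    fraction_label: str
    fraction_value: float
    entries: dict[float, tuple[float, float]] = field(compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.fraction_value <= 1):
            raise ValueError(f"fraction_value must be in (0, 1], got {self.fraction_value}")
        for dur, (ret, delay) in self.entries.items():
            if ret < 1.0:
                raise ValueError(f"retained duration below 1 s for original duration {dur}")
            if abs(ret + delay - dur) > 1e-9:
                raise ValueError(
                    f"retained + delay must equal the original duration "
                    f"({ret} + {delay} != {dur})"
                )

    def lookup(self, duration_s: float) -> tuple[float, float]:
        """Return ``(retained_duration_s, delay_s)`` for an original duration."""
        try:
            return self.entries[float(duration_s)]
        except KeyError:
            raise KeyError(
                f"scheme '{self.fraction_label}' has no entry for frame duration "
                f"{duration_s} s (known: {sorted(self.entries)})"
            ) from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "fraction_label": self.fraction_label,
                "fraction_value": self.fraction_value,
                "entries": {str(k): list(v) for k, v in sorted(self.entries.items())},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LowActivityScheme":
        obj = json.loads(text)
        return cls(
            fraction_label=obj["fraction_label"],
            fraction_value=float(obj["fraction_value"]),
            entries={float(k): (float(v[0]), float(v[1])) for k, v in obj["entries"].items()},
        )


@dataclass(frozen=True)
class TruncatedFrame:
    """One frame after delay insertion: only the tail of the frame is kept."""

    original_start_s: float
    original_duration_s: float
    delay_s: float
    retained_duration_s: float
    midtime_convention: str = "retained_window"

    def __post_init__(self) -> None:
        if self.midtime_convention not in _MIDTIME_CONVENTIONS:
            raise ValueError(
                f"midtime_convention must be one of {_MIDTIME_CONVENTIONS}, "
                f"got {self.midtime_convention!r}"
            )
        if self.retained_duration_s <= 0:
            raise ValueError("retained duration must be positive")
        if self.delay_s < 0 or self.delay_s + self.retained_duration_s > self.original_duration_s + 1e-9:
            raise ValueError("retained window must lie inside the original frame")

    @property
    def retained_start_s(self) -> float:
        return self.original_start_s + self.delay_s

    @property
    def retained_end_s(self) -> float:
        return self.original_start_s + self.original_duration_s

    @property
    def midtime_s(self) -> float:
        """Mid-time under the frame's convention.

        ``retained_window`` centres the mid-time on the window that actually
        contributed events (physically correct); ``original_frame`` keeps the
        full-frame mid-time, reproducing the timing bias a truncation-based
        reconstruction incurs when frame timing metadata is left unchanged.
        """
        if self.midtime_convention == "retained_window":
            return self.original_start_s + self.delay_s + self.retained_duration_s / 2
        return self.original_start_s + self.original_duration_s / 2


def make_full_schedule() -> FrameSchedule:
    """Full-activity 31-frame, 90-min schedule (8x15 s, 3x60 s, 5x120 s, 15x300 s)."""
    frames = []
    t = 0.0
    for n, dur in FULL_SCHEDULE_BLOCKS:
        for _ in range(n):
            frames.append((t, dur))
            t += dur
    return FrameSchedule(frames=tuple(frames), label="full_31_frame")


def make_scheme(fraction_label: str) -> LowActivityScheme:
    """Return the truncation scheme for one of the eight canonical labels.

    ``"full"`` maps every duration to itself with zero delay; the seven
    reduced labels return the verbatim published lookup.
    """
    label = str(fraction_label)
    if label == "full":
        entries = {d: (d, 0.0) for _, d in FULL_SCHEDULE_BLOCKS}
        return LowActivityScheme(fraction_label="full", fraction_value=1.0, entries=entries)
    if label not in _TRUNCATION_TABLE:
        raise ValueError(
            f"unknown scheme label {label!r}; valid labels are {', '.join(SCHEME_LABELS)}"
        )
    frac = Fraction(label)
    return LowActivityScheme(
        fraction_label=label,
        fraction_value=float(frac),
        entries=dict(_TRUNCATION_TABLE[label]),
    )


def make_custom_scheme(fraction_value: float, durations_s: Iterable[float] = (15.0, 60.0, 120.0, 300.0)) -> LowActivityScheme:
    """Build a scheme for an arbitrary fraction (extension beyond the 8 labels).

    Retained duration is ``max(1 s, round(duration * f))``.  Never used for
    the canonical labels, whose printed lookup takes precedence.
    """
    f = float(fraction_value)
    if not (0 < f <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {f}")
    entries = {}
    for d in durations_s:
        ret = max(1.0, float(round(d * f)))
        entries[float(d)] = (ret, float(d) - ret)
    return LowActivityScheme(fraction_label=f"custom:{f:g}", fraction_value=f, entries=entries)


def apply_scheme(
    schedule: FrameSchedule,
    scheme: LowActivityScheme,
    midtime_convention: str = "retained_window",
) -> list[TruncatedFrame]:
    """Truncate every frame of ``schedule`` according to ``scheme``.

    The retained window always sits at the end of the original frame (events
    binned at the start of each frame are rejected).  Frame count and order
    are preserved.
    """
    out = []
    for start, dur in schedule.frames:
        ret, delay = scheme.lookup(dur)
        out.append(
            TruncatedFrame(
                original_start_s=start,
                original_duration_s=dur,
                delay_s=delay,
                retained_duration_s=ret,
                midtime_convention=midtime_convention,
            )
        )
    return out


def percent_label(fraction_value: float) -> float:
    """Percentage of administered activity, rounded half-up to 2 decimals.

    ``1/15 -> 6.67``, ``1/2 -> 50.0``.
    """
    f = float(fraction_value)
    if not (0 < f <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {f}")
    return float(Decimal(repr(100 * f)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def retained_total_s(scheme: LowActivityScheme, schedule: FrameSchedule | None = None) -> float:
    """Total retained acquisition time (s) of ``schedule`` under ``scheme``."""
    schedule = schedule or make_full_schedule()
    return sum(scheme.lookup(d)[0] for d in schedule.durations_s)
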