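"""Block-design session timeline and epoch windows.

The paradigm is a 5-minute block design made of 60-s samples. Each sample
interleaves four 5-s rest periods with two 10-s hand-tapping periods
(opposite hands, onsets 20 s apart) and two 10-s mental-task periods (one
arithmetic subtraction, one backwards counting, onsets 20 s apart):

    rest(5) tap(10) rest(5) mental(10) rest(5) tap'(10) rest(5) mental'(10)

Tapping is recorded by EEG over the motor cortex, the mental tasks by NIRS
over the prefrontal cortex. EEG analysis epochs span +1 to +11 s relative to
each tapping onset; NIRS windows are shifted by the hemodynamic onset lag
(default 2 s, the delay at which oxy-hemoglobin starts to rise after the
prompt).

Time is float seconds from session start; block intervals are half-open
``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import InvalidArgumentError, ScheduleError

REST = "rest"
TAP_LEFT = "tap_left"
TAP_RIGHT = "tap_right"
MENTAL_ARITHMETIC = "mental_arithmetic"
MENTAL_COUNTING = "mental_counting"

TASK_LABELS = (REST, TAP_LEFT, TAP_RIGHT, MENTAL_ARITHMETIC, MENTAL_COUNTING)
TAP_LABELS = (TAP_LEFT, TAP_RIGHT)
MENTAL_LABELS = (MENTAL_ARITHMETIC, MENTAL_COUNTING)

SAMPLE_DURATION = 60.0  # seconds per data sample
REST_DURATION = 5.0
TASK_DURATION = 10.0

#: tolerance for timeline arithmetic on float seconds
_TIME_TOL = 1e-9


@dataclass(frozen=True)
class TaskBlock:
    """One contiguous block of the paradigm."""

    label: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.label not in TASK_LABELS:
            raise InvalidArgumentError(f"unknown task label {self.label!r}")
        if self.onset < 0:
            raise InvalidArgumentError(f"block onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise InvalidArgumentError(f"block duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class EpochWindow:
    """Analysis window derived from a task block, tagged with its modality."""

    start: float
    end: float
    label: str
    modality: Literal["eeg", "nirs"]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidArgumentError("epoch window must have end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class EventSchedule:
    """Ordered, contiguous list of task blocks tiling [0, total_duration)."""

    blocks: tuple[TaskBlock, ...]
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ScheduleError("schedule has no blocks")
        t = self.blocks[0].onset
        if abs(t) > _TIME_TOL:
            raise ScheduleError(f"first block must start at 0, starts at {t}")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if abs(nxt.onset - prev.end) > _TIME_TOL:
                raise ScheduleError(
                    f"blocks must be contiguous and non-overlapping: block ending at "
                    f"{prev.end} s followed by onset {nxt.onset} s"
                )

    @property
    def total_duration(self) -> float:
        return self.blocks[-1].end

    def blocks_with_label(self, *labels: str) -> list[TaskBlock]:
        return [b for b in self.blocks if b.label in labels]

    def label_at(self, time: float) -> str:
        """Task label at a time point (half-open block intervals)."""
        for b in self.blocks:
            if b.onset - _TIME_TOL <= time < b.end - _TIME_TOL:
                return b.label
        return self.blocks[-1].label if abs(time - self.total_duration) <= 1e-6 else REST

    def validate_paradigm(self) -> None:
        """Check the per-sample composition of the block design.

        Each 60-s sample must contain exactly four 5-s rest blocks, one
        tapping block per hand (10 s each, onsets 20 s apart) and one mental
        block per task (10 s each, onsets 20 s apart).
        """
        if self.n_samples < 1:
            raise ScheduleError("paradigm schedule must declare n_samples >= 1")
        if abs(self.total_duration - SAMPLE_DURATION * self.n_samples) > 1e-6:
            raise ScheduleError(
                f"total duration {self.total_duration} s != 60 s x {self.n_samples} samples"
            )
        for s in range(self.n_samples):
            lo, hi = s * SAMPLE_DURATION, (s + 1) * SAMPLE_DURATION
            sample = [b for b in self.blocks if lo - _TIME_TOL <= b.onset < hi - _TIME_TOL]
            counts = {lab: sum(b.label == lab for b in sample) for lab in TASK_LABELS}
            if counts[REST] != 4 or any(counts[lab] != 1 for lab in TASK_LABELS[1:]):
                raise ScheduleError(f"sample {s} composition invalid: {counts}")
            for labels in (TAP_LABELS, MENTAL_LABELS):
                # trials of one modality are separated by a 20-s gap
                # (end-to-next-onset), i.e. onsets are 30 s apart
                onsets = sorted(b.onset for b in sample if b.label in labels)
                if abs(onsets[1] - (onsets[0] + TASK_DURATION) - 20.0) > 1e-6:
                    raise ScheduleError(
                        f"sample {s}: {labels} trials at {onsets} are not separated by 20 s"
                    )


def build_session(
    n_samples: int,
    first_hand: Literal["left", "right"] = "left",
    first_mental: Literal["arithmetic", "counting"] = "counting",
    alternate: bool = True,
) -> EventSchedule:
    """Build the block-design timeline for ``n_samples`` 60-s data samples.

    Each sample is rest(5)-tap(10)-rest(5)-mental(10)-rest(5)-tap-opposite(10)-
    rest(5)-mental-opposite(10). With ``alternate`` set, the hand and mental
    sequences keep toggling across samples as well, so every hand and every
    mental task occurs exactly ``n_samples`` times in the session.

    The paradigm does not prescribe which hand or mental task is prompted
    first; the defaults (left hand, counting) are arbitrary but fixed for
    reproducibility.
    """
    if not isinstance(n_samples, int) or isinstance(n_samples, bool) or n_samples < 1:
        raise InvalidArgumentError(f"n_samples must be a positive integer, got {n_samples!r}")
    if first_hand not in ("left", "right"):
        raise InvalidArgumentError(f"first_hand must be 'left' or 'right', got {first_hand!r}")
    if first_mental not in ("arithmetic", "counting"):
        raise InvalidArgumentError(
            f"first_mental must be 'arithmetic' or 'counting', got {first_mental!r}"
        )

    hand = TAP_LEFT if first_hand == "left" else TAP_RIGHT
    mental = MENTAL_ARITHMETIC if first_mental == "arithmetic" else MENTAL_COUNTING

    def flip(label: str) -> str:
        pairs = {
            TAP_LEFT: TAP_RIGHT,
            TAP_RIGHT: TAP_LEFT,
            MENTAL_ARITHMETIC: MENTAL_COUNTING,
            MENTAL_COUNTING: MENTAL_ARITHMETIC,
        }
        return pairs[label]

    blocks: list[TaskBlock] = []
    t = 0.0
    for _ in range(n_samples):
        for slot in range(4):
            blocks.append(TaskBlock(REST, t, REST_DURATION))
            t += REST_DURATION
            if slot % 2 == 0:
                blocks.append(TaskBlock(hand, t, TASK_DURATION))
                hand = flip(hand)
            else:
                blocks.append(TaskBlock(mental, t, TASK_DURATION))
                mental = flip(mental)
            t += TASK_DURATION
        if not alternate:
            # restart each sample from the configured first tasks
            hand = TAP_LEFT if first_hand == "left" else TAP_RIGHT
            mental = MENTAL_ARITHMETIC if first_mental == "arithmetic" else MENTAL_COUNTING
    schedule = EventSchedule(tuple(blocks), n_samples=n_samples)
    schedule.validate_paradigm()
    return schedule


def epoch_windows(
    schedule: EventSchedule,
    modality: Literal["eeg", "nirs"],
    *,
    eeg_offsets: tuple[float, float] = (1.0, 11.0),
    nirs_lag: float = 2.0,
    nirs_length: float = 10.0,
) -> list[EpochWindow]:
    """Derive per-task analysis windows from a schedule.

    EEG windows span ``[onset + 1, onset + 11]`` around each tapping block;
    NIRS windows span ``[onset + lag, onset + lag + 10]`` around each mental
    block, the lag accounting for the hemodynamic onset delay.
    """
    if modality == "eeg":
        lo, hi = eeg_offsets
        return [
            EpochWindow(b.onset + lo, b.onset + hi, b.label, "eeg")
            for b in schedule.blocks_with_label(*TAP_LABELS)
        ]
    if modality == "nirs":
        return [
            EpochWindow(b.onset + nirs_lag, b.onset + nirs_lag + nirs_length, b.label, "nirs")
            for b in schedule.blocks_with_label(*MENTAL_LABELS)
        ]
    raise InvalidArgumentError(f"modality must be 'eeg' or 'nirs', got {modality!r}")


def write_events(schedule: EventSchedule, path: str | Path) -> None:
    """Write the schedule as a BIDS-style events TSV (onset, duration, trial_type)."""
    frame = pd.DataFrame(
        {
            "onset": [b.onset for b in schedule.blocks],
            "duration": [b.duration for b in schedule.blocks],
            "trial_type": [b.label for b in schedule.blocks],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_events(path: str | Path, n_samples: int | None = None) -> EventSchedule:
    """Read a BIDS-style events TSV back into a validated schedule."""
    frame = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(frame.columns):
        raise ScheduleError(
            f"events file {path} lacks required columns {sorted(required - set(frame.columns))}"
        )
    blocks = tuple(
        TaskBlock(str(row.trial_type), float(row.onset), float(row.duration))
        for row in frame.itertuples()
    )
    if n_samples is None:
        n_samples = int(round((blocks[-1].onset + blocks[-1].duration) / SAMPLE_DURATION))
    return EventSchedule(blocks, n_samples=n_samples)


def intended_command(label: str) -> str:
    """Control command a block's task is meant to produce (rest -> Stop)."""
    mapping = {
        REST: "Stop",
        TAP_LEFT: "Left",
        TAP_RIGHT: "Right",
        MENTAL_ARITHMETIC: "Back",
        MENTAL_COUNTING: "Forward",
    }
    return mapping[label]


def iter_rest_windows(schedule: EventSchedule) -> Iterable[EpochWindow]:
    """Windows spanning each rest block (used as the Stop class for training)."""
    for b in schedule.blocks_with_label(REST):
        yield EpochWindow(b.onset, b.end, REST, "eeg")
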