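"""Acquisition parameters and the blocked neurofeedback run design.

One neurofeedback (NF) run lasts 10 minutes at TR = 0.8 s and interleaves
three 51-s rest blocks with six 26-s focused-attention meditation blocks:
rest - (cue, meditation, feedback) x3 - rest - (cue, meditation, feedback) x3
- rest.  Cue and feedback durations are not part of the mandated structure
and default to 3 s and 10 s; whatever run time remains is distributed as
equal unmodelled gaps after each feedback block so the final rest block ends
exactly at the end of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hrf

REST = "rest"
MEDITATION = "meditation"
CUE = "cue"
FEEDBACK = "feedback"

REST_DURATION_S = 51.0
MEDITATION_DURATION_S = 26.0
N_REST = 3
N_MEDITATION = 6


class DesignSizingError(ValueError):
    """Raised when a run is too short to hold the mandated blocks."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Scan timing for one NF session.

    ``run_length_seconds`` need not be an exact multiple of ``tr_seconds``;
    the number of volumes is the floor of their ratio.
    """

    tr_seconds: float = 0.8
    run_length_seconds: float = 600.0
    n_runs_per_session: int = 3
    n_sessions: int = 2

    def __post_init__(self):
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.run_length_seconds <= 0:
            raise ValueError("run_length_seconds must be positive")
        if self.n_runs_per_session < 1 or self.n_sessions < 1:
            raise ValueError("run/session counts must be >= 1")

    @property
    def n_volumes(self) -> int:
        # tolerance guards against binary floating point (600/0.8 is exactly 750)
        return int(np.floor(self.run_length_seconds / self.tr_seconds + 1e-9))


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    condition: str


@dataclass
class BlockDesign:
    """Sorted, non-overlapping events of one NF run."""

    events: list = field(default_factory=list)
    run_length_seconds: float = 600.0

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(self.events, self.events[1:]):
            if a.onset + a.duration > b.onset + 1e-9:
                raise ValueError(
                    f"overlapping events: {a.condition}@{a.onset}s and {b.condition}@{b.onset}s"
                )
        n_rest = len(self.of_condition(REST))
        n_med = len(self.of_condition(MEDITATION))
        if n_rest != N_REST or n_med != N_MEDITATION:
            raise ValueError(
                f"an NF run needs {N_REST} rest and {N_MEDITATION} meditation blocks, "
                f"got {n_rest} and {n_med}"
            )

    def of_condition(self, condition: str) -> list:
        return [e for e in self.events if e.condition == condition]

    def regressor(self, condition: str, n_volumes: int, tr: float,
                  convolve: bool = True) -> np.ndarray:
        ev = self.of_condition(condition)
        onsets = [e.onset for e in ev]
        durations = [e.duration for e in ev]
        if convolve:
            return hrf.convolved_regressor(onsets, durations, n_volumes, tr)
        return hrf.boxcar(onsets, durations, n_volumes, tr)

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type; seconds)."""
        return pd.DataFrame(
            {
                "onset": [e.onset for e in self.events],
                "duration": [e.duration for e in self.events],
                "trial_type": [e.condition for e in self.events],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, run_length_seconds: float) -> "BlockDesign":
        required = {"onset", "duration", "trial_type"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        events = [
            Event(float(r.onset), float(r.duration), str(r.trial_type))
            for r in frame.itertuples()
        ]
        return cls(events=events, run_length_seconds=run_length_seconds)


def make_block_design(acquisition: AcquisitionParams, cue_s: float = 3.0,
                      feedback_s: float = 10.0) -> BlockDesign:
    """Build the blocked NF-run design for the given acquisition.

    Raises
    ------
    DesignSizingError
        If the mandated blocks plus cue/feedback do not fit in the run,
        naming the deficit in seconds.
    """
    if cue_s < 0 or feedback_s < 0:
        raise ValueError("cue_s and feedback_s must be >= 0")
    mandated = (
        N_REST * REST_DURATION_S
        + N_MEDITATION * (cue_s + MEDITATION_DURATION_S + feedback_s)
    )
    slack = acquisition.run_length_seconds - mandated
    if slack < 0:
        raise DesignSizingError(
            f"run of {acquisition.run_length_seconds:g} s is {-slack:g} s too short "
            f"for the mandated blocks ({mandated:g} s)"
        )
    gap = slack / N_MEDITATION  # unmodelled gap after each feedback block
    events = []
    t = 0.0
    for half in range(2):
        events.append(Event(t, REST_DURATION_S, REST))
        t += REST_DURATION_S
        for _ in range(3):
            if cue_s > 0:
                events.append(Event(t, cue_s, CUE))
            t += cue_s
            events.append(Event(t, MEDITATION_DURATION_S, MEDITATION))
            t += MEDITATION_DURATION_S
            if feedback_s > 0:
                events.append(Event(t, feedback_s, FEEDBACK))
            t += feedback_s + gap
    events.append(Event(t, REST_DURATION_S, REST))
    return BlockDesign(events=events, run_length_seconds=acquisition.run_length_seconds)
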