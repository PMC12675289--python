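"""Shared containers for behavioural logs, cohorts, photometry and traces.

All containers are thin wrappers over pandas/numpy with validation on
construction and plain-text round-trip I/O (CSV), so every pipeline stage can
be run from files as well as in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vocab

BOUT_COLUMNS = ["behaviour", "onset_s", "offset_s"]
EVENTLOG_CSV_COLUMNS = ["session_id", "subject_id", "behaviour", "onset_s", "offset_s"]


@dataclass
class EventLog:
    """Timed behavioural bouts for one session.

    Bouts are kept sorted by (onset, offset, label); labels must come from the
    declared vocabulary and bouts must lie inside ``[0, assay_duration]``.
    """

    session_id: str
    subject_id: str
    bouts: pd.DataFrame  # columns: behaviour, onset_s, offset_s
    assay_duration: float = vocab.DEFAULT_ASSAY_DURATION_S
    vocabulary: frozenset = vocab.VOCABULARY

    def __post_init__(self) -> None:
        b = pd.DataFrame(self.bouts, columns=BOUT_COLUMNS).reset_index(drop=True)
        if len(b):
            unknown = set(b["behaviour"]) - set(self.vocabulary)
            if unknown:
                raise ValueError(f"unknown behaviour labels: {sorted(unknown)}")
            if (b["onset_s"] < 0).any() or (b["offset_s"] > self.assay_duration).any():
                raise ValueError("bout outside [0, assay_duration]")
            if (b["onset_s"] >= b["offset_s"]).any():
                raise ValueError("bout with onset >= offset")
            # deterministic order: onset, then offset, then label
            b = b.sort_values(
                ["onset_s", "offset_s", "behaviour"], kind="mergesort"
            ).reset_index(drop=True)
        self.bouts = b

    def __len__(self) -> int:
        return len(self.bouts)

    def filtered(self, labels) -> "EventLog":
        """Return a copy keeping only bouts whose label is in ``labels``."""
        keep = self.bouts[self.bouts["behaviour"].isin(set(labels))]
        return EventLog(
            self.session_id, self.subject_id, keep, self.assay_duration, self.vocabulary
        )

    def first_onset(self, labels) -> float | None:
        """Onset of the earliest bout with a label in ``labels``, or None."""
        sel = self.bouts[self.bouts["behaviour"].isin(set(labels))]
        return None if sel.empty else float(sel["onset_s"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.bouts.copy()
        out.insert(0, "subject_id", self.subject_id)
        out.insert(0, "session_id", self.session_id)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, assay_duration=vocab.DEFAULT_ASSAY_DURATION_S,
                 vocabulary=vocab.VOCABULARY) -> list["EventLog"]:
        """Read one or more sessions from a BORIS-style export CSV."""
        df = pd.read_csv(path)
        missing = set(EVENTLOG_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"event-log CSV missing columns: {sorted(missing)}")
        logs = []
        for (sid, sub), grp in df.groupby(["session_id", "subject_id"], sort=True):
            logs.append(
                cls(str(sid), str(sub), grp[BOUT_COLUMNS], assay_duration, vocabulary)
            )
        return logs


def write_event_logs(logs, path) -> None:
    pd.concat([lg.to_frame() for lg in logs], ignore_index=True).to_csv(path, index=False)


COHORT_COLUMNS = ["subject_id", "stage", "aggressive"]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table (subject_id, stage, aggressive[, p4, e2])."""
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad = set(table["stage"]) - set(vocab.STAGES)
    if bad:
        raise ValueError(f"unknown oestrous stages: {sorted(bad)}")
    if not table["aggressive"].isin([0, 1]).all():
        raise ValueError("aggressive must be binary 0/1")
    return table.reset_index(drop=True)


@dataclass
class PhotometryRecording:
    """Interleaved two-channel photometry sample stream.

    ``samples`` columns: sample_index, channel (isosbestic_415 | activity_470),
    value. Channels must strictly alternate in sample_index order.
    """

    samples: pd.DataFrame
    rate_hz: float = vocab.DEFAULT_FRAME_RATE_HZ  # per-channel effective rate

    CH_ISO = "isosbestic_415"
    CH_ACT = "activity_470"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.samples, columns=["sample_index", "channel", "value"])
        df = df.sort_values("sample_index", kind="mergesort").reset_index(drop=True)
        bad = set(df["channel"]) - {self.CH_ISO, self.CH_ACT}
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)}")
        self.samples = df

    def __len__(self) -> int:
        return len(self.samples)

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rate_hz=vocab.DEFAULT_FRAME_RATE_HZ) -> "PhotometryRecording":
        return cls(pd.read_csv(path), rate_hz)


@dataclass
class TraceMatrix:
    """Neurons x frames ΔF/F matrix with a uniform frame clock.

    ``condition`` is Pre/Post food deprivation; ``outcome`` the behavioural
    classification of the animal, both optional metadata.
    """

    frame_times: np.ndarray  # seconds, strictly increasing
    dff: np.ndarray  # (n_neurons, n_frames)
    neuron_ids: list[str] = field(default_factory=list)
    subject_id: str = ""
    condition: str = ""  # {"Pre", "Post", ""}
    outcome: str = ""  # {"agg_plus", "agg_minus", ""}

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if self.dff.shape[1] != self.frame_times.size:
            raise ValueError("dff column count must match frame_times length")
        if self.frame_times.size >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.isnan(self.dff).any():
            raise ValueError("missing frames (NaN) in dff")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:04d}" for i in range(self.dff.shape[0])]
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron identifiers must be unique")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def frame_rate(self) -> float:
        dt = np.diff(self.frame_times)
        return float(1.0 / np.median(dt)) if dt.size else float("nan")

    def frame_index(self, t: float) -> int:
        """Nearest-frame index for time ``t`` (round-half-even on the grid)."""
        rel = (t - self.frame_times[0]) * self.frame_rate
        idx = int(np.round(rel))  # numpy rounds half to even
        return min(max(idx, 0), self.n_frames - 1)

    def to_csv(self, path) -> None:
        """Row 1 = frame times; each subsequent row = one neuron."""
        mat = np.vstack([self.frame_times, self.dff])
        index = ["frame_time_s"] + list(self.neuron_ids)
        pd.DataFrame(mat, index=index).to_csv(path, header=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "TraceMatrix":
        raw = pd.read_csv(path, header=None, index_col=0)
        if raw.index[0] != "frame_time_s":
            raise ValueError("first row of a trace CSV must be frame_time_s")
        return cls(
            raw.iloc[0].to_numpy(float),
            raw.iloc[1:].to_numpy(float),
            neuron_ids=[str(i) for i in raw.index[1:]],
            **meta,
        )


def warn(msg: str) -> None:
    """Package-wide soft-failure channel (UserWarning)."""
    warnings.warn(msg, UserWarning, stacklevel=3)
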