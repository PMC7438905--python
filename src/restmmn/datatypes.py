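"""Core domain types: recordings, event lists, frequency bands, result tables.

All signals are stored in microvolts, channels x samples, with channel labels
from the 10-20 system. Event onsets are stored in seconds; at the native
500 Hz sampling rate one sample is 2 ms, and conversion to sample indices
rounds to the nearest sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "BANDS",
    "BAND_ORDER",
    "EventList",
    "Recording",
    "CohortResultTable",
    "ValidationError",
    "CONDITIONS",
]


class ValidationError(ValueError):
    """An input violated a structural invariant (labels, onsets, shapes)."""


CONDITIONS = ("standard", "deviant")


class Band(NamedTuple):
    """A closed-open frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float


#: Canonical analysis bands. Adjacent bands share a printed edge frequency;
#: the half-open convention ensures no spectral bin is counted twice.
BANDS: dict[str, Band] = {
    "delta": Band("delta", 1.0, 4.0),
    "theta": Band("theta", 4.0, 8.0),
    "alpha": Band("alpha", 8.0, 13.0),
    "beta": Band("beta", 13.0, 30.0),
    "gamma": Band("gamma", 30.0, 60.0),
}

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")


def get_band(band: "Band | str") -> Band:
    if isinstance(band, Band):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValidationError(
            f"unknown band {band!r}; known bands: {sorted(BANDS)}"
        ) from None


@dataclass(frozen=True)
class EventList:
    """Stimulus events: onset (s), condition, stimulus duration (ms)."""

    onsets: np.ndarray
    conditions: np.ndarray
    durations_ms: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        conditions = np.asarray(self.conditions, dtype=object)
        durations = np.asarray(self.durations_ms, dtype=float)
        if not (len(onsets) == len(conditions) == len(durations)):
            raise ValidationError("event columns have mismatched lengths")
        if len(onsets) and np.any(np.diff(onsets) <= 0):
            raise ValidationError("event onsets must be strictly increasing")
        unknown = set(conditions) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown condition labels: {sorted(unknown)}")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "conditions", conditions)
        object.__setattr__(self, "durations_ms", durations)

    def __len__(self) -> int:
        return len(self.onsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "condition": self.conditions,
                "duration_ms": self.durations_ms,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventList":
        required = {"onset_s", "condition", "duration_ms"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"event table missing columns: {sorted(missing)}")
        return cls(
            onsets=df["onset_s"].to_numpy(dtype=float),
            conditions=df["condition"].to_numpy(dtype=object),
            durations_ms=df["duration_ms"].to_numpy(dtype=float),
        )


@dataclass
class Recording:
    """A multichannel EEG recording, channels x samples, in microvolts.

    Parameters
    ----------
    signal
        Array of shape ``(n_channels, n_samples)``, microvolts.
    fs
        Sampling rate in Hz (500 Hz in the emulated acquisition).
    channel_labels
        Unique 10-20 channel names, one per signal row.
    reference
        Label of the online reference electrode (FCz in the emulated setup).
    events
        Optional stimulus events for oddball sessions.
    """

    signal: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    reference: str = "FCz"
    events: Optional[EventList] = None
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        self.channel_labels = list(self.channel_labels)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            seen, dupes = set(), set()
            for lab in self.channel_labels:
                (dupes if lab in seen else seen).add(lab)
            raise ValidationError(f"duplicate channel labels: {sorted(dupes)}")
        if self.events is not None and len(self.events):
            if self.events.onsets[0] < 0 or self.events.onsets[-1] >= self.duration_s:
                raise ValidationError(
                    "event onsets must lie within [0, recording duration)"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"channel {label!r} not in recording "
                f"(available: {self.channel_labels})"
            ) from None

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Return a copy restricted to ``labels`` (in the given order)."""
        idx = [self.channel_index(lab) for lab in labels]
        return replace(self, signal=self.signal[idx], channel_labels=list(labels))


#: Fixed column order of the cohort result table.
RESULT_COLUMNS = (
    "subject_id",
    "group",
    "band",
    "C",
    "L",
    "mmn_latency_ms",
    "mmn_amplitude_uv",
)


@dataclass
class CohortResultTable:
    """Tidy per-subject, per-band results feeding the statistics stage.

    One row per subject x band carries the network metrics (C, L); the MMN
    latency/amplitude columns repeat the subject's single ERP measurement on
    every band row.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame)
        missing = set(RESULT_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"result table missing columns: {sorted(missing)}")
        df = df.loc[:, list(RESULT_COLUMNS)]
        if len(df):
            bad = set(df["band"]) - set(BANDS)
            if bad:
                raise ValidationError(f"unknown band names in table: {sorted(bad)}")
            dup = df.duplicated(["subject_id", "band"])
            if dup.any():
                raise ValidationError("duplicate (subject, band) rows in result table")
            # MMN values must be constant within a subject
            per_subj = df.groupby("subject_id")[["mmn_latency_ms", "mmn_amplitude_uv"]].nunique()
            if (per_subj > 1).any().any():
                raise ValidationError("MMN fields differ across a subject's band rows")
            band_rank = {b: i for i, b in enumerate(BAND_ORDER)}
            df = df.sort_values(
                ["subject_id", "band"], key=lambda s: s.map(band_rank) if s.name == "band" else s
            ).reset_index(drop=True)
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())
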