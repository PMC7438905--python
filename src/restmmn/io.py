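"""Readers and writers for recordings, events and result tables.

The native interchange format is a flat little-endian float64 matrix
(``<stem>.dat``) with a JSON sidecar (``<stem>.json``) carrying sampling
rate, channel labels, reference and units; EDF is supported read-only for
interoperability. Events travel as TSV (onset_s, condition, duration_ms)
and result tables as CSV with a fixed column order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datatypes import (
    RESULT_COLUMNS,
    CohortResultTable,
    EventList,
    Recording,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_results",
    "write_results",
]

SIDECAR_SUFFIX = ".json"
DATA_SUFFIX = ".dat"
EVENTS_SUFFIX = "_events.tsv"


def _stem(path: Union[str, Path]) -> Path:
    path = Path(path)
    if path.suffix in (DATA_SUFFIX, SIDECAR_SUFFIX):
        return path.with_suffix("")
    return path


def write_recording(rec: Recording, path: Union[str, Path]) -> Path:
    """Write ``rec`` in the matrix+sidecar format; returns the sidecar path.

    Produces ``<stem>.dat`` (float64, C order), ``<stem>.json`` and, when
    events are attached, ``<stem>_events.tsv``.
    """
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(rec.signal, dtype="<f8")
    data.tofile(stem.with_suffix(DATA_SUFFIX))
    sidecar = {
        "format": "restmmn-matrix-v1",
        "units": "uV",
        "fs_hz": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_labels": list(rec.channel_labels),
        "reference": rec.reference,
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
    }
    sidecar_path = stem.with_suffix(SIDECAR_SUFFIX)
    sidecar_path.write_text(json.dumps(sidecar, indent=1) + "\n")
    if rec.events is not None:
        write_events(rec.events, stem.parent / (stem.name + EVENTS_SUFFIX))
    return sidecar_path


def _read_matrix(stem: Path) -> Recording:
    sidecar_path = stem.with_suffix(SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    for key in ("fs_hz", "n_channels", "n_samples", "channel_labels"):
        if key not in meta:
            raise ValidationError(f"sidecar {sidecar_path} missing field {key!r}")
    data_path = stem.with_suffix(DATA_SUFFIX)
    raw = np.fromfile(data_path, dtype="<f8")
    n_ch, n_samp = int(meta["n_channels"]), int(meta["n_samples"])
    if raw.size != n_ch * n_samp:
        raise ValidationError(
            f"{data_path}: expected {n_ch}x{n_samp} values, found {raw.size}"
        )
    scale = {"uV": 1.0, "mV": 1e3, "V": 1e6}.get(meta.get("units", "uV"))
    if scale is None:
        raise ValidationError(f"unknown units {meta['units']!r} in {sidecar_path}")
    events = None
    events_path = stem.parent / (stem.name + EVENTS_SUFFIX)
    if events_path.exists():
        events = read_events(events_path)
    return Recording(
        signal=raw.reshape(n_ch, n_samp) * scale,
        fs=float(meta["fs_hz"]),
        channel_labels=meta["channel_labels"],
        reference=meta.get("reference", "FCz"),
        events=events,
        subject_id=meta.get("subject_id", ""),
        group_label=meta.get("group_label", ""),
    )


def _read_edf(path: Path) -> Recording:
    # mne reads EDF in volts; internal unit is microvolts.
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    events = None
    events_path = path.parent / (path.stem + EVENTS_SUFFIX)
    if events_path.exists():
        events = read_events(events_path)
    return Recording(
        signal=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def read_recording(path: Union[str, Path], format: Optional[str] = None) -> Recording:
    """Read a recording from EDF or the native matrix+sidecar format.

    ``format`` may be ``"edf"`` or ``"matrix"``; by default it is inferred
    from the file suffix. A sibling ``<stem>_events.tsv`` is attached as the
    recording's event list when present.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_edf(path)
    if format == "matrix":
        return _read_matrix(_stem(path))
    raise ValueError(f"unknown recording format {format!r}")


def write_events(events: EventList, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events(path: Union[str, Path]) -> EventList:
    df = pd.read_csv(path, sep="\t")
    return EventList.from_frame(df)


def write_results(table: CohortResultTable, path: Union[str, Path]) -> Path:
    """Write a cohort result table as CSV with the documented column order.

    Rows are ordered deterministically by (subject, band); an empty table is
    an error.
    """
    if len(table) == 0:
        raise ValidationError("refusing to write an empty result table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False, columns=list(RESULT_COLUMNS))
    return path


def read_results(path: Union[str, Path]) -> CohortResultTable:
    return CohortResultTable(pd.read_csv(path))
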