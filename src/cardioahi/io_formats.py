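"""Reading and writing of recordings, annotations and pipeline outputs.

ECG is accepted as EDF (European Data Format, one channel selected by
label). Respiratory-event annotations use a plain CSV schema
(``kind,onset_s,duration_s,desaturation_pct,arousal``) because no standard
interchange format for respiratory events exists across public sleep
datasets. Hypnograms are one stage token per line (``wake``/``sleep``).
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EPOCH_SECONDS = 30.0
EVENT_KINDS = ("obstructive_apnea", "hypopnea", "central_apnea", "mixed_apnea")

ANNOTATION_COLUMNS = ["kind", "onset_s", "duration_s", "desaturation_pct", "arousal"]


class SchemaError(ValueError):
    """An annotation table violates the expected schema."""


@dataclass
class ECGRecord:
    """A single-lead ECG trace.

    Attributes
    ----------
    samples : ndarray
        Amplitude series in arbitrary units.
    sampling_rate : float
        Sampling frequency in Hz (> 0).
    record_id : str
        Identifier of the recording.
    """

    samples: np.ndarray
    sampling_rate: float
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def n_epochs(self) -> int:
        return int(self.duration // EPOCH_SECONDS)


@dataclass
class RespiratoryEvent:
    """A scored respiratory event.

    ``desaturation`` (percent) and ``arousal`` may be absent (``None``)
    when the source dataset does not provide event characteristics.
    """

    kind: str
    onset: float
    duration: float
    desaturation: Optional[float] = None
    arousal: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SchemaError(f"unknown respiratory event kind: {self.kind!r}")
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")
        if self.duration < 10.0:
            raise ValueError("respiratory events are scored with duration >= 10 s")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class SleepWakeSequence:
    """Per-30-s-epoch sleep/wake staging collapsed to two classes."""

    stages: np.ndarray  # array of "sleep"/"wake" tokens
    epoch_length: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        stages = np.asarray(self.stages, dtype=object)
        bad = set(stages) - {"sleep", "wake"}
        if bad:
            raise SchemaError(f"unknown sleep stages: {sorted(bad)}")
        self.stages = stages

    def __len__(self) -> int:
        return self.stages.size

    @property
    def is_sleep(self) -> np.ndarray:
        return self.stages == "sleep"


# ---------------------------------------------------------------------------
# EDF reading / writing (minimal, single-channel oriented)
# ---------------------------------------------------------------------------

_EDF_HEADER = struct.Struct("<8s80s80s8s8s8s44s8s8s4s")


def write_edf(path, record: ECGRecord, channel_label: str = "ECG") -> None:
    """Write a one-channel EDF file (16-bit, one data record per second)."""
    fs = record.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    x = np.asarray(record.samples, dtype=float)
    n_rec = int(np.ceil(x.size / fs)) if x.size else 0
    pad = n_rec * fs - x.size
    if pad:
        x = np.concatenate([x, np.zeros(pad)])
    phys_min, phys_max = float(x.min(initial=-1.0)), float(x.max(initial=1.0))
    if phys_max <= phys_min:
        phys_max = phys_min + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + dig_min).astype("<i2")

    def pad_field(value, width):
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(pad_field("0", 8))
        fh.write(pad_field(record.record_id, 80))
        fh.write(pad_field("Startdate X X X X", 80))
        fh.write(pad_field("01.01.00", 8))
        fh.write(pad_field("00.00.00", 8))
        fh.write(pad_field(256 + 256, 8))  # header bytes: fixed + 1 signal
        fh.write(pad_field("", 44))
        fh.write(pad_field(n_rec, 8))
        fh.write(pad_field(1, 8))  # record duration, seconds
        fh.write(pad_field(1, 4))  # number of signals
        fh.write(pad_field(channel_label, 16))
        fh.write(pad_field("", 80))  # transducer
        fh.write(pad_field("uV", 8))
        fh.write(pad_field(f"{phys_min:.6g}", 8))
        fh.write(pad_field(f"{phys_max:.6g}", 8))
        fh.write(pad_field(dig_min, 8))
        fh.write(pad_field(dig_max, 8))
        fh.write(pad_field("", 80))  # prefiltering
        fh.write(pad_field(fs, 8))  # samples per record
        fh.write(pad_field("", 32))
        fh.write(digital.tobytes())


def read_edf(path, channel: Optional[str] = None) -> ECGRecord:
    """Read one channel from an EDF file.

    Parameters
    ----------
    path : path-like
        EDF file.
    channel : str, optional
        Channel label to extract; defaults to the first channel.
    """
    path = Path(path)
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise IOError(f"cannot read ECG file {path}: {exc}") from exc
    if len(data) < 256:
        raise IOError(f"cannot read ECG file {path}: truncated EDF header")

    def fld(offset, width, cast=str):
        raw = data[offset:offset + width].decode("ascii", "replace").strip()
        return cast(raw) if raw else cast("0")

    record_id = data[8:88].decode("ascii", "replace").strip() or path.stem
    n_records = fld(236, 8, int)
    rec_dur = fld(244, 8, float)
    n_signals = fld(252, 4, int)
    if n_signals < 1:
        raise IOError(f"cannot read ECG file {path}: no signals")
    off = 256
    labels = [data[off + 16 * i:off + 16 * (i + 1)].decode("ascii", "replace").strip()
              for i in range(n_signals)]
    off += n_signals * (16 + 80 + 8)
    phys_min = [float(data[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_signals)]
    off += n_signals * 8
    phys_max = [float(data[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_signals)]
    off += n_signals * 8
    dig_min = [int(data[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_signals)]
    off += n_signals * 8
    dig_max = [int(data[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_signals)]
    off += n_signals * 8 + n_signals * 80
    spr = [int(data[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_signals)]

    if channel is None:
        idx = 0
    else:
        try:
            idx = labels.index(channel)
        except ValueError:
            raise IOError(
                f"cannot read ECG file {path}: channel {channel!r} not in {labels}")
    header_bytes = fld(184, 8, int)
    body = np.frombuffer(data, dtype="<i2", offset=header_bytes)
    rec_len = sum(spr)
    body = body[: n_records * rec_len].reshape(n_records, rec_len)
    start = sum(spr[:idx])
    digital = body[:, start:start + spr[idx]].reshape(-1).astype(float)
    g = (phys_max[idx] - phys_min[idx]) / (dig_max[idx] - dig_min[idx])
    samples = (digital - dig_min[idx]) * g + phys_min[idx]
    fs = spr[idx] / rec_dur
    return ECGRecord(samples=samples, sampling_rate=fs, record_id=record_id)


# ---------------------------------------------------------------------------
# Annotation / hypnogram tables
# ---------------------------------------------------------------------------

def read_events(path) -> list[RespiratoryEvent]:
    """Read respiratory events from the CSV annotation schema."""
    try:
        table = pd.read_csv(path)
    except OSError as exc:
        raise IOError(f"cannot read annotation file {path}: {exc}") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"annotation file {path} lacks columns {missing}")
    events = []
    for i, row in table.iterrows():
        kind = str(row["kind"])
        if kind not in EVENT_KINDS:
            raise SchemaError(
                f"annotation row {i} of {path}: unknown event kind {kind!r}")
        desat = row["desaturation_pct"]
        arousal = row["arousal"]
        events.append(RespiratoryEvent(
            kind=kind,
            onset=float(row["onset_s"]),
            duration=float(row["duration_s"]),
            desaturation=None if pd.isna(desat) else float(desat),
            arousal=None if pd.isna(arousal) else bool(arousal),
        ))
    return events


def write_events(path, events: Sequence[RespiratoryEvent]) -> None:
    rows = [{
        "kind": e.kind, "onset_s": e.onset, "duration_s": e.duration,
        "desaturation_pct": np.nan if e.desaturation is None else e.desaturation,
        "arousal": np.nan if e.arousal is None else e.arousal,
    } for e in events]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_hypnogram(path) -> SleepWakeSequence:
    """Read a one-token-per-line sleep/wake hypnogram."""
    try:
        tokens = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    except OSError as exc:
        raise IOError(f"cannot read hypnogram file {path}: {exc}") from exc
    return SleepWakeSequence(np.array(tokens, dtype=object))


def write_hypnogram(path, stages: SleepWakeSequence) -> None:
    Path(path).write_text("\n".join(stages.stages) + "\n")


def read_recording(ecg_path, annotation_path, hypnogram_path=None,
                   channel: Optional[str] = None):
    """Load an ECG recording with its respiratory events and hypnogram.

    Returns ``(ECGRecord, events, SleepWakeSequence)`` with events sorted
    by onset. When no hypnogram is given, all epochs are assumed asleep.
    """
    ecg = read_edf(ecg_path, channel=channel)
    events = sorted(read_events(annotation_path), key=lambda e: e.onset)
    n_epochs = ecg.n_epochs
    if hypnogram_path is None:
        stages = SleepWakeSequence(np.array(["sleep"] * n_epochs, dtype=object))
    else:
        stages = read_hypnogram(hypnogram_path)
        if len(stages) != n_epochs:
            raise SchemaError(
                f"hypnogram length {len(stages)} != epoch count {n_epochs}")
    return ecg, events, stages


# ---------------------------------------------------------------------------
# Dataset-harmonisation rules
# ---------------------------------------------------------------------------

def harmonise_hypopneas(events: Sequence[RespiratoryEvent],
                        missing_policy: str = "keep") -> list[RespiratoryEvent]:
    """Drop hypopneas scored with <4% desaturation and no arousal.

    Datasets scored with a 3% desaturation rule include mild hypopneas
    that a 4% rule would not; removing hypopneas with desaturation < 4%
    that were not followed by an arousal harmonises the scoring. Events
    of other kinds pass through unchanged, order preserved.

    Parameters
    ----------
    missing_policy : {"keep", "drop"}
        What to do with hypopneas lacking both desaturation and arousal
        information. The default keeps them with a warning (public
        minute-annotated datasets provide no event characteristics).
    """
    if missing_policy not in ("keep", "drop"):
        raise ValueError("missing_policy must be 'keep' or 'drop'")
    out = []
    for e in events:
        if e.kind != "hypopnea":
            out.append(e)
            continue
        if e.desaturation is None and e.arousal is None:
            warnings.warn(
                "hypopnea without desaturation or arousal information; "
                f"policy={missing_policy}", stacklevel=2)
            if missing_policy == "keep":
                out.append(e)
            continue
        arousal = bool(e.arousal) if e.arousal is not None else False
        desat = e.desaturation if e.desaturation is not None else 0.0
        if not arousal and desat < 4.0:
            continue
        out.append(e)
    return out


def split_minute_labels(labels60) -> np.ndarray:
    """Split per-60-s labels into per-30-s labels by duplication."""
    arr = np.asarray(labels60)
    return np.repeat(arr, 2)


# ---------------------------------------------------------------------------
# Pipeline outputs
# ---------------------------------------------------------------------------

def write_epoch_predictions(path, probabilities, labels) -> None:
    """Per-epoch probability/label CSV export."""
    pd.DataFrame({
        "epoch_index": np.arange(len(probabilities)),
        "re_probability": probabilities,
        "re_class": np.asarray(labels).astype(int),
    }).to_csv(path, index=False)


def write_ahi_report(path, estimate) -> None:
    """AHI estimate JSON export (accepts a modelling.AHIEstimate)."""
    payload = {
        "record_id": estimate.record_id,
        "n_analysable_epochs": int(estimate.n_analysable_epochs),
        "n_detected_re_epochs": int(estimate.n_detected_re_epochs),
        "ahi_pred": float(estimate.ahi_pred),
        "severity": estimate.severity,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
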