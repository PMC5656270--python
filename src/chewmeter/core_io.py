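"""Domain types and file I/O for jaw-motion sensor recordings and annotations.

The package works on single-channel voltage time series recorded by a
piezoelectric film sensor placed below the ear, together with human
annotations of chewing sequences (start/end time, intake vs. non-intake,
and a reference chew count for each chewing sequence).

Conventions
-----------
* Annotation times are seconds (floats) on half-open intervals
  ``[start_s, end_s)``; sample ``i`` belongs to a segment iff
  ``start_s <= i / fs < end_s``.
* WAV full-scale amplitude is mapped linearly onto a configurable voltage
  range, default 0–2 V (the amplifier's output range).  Counting is
  scale-invariant, so the mapping only affects display.
* Annotation files are UTF-8 CSV with header
  ``subject_id,visit_id,start_s,end_s,label,chew_count``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

INTAKE = "intake"
NON_INTAKE = "non-intake"

ANNOTATION_COLUMNS = ["subject_id", "visit_id", "start_s", "end_s", "label", "chew_count"]

#: Default linear mapping of WAV full scale onto volts.
DEFAULT_VOLT_RANGE: Tuple[float, float] = (0.0, 2.0)


@dataclass
class SensorSignal:
    """A single-channel jaw-motion voltage recording.

    Parameters
    ----------
    samples : ndarray
        Voltage samples.
    fs : float
        Sampling rate in Hz, > 0.
    subject_id, visit_id : str
        Identity of the recording.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    visit_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("SensorSignal requires a 1-D sample array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "SensorSignal":
        return SensorSignal(samples, self.fs, self.subject_id, self.visit_id)

    def sample_slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples in the half-open interval [start_s, end_s).

        Index arithmetic is tolerant to float representation of times that
        are exact sample multiples.
        """
        i0 = int(math.ceil(start_s * self.fs - 1e-9))
        i1 = int(math.ceil(end_s * self.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.samples))
        return self.samples[i0:i1]


@dataclass
class ChewSegment:
    """One annotated segment: a chewing sequence or a non-intake period.

    ``chew_count`` is the human-annotated reference count CNT(k) and is only
    present for intake segments.
    """

    start_s: float
    end_s: float
    label: str = INTAKE
    chew_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(
                f"segment end ({self.end_s}) must exceed start ({self.start_s})"
            )
        if self.start_s < 0:
            raise ValueError("segment start must be >= 0")
        if self.label not in (INTAKE, NON_INTAKE):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == NON_INTAKE and self.chew_count is not None:
            raise ValueError("chew_count only allowed on intake segments")
        if self.chew_count is not None and self.chew_count < 0:
            raise ValueError("chew_count must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_intake(self) -> bool:
        return self.label == INTAKE


@dataclass
class VisitSummary:
    """Per-visit aggregates.

    ``acnt``/``acr`` are the annotated cumulative chew count and mean
    chewing rate; ``ecnt``/``ecr`` are their algorithm estimates.
    """

    subject_id: str = ""
    visit_id: str = ""
    n_sequences: int = 0
    acnt: int = 0
    acr: float = 0.0
    ecnt: int = 0
    ecr: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_sequences, self.acnt, self.ecnt) < 0:
            raise ValueError("counts must be non-negative")
        if min(self.acr, self.ecr) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class ErrorReport:
    """Per-visit percent errors of estimated vs. annotated chew counts."""

    per_visit_signed: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_visit_abs: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_signed: float = 0.0
    mean_abs: float = 0.0
    std_signed: float = 0.0
    std_abs: float = 0.0
    n_visits: int = 0
    ci95_signed: Tuple[float, float] = (0.0, 0.0)


VisitKey = Tuple[str, str]


def read_signal(
    path,
    fs_override: Optional[float] = None,
    volt_range: Tuple[float, float] = DEFAULT_VOLT_RANGE,
) -> SensorSignal:
    """Read a mono WAV or raw float32 recording into a :class:`SensorSignal`.

    WAV amplitudes (full scale) are mapped linearly onto ``volt_range``.
    A raw ``.bin``/``.raw``/``.f32`` file must be accompanied by a JSON
    sidecar ``<path>.json`` declaring at least ``fs``; samples are taken
    to already be volts.  Subject/visit ids come from the sidecar if
    present, else from the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError("multi-channel WAV unsupported; mono required")
        if data.dtype == np.int16:
            norm = data.astype(float) / 32768.0
        elif data.dtype == np.int32:
            norm = data.astype(float) / 2147483648.0
        elif data.dtype in (np.float32, np.float64):
            norm = data.astype(float)
        else:
            raise ValueError(f"unsupported WAV sample format {data.dtype}")
        lo, hi = meta.get("volt_range", volt_range)
        volts = (norm + 1.0) / 2.0 * (hi - lo) + lo
    else:
        if not meta:
            raise ValueError(f"raw input {path} requires a JSON sidecar {sidecar}")
        if "fs" not in meta:
            raise ValueError("sidecar must declare 'fs'")
        fs = meta["fs"]
        volts = np.fromfile(path, dtype=np.float32).astype(float)

    fs = float(fs_override if fs_override is not None else fs)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    return SensorSignal(
        volts,
        fs,
        subject_id=str(meta.get("subject_id", path.stem)),
        visit_id=str(meta.get("visit_id", path.stem)),
    )


def write_signal(
    path,
    signal: SensorSignal,
    volt_range: Tuple[float, float] = DEFAULT_VOLT_RANGE,
) -> None:
    """Write a signal as float32 WAV (volts mapped back to full scale)."""
    path = Path(path)
    lo, hi = volt_range
    norm = (signal.samples - lo) / (hi - lo) * 2.0 - 1.0
    wavfile.write(path, int(round(signal.fs)), norm.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "fs": signal.fs,
                "subject_id": signal.subject_id,
                "visit_id": signal.visit_id,
                "volt_range": [lo, hi],
            }
        )
    )


def _check_visit(segments: List[ChewSegment]) -> List[ChewSegment]:
    segments = sorted(segments, key=lambda s: s.start_s)
    for a, b in zip(segments, segments[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise ValueError(
                f"overlapping annotation: [{a.start_s}, {a.end_s}) and "
                f"[{b.start_s}, {b.end_s})"
            )
    return segments


def read_annotations(path) -> Dict[VisitKey, List[ChewSegment]]:
    """Read an annotations CSV, grouped by (subject_id, visit_id).

    Rows are sorted by start time and checked for overlap within each visit.
    ``chew_count`` must be empty for non-intake rows.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "visit_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    visits: Dict[VisitKey, List[ChewSegment]] = {}
    for row in df.itertuples(index=False):
        count = row.chew_count
        count = None if pd.isna(count) else int(count)
        seg = ChewSegment(
            start_s=float(row.start_s),
            end_s=float(row.end_s),
            label=str(row.label),
            chew_count=count,
        )
        visits.setdefault((row.subject_id, row.visit_id), []).append(seg)
    return {key: _check_visit(segs) for key, segs in visits.items()}


def write_annotations(path, visits: Dict[VisitKey, List[ChewSegment]]) -> None:
    rows = []
    for (subject_id, visit_id), segments in visits.items():
        for seg in segments:
            rows.append(
                {
                    "subject_id": subject_id,
                    "visit_id": visit_id,
                    "start_s": seg.start_s,
                    "end_s": seg.end_s,
                    "label": seg.label,
                    "chew_count": "" if seg.chew_count is None else seg.chew_count,
                }
            )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def annotated_summary(segments: Sequence[ChewSegment]) -> Tuple[int, float, int]:
    """ACNT, ACR and N for one visit's annotations.

    ACNT is the sum of the reference counts CNT(k) over the N intake
    sequences; ACR is the mean of the per-sequence rates CNT(k)/D(k).
    """
    intake = [s for s in segments if s.is_intake and s.chew_count is not None]
    if not intake:
        return 0, 0.0, 0
    acnt = int(sum(s.chew_count for s in intake))
    acr = float(np.mean([s.chew_count / s.duration_s for s in intake]))
    return acnt, acr, len(intake)
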