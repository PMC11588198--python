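"""Reading and writing the standard artefacts of a phonocardiogram study.

Audio is mono PCM WAV at (nominally) 4000 Hz.  Segmentations are
three-column whitespace-separated text files (start seconds, end seconds,
state code) with the codes 1=S1, 2=systole, 3=S2, 4=diastole and, as an
extension for ground truth with localised murmurs, 5=murmur.  Intervals are
half-open ``[start, end)`` and must be ordered and non-overlapping.
Per-patient metadata is a flat ``key: value`` text block.  Per-recording
results are JSON lines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: canonical state order used everywhere in the package
STATE_ORDER = ("S1", "systole", "S2", "diastole", "murmur")

STATE_CODES = {1: "S1", 2: "systole", 3: "S2", 4: "diastole", 5: "murmur"}
CODE_FOR_STATE = {v: k for k, v in STATE_CODES.items()}

#: the four standard auscultation sites
SITES = ("AV", "PV", "TV", "MV")


@dataclass
class PcgRecording:
    """A single-channel heart sound recording.

    Attributes
    ----------
    samples : ndarray
        Dimensionless amplitude values (float64).
    fs : int
        Sampling rate in Hz; dataset-conformant recordings use 4000 Hz.
    recording_id : str
        Opaque identifier.
    site : str
        Auscultation site: one of AV, PV, TV, MV or "other".
    """

    samples: np.ndarray
    fs: int = 4000
    recording_id: str = ""
    site: str = "other"

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class SegmentInterval:
    """Half-open interval ``[start, end)`` (seconds) in a given heart-sound state."""

    start: float
    end: float
    state: str

    def __post_init__(self):
        if self.state not in STATE_ORDER:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.start < self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")


@dataclass
class PatientRecord:
    """Per-patient metadata and recording references."""

    patient_id: str
    age_group: str = "child"
    pregnant: bool = False
    murmur_label: str = "absent"  # present | absent | unknown
    murmur_timing: str = "none"  # early-systolic | mid-systolic | holosystolic | none
    outcome: str = "normal"  # normal | abnormal
    recordings: list = field(default_factory=list)


#: ordinal coding of the dataset's age bands
AGE_GROUPS = ("neonate", "infant", "child", "adolescent", "young adult")


def age_group_ordinal(age_group: str) -> int:
    """Map an age band to its ordinal position (unknown bands -> -1)."""
    try:
        return AGE_GROUPS.index(age_group)
    except ValueError:
        return -1


# ---------------------------------------------------------------------------
# WAV audio

def read_recording(path, site: str = "other") -> PcgRecording:
    """Read a mono PCM WAV file into a :class:`PcgRecording`.

    Integer PCM samples are scaled to [-1, 1); float files pass through.
    Raises ``ValueError`` on multi-channel input.
    """
    path = Path(path)
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"expected mono audio, got {data.shape[1]} channels in {path}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return PcgRecording(samples=samples, fs=int(fs), recording_id=path.stem, site=site)


def write_recording(path, rec: PcgRecording) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    x = np.asarray(rec.samples, dtype=np.float64)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 1.0:
        x = x / peak
    pcm = np.clip(np.round(x * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), rec.fs, pcm)


# ---------------------------------------------------------------------------
# Segmentation TSV

def read_segmentation(path) -> list[SegmentInterval]:
    """Parse a three-column segmentation file into ordered intervals.

    Validates ordering and non-overlap; raises ``ValueError`` naming the
    offending row on violation or unknown state code.
    """
    intervals: list[SegmentInterval] = []
    prev_end = -np.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            start, end = float(parts[0]), float(parts[1])
            try:
                code = int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer state code {parts[2]!r}")
            if code not in STATE_CODES:
                raise ValueError(f"{path}:{lineno}: unknown state code {code}")
            if start < prev_end - 1e-9:
                raise ValueError(f"{path}:{lineno}: interval overlaps or is out of order")
            intervals.append(SegmentInterval(start, end, STATE_CODES[code]))
            prev_end = end
    return intervals


def write_segmentation(path, intervals: list[SegmentInterval]) -> None:
    """Write intervals as the three-column dialect (times with 4 decimals)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.start:.4f}\t{iv.end:.4f}\t{CODE_FOR_STATE[iv.state]}\n")


# ---------------------------------------------------------------------------
# Patient metadata (flat key: value block)

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}

_KNOWN_KEYS = {
    "patient_id", "age_group", "pregnant", "murmur_label", "murmur_timing",
    "outcome", "recordings",
}


def read_patient_metadata(path) -> PatientRecord:
    """Parse a ``key: value`` metadata block; unknown keys are ignored with a warning."""
    fields: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or ":" not in line:
                continue
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key not in _KNOWN_KEYS:
                logger.warning("ignoring unknown metadata key %r in %s", key, path)
                continue
            if key == "pregnant":
                fields[key] = _BOOL.get(value.lower(), False)
            elif key == "recordings":
                fields[key] = [tok for tok in value.split(",") if tok]
            else:
                fields[key] = value
    if "patient_id" not in fields:
        raise ValueError(f"{path}: missing patient_id")
    return PatientRecord(**fields)


def write_patient_metadata(path, patient: PatientRecord) -> None:
    with open(path, "w") as fh:
        fh.write(f"patient_id: {patient.patient_id}\n")
        fh.write(f"age_group: {patient.age_group}\n")
        fh.write(f"pregnant: {str(patient.pregnant).lower()}\n")
        fh.write(f"murmur_label: {patient.murmur_label}\n")
        fh.write(f"murmur_timing: {patient.murmur_timing}\n")
        fh.write(f"outcome: {patient.outcome}\n")
        if patient.recordings:
            names = ",".join(str(r) for r in patient.recordings)
            fh.write(f"recordings: {names}\n")


# ---------------------------------------------------------------------------
# Result files (JSON lines: one object per recording)

def write_results(path, records: list[dict]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_results(path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
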