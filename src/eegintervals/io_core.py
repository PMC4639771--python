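"""Recording data model, EDF input/output and the 10-20 montage.

A :class:`Recording` bundles a multichannel scalp EEG signal (microvolts),
its sampling rate, the named protocol segments of a standard clinical EEG
session (pre-Fs, Fs, post-Fs, Hv, post-Hv) and per-subject metadata
(diagnosis, number of antiepileptic drugs, visual EEG score).

EDF files are read through :func:`mne.io.read_raw_edf`.  Writing uses a
small 16-bit EDF writer implemented here; the physical range is fixed at
±1000 µV against digital ±32767 so the quantisation step is reproducible.
"""

from __future__ import annotations

import datetime
import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The 19 scalp electrodes of the international 10-20 system, fixed order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Homologous left/right electrode pairs, anterior to posterior.
SYMMETRIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("T3", "T4"),
    ("C3", "C4"), ("T5", "T6"), ("P3", "P4"), ("O1", "O2"),
)

#: Midline electrodes kept as singleton groups.
MIDLINE: tuple[str, ...] = ("Fz", "Cz", "Pz")

#: Protocol segment labels in temporal order.
SEGMENT_LABELS: tuple[str, ...] = ("pre-Fs", "Fs", "post-Fs", "Hv", "post-Hv")

DIAGNOSES = ("TLE", "FLE", "PNES", "headache")
EPILEPSY_DIAGNOSES = ("TLE", "FLE")
CONTROL_DIAGNOSES = ("PNES", "headache")

_EDF_PHYS_MAX = 1000.0   # µV
_EDF_DIG_MAX = 32767


class ChannelError(ValueError):
    """A required 10-20 channel is absent or unknown."""


class SegmentError(ValueError):
    """A segment label is unknown or lies outside the recording."""


def normalize_label(label: str) -> str:
    """Map an EDF channel label onto the 10-20 vocabulary.

    Strips common prefixes/suffixes ("EEG Fp1-REF" -> "Fp1"), periods and
    case differences.  Returns the canonical label or raises
    :class:`ChannelError`.
    """
    s = label.strip().replace(".", "")
    for prefix in ("EEG ", "eeg "):
        if s.startswith(prefix):
            s = s[len(prefix):]
    s = s.split("-")[0].strip()
    lut = {c.lower(): c for c in CHANNELS_1020}
    key = s.lower()
    if key not in lut:
        raise ChannelError(f"channel label {label!r} is not a 10-20 electrode")
    return lut[key]


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata consumed as classification labels.

    diagnosis
        One of TLE / FLE (epilepsy) or PNES / headache (control).
    n_aed
        Number of distinct antiepileptic drugs taken, 0-3 (sedative
        benzodiazepines counted in).
    eeg_score
        4-level ordinal summary of the visual EEG report: 0 normal,
        1 normal variant, 2 nonspecific abnormality, 3 epileptiform.
    """

    subject_id: str
    diagnosis: str
    n_aed: int = 0
    eeg_score: int = 0
    epilepsy_duration_years: float | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if not 0 <= int(self.n_aed) <= 3:
            raise ValueError("n_aed must be in 0..3")
        if not 0 <= int(self.eeg_score) <= 3:
            raise ValueError("eeg_score must be in 0..3")
        if (self.epilepsy_duration_years is not None
                and self.epilepsy_duration_years < 0):
            raise ValueError("epilepsy_duration_years must be >= 0")

    @property
    def is_epilepsy(self) -> bool:
        return self.diagnosis in EPILEPSY_DIAGNOSES

    @property
    def group(self) -> str:
        return "epilepsy" if self.is_epilepsy else "control"


class SegmentMap(dict):
    """Named half-open time intervals ``label -> (start_s, end_s)``.

    Labels come from the protocol vocabulary (plus optional ``post-Hv/i``
    sub-segments).  Intervals must be pairwise non-overlapping.
    """

    def __init__(self, segments: Mapping[str, tuple[float, float]]):
        super().__init__()
        for label, (start, end) in segments.items():
            base = label.split("/")[0]
            if base not in SEGMENT_LABELS:
                raise SegmentError(f"unknown segment label {label!r}")
            if not end > start >= 0:
                raise SegmentError(f"segment {label!r}: need 0 <= start < end")
            self[label] = (float(start), float(end))
        items = sorted(self.values())
        for (s0, e0), (s1, e1) in zip(items, items[1:]):
            if s1 < e0:
                raise SegmentError("segments overlap")

    @property
    def end(self) -> float:
        return max(e for _, e in self.values()) if self else 0.0

    def ordered_labels(self) -> list[str]:
        """Labels sorted by start time."""
        return sorted(self, key=lambda k: self[k][0])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.items()}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentMap":
        return cls(json.loads(Path(path).read_text()))

    def with_posthv_subsegments(self, n: int = 3) -> "SegmentMap":
        """Return a copy with post-Hv additionally split into ``n`` equal
        sub-segments ``post-Hv/1 … post-Hv/n`` (the original post-Hv entry
        is replaced so segments stay non-overlapping)."""
        if "post-Hv" not in self:
            raise SegmentError("no post-Hv segment to subdivide")
        start, end = self["post-Hv"]
        out = {k: v for k, v in self.items() if k != "post-Hv"}
        edges = np.linspace(start, end, n + 1)
        for i in range(n):
            out[f"post-Hv/{i + 1}"] = (float(edges[i]), float(edges[i + 1]))
        return SegmentMap(out)


@dataclass
class Recording:
    """A referential multichannel EEG recording in microvolts."""

    subject_id: str
    fs: float
    channels: list[str]
    signal: np.ndarray          # shape (n_channels, n_samples), µV
    segments: SegmentMap
    meta: SubjectMeta | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError("signal must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = self.signal.shape[1] / self.fs
        for label, (start, end) in self.segments.items():
            if end > dur + 1e-9:
                raise SegmentError(
                    f"segment {label!r} ends at {end} s but the recording "
                    f"lasts {dur:.3f} s")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise ChannelError(f"channel {label!r} not in recording") from None


def extract_segment(
    rec: Recording,
    label: str,
    channels: Sequence[str] | None = None,
) -> np.ndarray:
    """Return the ``channels × samples`` block of a named protocol segment.

    Segment boundaries are half-open in seconds and map to the sample range
    ``[floor(start*fs), floor(end*fs))``.  The pseudo-label ``"whole"``
    concatenates every segment of the map in temporal order.
    """
    chan = list(rec.channels) if channels is None else list(channels)
    rows = [rec.channel_index(c) for c in chan]
    if label == "whole":
        parts = [extract_segment(rec, lab, chan)
                 for lab in rec.segments.ordered_labels()]
        return np.concatenate(parts, axis=1)
    if label not in rec.segments:
        raise SegmentError(f"segment {label!r} not in segment map")
    start, end = rec.segments[label]
    i0 = int(np.floor(start * rec.fs))
    i1 = int(np.floor(end * rec.fs))
    return rec.signal[rows, i0:i1]


def symmetric_channel_pairs(
    channels: Iterable[str],
    include_midline: bool = True,
) -> list[tuple[str, ...]]:
    """Group channels into homologous left/right pairs plus midline singletons.

    Returns up to 11 groups in a fixed anterior-to-posterior order:
    the 8 lateral pairs (Fp1+Fp2 ... O1+O2) then Fz, Cz, Pz.  A pair with a
    missing member degrades to the present member with a warning.
    """
    have = {normalize_label(c) for c in channels}
    groups: list[tuple[str, ...]] = []
    for left, right in SYMMETRIC_PAIRS:
        members = tuple(c for c in (left, right) if c in have)
        if not members:
            continue
        if len(members) == 1:
            warnings.warn(
                f"pair {left}+{right}: only {members[0]} present",
                stacklevel=2)
        groups.append(members)
    if include_midline:
        for mid in MIDLINE:
            if mid in have:
                groups.append((mid,))
    return groups


def group_label(group: tuple[str, ...]) -> str:
    return "+".join(group)


# ---------------------------------------------------------------------------
# EDF input/output
# ---------------------------------------------------------------------------

def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a recording as 16-bit EDF (physical ±1000 µV, digital ±32767).

    The record duration is 1 s, so the recording is truncated to a whole
    number of seconds (synthetic protocols use integer-second segments).
    Samples outside ±1000 µV are clipped.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    nch = len(rec.channels)
    now = datetime.datetime(2000, 1, 1)

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > n:
            raise ValueError(f"field too long: {s!r}")
        return b.ljust(n)

    header = b"".join([
        pad("0", 8),
        pad(rec.subject_id[:80], 80),
        pad("interval-analysis synthetic", 80),
        pad(now.strftime("%d.%m.%y"), 8),
        pad(now.strftime("%H.%M.%S"), 8),
        pad(str(256 * (nch + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(nch), 4),
    ])
    fields = [
        (16, [pad(c, 16) for c in rec.channels]),
        (80, [pad("AgAgCl electrode", 80)] * nch),
        (8, [pad("uV", 8)] * nch),
        (8, [pad(f"{-_EDF_PHYS_MAX:.0f}", 8)] * nch),
        (8, [pad(f"{_EDF_PHYS_MAX:.0f}", 8)] * nch),
        (8, [pad(str(-_EDF_DIG_MAX), 8)] * nch),
        (8, [pad(str(_EDF_DIG_MAX), 8)] * nch),
        (80, [pad("HP:0.5Hz", 80)] * nch),
        (8, [pad(str(fs), 8)] * nch),
        (32, [pad("", 32)] * nch),
    ]
    sig_header = b"".join(b"".join(col) for _, col in fields)

    scale = _EDF_DIG_MAX / _EDF_PHYS_MAX
    digital = np.clip(np.round(rec.signal[:, :n_rec * fs] * scale),
                      -_EDF_DIG_MAX, _EDF_DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())  # channel-sequential within record


def read_recording(
    path: str | Path,
    meta: SubjectMeta | None = None,
    segments: SegmentMap | Mapping[str, tuple[float, float]] | None = None,
    require_full_montage: bool = True,
) -> Recording:
    """Read an EDF file into a :class:`Recording` (µV).

    The sampling rate is taken from the EDF header; a per-channel rate
    mismatch raises.  Channel labels are normalised onto the 10-20
    vocabulary; with ``require_full_montage`` missing electrodes raise a
    :class:`ChannelError` naming the absentees.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    header_rates = _edf_channel_rates(path)
    if len(set(header_rates)) > 1:
        raise ValueError(
            f"per-channel sampling rates differ: {sorted(set(header_rates))}")
    fs = float(header_rates[0])
    labels = []
    for name in raw.ch_names:
        labels.append(normalize_label(name))
    if require_full_montage:
        missing = [c for c in CHANNELS_1020 if c not in labels]
        if missing:
            raise ChannelError(
                "missing required channels: " + ", ".join(missing))
    order = ([labels.index(c) for c in CHANNELS_1020]
             if require_full_montage else list(range(len(labels))))
    signal = raw.get_data()[order] * 1e6  # mne returns volts
    channels = [labels[i] for i in order]
    seg = (segments if isinstance(segments, SegmentMap)
           else SegmentMap(segments or
                           {"pre-Fs": (0.0, signal.shape[1] / fs)}))
    subject_id = meta.subject_id if meta is not None else Path(path).stem
    return Recording(subject_id=subject_id, fs=fs, channels=channels,
                     signal=signal, segments=seg, meta=meta)


def _edf_channel_rates(path: str | Path) -> list[float]:
    """Per-channel sampling rates straight from the EDF header."""
    with open(path, "rb") as fh:
        fh.seek(244)
        record_dur = float(fh.read(8).decode("ascii").strip() or "1")
        fh.seek(252)
        nch = int(fh.read(4).decode("ascii").strip())
        fh.seek(256 + nch * (16 + 80 + 8 * 5 + 80))
        samples = [int(fh.read(8).decode("ascii").strip())
                   for _ in range(nch)]
    return [s / record_dur for s in samples]


# ---------------------------------------------------------------------------
# Metadata sidecar
# ---------------------------------------------------------------------------

def write_meta_csv(path: str | Path, metas: Sequence[SubjectMeta]) -> None:
    import pandas as pd

    rows = [{
        "subject_id": m.subject_id,
        "diagnosis": m.diagnosis,
        "nAED": m.n_aed,
        "eeg_score": m.eeg_score,
        "duration_years": (np.nan if m.epilepsy_duration_years is None
                           else m.epilepsy_duration_years),
    } for m in metas]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_meta_csv(path: str | Path) -> list[SubjectMeta]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        dur = row.get("duration_years")
        out.append(SubjectMeta(
            subject_id=str(row["subject_id"]),
            diagnosis=str(row["diagnosis"]),
            n_aed=int(row["nAED"]),
            eeg_score=int(row["eeg_score"]),
            epilepsy_duration_years=None if pd.isna(dur) else float(dur),
        ))
    return out
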