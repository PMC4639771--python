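"""Zero-crossing detection and the interval spectrum.

The interval spectrum of a band-passed EEG signal is the normalised
histogram of the times between successive crossings of the isoelectric
(zero) line.  Crossing times are located with sub-sample precision by
linear interpolation between the bracketing samples.  Histograms use
1000 half-open 4-ms bins spanning 0-4000 ms and are pooled over channel
groups and/or protocol segments before normalisation; pooling everything
is "whole-recording" analysis.

Two crossing conventions are provided.  The default, ``rising``, takes
intervals between successive negative-to-non-negative crossings — one
interval per oscillation cycle, so an f-Hz rhythm maps to 1000/f ms
intervals and the 8-13 Hz alpha band corresponds to the 77-125 ms
interval range.  The alternative ``all`` convention uses every crossing
(half-period intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import json

import numpy as np

from .filters import BandPass

BIN_WIDTH_MS = 4.0
RANGE_MS = 4000.0
N_BINS = int(RANGE_MS / BIN_WIDTH_MS)

#: Interval-range counterparts of the clinical frequency bands (ms).
ALPHA_RANGE_MS = (77.0, 125.0)   # 8-13 Hz
THETA_RANGE_MS = (125.0, 250.0)  # 4-8 Hz

CONVENTIONS = ("rising", "all")


def bin_left_edges(bin_width_ms: float = BIN_WIDTH_MS,
                   range_ms: float = RANGE_MS) -> np.ndarray:
    return np.arange(0.0, range_ms, bin_width_ms)


def bins_in_range(lo_ms: float, hi_ms: float,
                  bin_width_ms: float = BIN_WIDTH_MS) -> np.ndarray:
    """Indices of bins whose centre lies in ``[lo_ms, hi_ms)``."""
    centers = bin_left_edges(bin_width_ms) + bin_width_ms / 2
    return np.nonzero((centers >= lo_ms) & (centers < hi_ms))[0]


def detect_crossings(
    x: np.ndarray,
    fs: float,
    convention: str = "rising",
    threshold: float = 0.0,
) -> np.ndarray:
    """Zero-crossing times (ms) of a zero-mean band-passed signal.

    ``rising`` keeps passages from negative to non-negative; ``all`` keeps
    both directions.  The sign of an exact zero sample is treated as
    positive, so a run of zeros yields at most one crossing, at the run's
    first sample.  Times are strictly increasing; a constant signal gives
    an empty array.  ``threshold`` shifts the detection level off the
    isoelectric line (µV); results are insensitive to small shifts when a
    clear rhythm is present.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown crossing convention {convention!r}")
    x = np.asarray(x, dtype=np.float64)
    if threshold:
        x = x - threshold
    pos = x >= 0.0  # sign(0) := +
    if convention == "rising":
        idx = np.nonzero(~pos[:-1] & pos[1:])[0]
    else:
        idx = np.nonzero(pos[:-1] != pos[1:])[0]
    if idx.size == 0:
        return np.empty(0)
    x0 = x[idx]
    x1 = x[idx + 1]
    frac = x0 / (x0 - x1)  # denominators nonzero: signs differ strictly
    return (idx + frac) * (1000.0 / fs)


def crossings_to_intervals(times_ms: np.ndarray) -> np.ndarray:
    """First differences of the crossing times; empty for < 2 crossings."""
    t = np.asarray(times_ms, dtype=np.float64)
    if t.size < 2:
        return np.empty(0)
    return np.diff(t)


def build_histogram(
    intervals_ms: np.ndarray,
    bin_width_ms: float = BIN_WIDTH_MS,
    range_ms: float = RANGE_MS,
) -> tuple[np.ndarray, int]:
    """Histogram interval lengths into half-open bins ``[k·w, (k+1)·w)``.

    Returns ``(raw_counts, overflow)`` where ``overflow`` tallies the
    intervals at or beyond ``range_ms`` that were discarded.
    """
    iv = np.asarray(intervals_ms, dtype=np.float64)
    n_bins = int(round(range_ms / bin_width_ms))
    if iv.size == 0:
        return np.zeros(n_bins, dtype=np.int64), 0
    k = np.floor(iv / bin_width_ms).astype(np.int64)
    overflow = int(np.count_nonzero(k >= n_bins))
    counts = np.bincount(k[k < n_bins], minlength=n_bins)
    return counts.astype(np.int64), overflow


@dataclass
class IntervalSpectrum:
    """Pooled, normalised zero-crossing interval histogram.

    ``raw_counts`` are integer counts per 4-ms bin; ``p`` is the
    normalised probability vector (``p = raw_counts / Σ raw_counts``).
    Provenance records what was pooled.
    """

    raw_counts: np.ndarray
    band: BandPass | None = None
    channel_groups: tuple[str, ...] = ()
    segment_labels: tuple[str, ...] = ()
    subject_id: str = ""
    convention: str = "rising"
    overflow: int = 0
    bin_width_ms: float = BIN_WIDTH_MS

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.raw_counts.sum())

    @property
    def p(self) -> np.ndarray:
        tot = self.total
        if tot == 0:
            raise ValueError("empty spectrum: no intervals detected")
        return self.raw_counts / tot

    @property
    def bin_lefts(self) -> np.ndarray:
        return bin_left_edges(self.bin_width_ms,
                              self.bin_width_ms * len(self.raw_counts))

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_lefts + self.bin_width_ms / 2

    def bin_index(self, bin_left_ms: float) -> int:
        k = bin_left_ms / self.bin_width_ms
        if k != int(k) or not 0 <= k < len(self.raw_counts):
            raise ValueError(
                f"{bin_left_ms} ms is not a bin left edge "
                f"(width {self.bin_width_ms} ms)")
        return int(k)

    def to_tsv(self, path: str | Path) -> None:
        prov = {
            "band": None if self.band is None else [self.band.lo, self.band.hi],
            "channel_groups": list(self.channel_groups),
            "segment_labels": list(self.segment_labels),
            "subject_id": self.subject_id,
            "convention": self.convention,
            "overflow": self.overflow,
            "bin_width_ms": self.bin_width_ms,
        }
        p = self.p
        lines = ["# " + json.dumps(prov), "bin_left_ms\traw_count\tp"]
        for left, c, pi in zip(self.bin_lefts, self.raw_counts, p):
            lines.append(f"{left:g}\t{c}\t{pi:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IntervalSpectrum":
        text = Path(path).read_text().splitlines()
        prov = json.loads(text[0][2:])
        counts = [int(line.split("\t")[1]) for line in text[2:] if line]
        band = None if prov["band"] is None else BandPass(*prov["band"])
        return cls(np.array(counts), band=band,
                   channel_groups=tuple(prov["channel_groups"]),
                   segment_labels=tuple(prov["segment_labels"]),
                   subject_id=prov["subject_id"],
                   convention=prov["convention"],
                   overflow=prov["overflow"],
                   bin_width_ms=prov["bin_width_ms"])


def pool_and_normalize(
    parts: Sequence[np.ndarray | tuple[np.ndarray, int]],
    band: BandPass | None = None,
    channel_groups: Iterable[str] = (),
    segment_labels: Iterable[str] = (),
    subject_id: str = "",
    convention: str = "rising",
    bin_width_ms: float = BIN_WIDTH_MS,
) -> IntervalSpectrum:
    """Sum raw per-(channel, segment) histograms and normalise.

    ``parts`` may mix bare count vectors and ``(counts, overflow)`` pairs
    as returned by :func:`build_histogram`.  All parts must share the
    binning.  Raises if the grand total is zero.
    """
    counts_list = []
    overflow = 0
    for part in parts:
        if isinstance(part, tuple):
            c, o = part
            overflow += o
        else:
            c = part
        counts_list.append(np.asarray(c, dtype=np.int64))
    if not counts_list:
        raise ValueError("no histograms to pool")
    shape0 = counts_list[0].shape
    if any(c.shape != shape0 for c in counts_list):
        raise ValueError("histograms share no common binning")
    total = np.sum(counts_list, axis=0)
    spectrum = IntervalSpectrum(
        total, band=band, channel_groups=tuple(channel_groups),
        segment_labels=tuple(segment_labels), subject_id=subject_id,
        convention=convention, overflow=overflow, bin_width_ms=bin_width_ms)
    if spectrum.total == 0:
        raise ValueError("empty spectrum: no intervals detected")
    return spectrum
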