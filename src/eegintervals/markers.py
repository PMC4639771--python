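"""Scalar markers of the interval spectrum (and Fourier comparators).

Three marker families are screened and classified with:

1. single-bin relative counts ("spectrometry": the probability of, say,
   96-ms intervals),
2. descriptive statistics of the interval distribution (mean, median,
   mode, standard deviation, interquartile range, all in ms, computed
   over bin centres), and
3. entropies — Shannon entropy ``Hs = -Σ p_i log2 p_i`` and min-entropy
   ``Hmin = -log2 max_i p_i`` — which quantify the irregularity of the
   dominant rhythm.  Both are reported in bits; classification is
   invariant to the logarithm base.

A Welch power-spectral-density score at a chosen frequency serves as the
Fourier-analysis comparator, indexed by inverse frequency (1000/f ms) to
overlay the interval axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .intervals import IntervalSpectrum

DESCRIPTIVE_KINDS = ("mean", "median", "mode", "sd", "iqr")
ENTROPY_KINDS = ("shannon_entropy", "min_entropy")


@dataclass(frozen=True)
class MarkerDef:
    """A scalar feature of a spectrum plus an inversion flag.

    ``kind`` is one of ``bin_count`` (with ``bin_left_ms``), the five
    descriptive statistics, the two entropies, or ``fourier_band_amp``
    (with ``freq_hz``).  With ``invert`` the score is the negated marker,
    which maps AUC to 1 − AUC.
    """

    kind: str
    bin_left_ms: float | None = None
    freq_hz: float | None = None
    invert: bool = False

    def __post_init__(self) -> None:
        kinds = ("bin_count", *DESCRIPTIVE_KINDS, *ENTROPY_KINDS,
                 "fourier_band_amp")
        if self.kind not in kinds:
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.kind == "bin_count":
            b = self.bin_left_ms
            if b is None or b % 4 or not 0 <= b <= 3996:
                raise ValueError(
                    "bin_count needs bin_left_ms, a multiple of 4 in "
                    "[0, 3996]")
        if self.kind == "fourier_band_amp" and self.freq_hz is None:
            raise ValueError("fourier_band_amp needs freq_hz")

    def evaluate(self, spectrum: IntervalSpectrum) -> float:
        if self.kind == "bin_count":
            v = bin_marker(spectrum, self.bin_left_ms)
        elif self.kind in DESCRIPTIVE_KINDS:
            v = descriptive_markers(spectrum)[self.kind]
        elif self.kind in ENTROPY_KINDS:
            hs, hmin = entropy_markers(spectrum)
            v = hs if self.kind == "shannon_entropy" else hmin
        else:
            raise ValueError(
                "fourier_band_amp is evaluated on a signal, not a spectrum")
        return -v if self.invert else v


def bin_marker(spectrum: IntervalSpectrum, bin_left_ms: float) -> float:
    """Relative count (probability) of intervals in one 4-ms bin."""
    return float(spectrum.p[spectrum.bin_index(bin_left_ms)])


def descriptive_markers(spectrum: IntervalSpectrum) -> dict[str, float]:
    """Mean, median, mode, sd and IQR of the binned interval distribution.

    Moments use bin centres (left edge + half width); the mode is the
    centre of the highest-probability bin with ties broken towards the
    smallest bin; median and IQR interpolate the cumulative distribution
    linearly within bins.
    """
    p = spectrum.p
    centers = spectrum.bin_centers
    mean = float(p @ centers)
    sd = float(np.sqrt(p @ (centers - mean) ** 2))
    mode = float(centers[int(np.argmax(p))])
    q25, q50, q75 = _quantiles(spectrum, (0.25, 0.5, 0.75))
    return {"mean": mean, "median": q50, "mode": mode, "sd": sd,
            "iqr": q75 - q25}


def _quantiles(spectrum: IntervalSpectrum, qs) -> list[float]:
    # linear interpolation of the CDF over occupied bin centres; a point
    # mass therefore has zero IQR
    p = spectrum.p
    nz = p > 0
    cum = np.cumsum(p[nz])
    cum[-1] = 1.0
    x = spectrum.bin_centers[nz]
    return [float(np.interp(q, cum, x)) for q in qs]


def entropy_markers(spectrum: IntervalSpectrum,
                    base: float = 2.0) -> tuple[float, float]:
    """Shannon entropy and min-entropy of the spectrum, in log-``base`` units.

    Zero-probability bins contribute nothing to the Shannon sum; the
    min-entropy is the negative logarithm of the highest peak.  For any
    distribution ``Hmin <= Hs``.
    """
    p = spectrum.p
    nz = p[p > 0]
    hs = float(-(nz * (np.log(nz) / np.log(base))).sum())
    hmin = float(-np.log(nz.max()) / np.log(base))
    return hs, hmin


def welch_psd(x: np.ndarray, fs: float, window_s: float = 4.0,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (Hann taper, 4-s window, 50% overlap)."""
    nper = int(round(window_s * fs))
    if len(x) < nper:
        raise ValueError(
            f"signal shorter ({len(x)} samples) than one Welch window "
            f"({nper})")
    return welch(x, fs=fs, window="hann", nperseg=nper,
                 noverlap=int(round(nper * overlap)))


def welch_band_amp(x: np.ndarray, fs: float, freq_hz: float,
                   window_s: float = 4.0, amplitude: bool = False) -> float:
    """Welch power density at the frequency bin nearest ``freq_hz``.

    The Fourier comparator score; ``amplitude`` returns the square root
    (amplitude rather than power density).
    """
    f, pxx = welch_psd(x, fs, window_s)
    v = float(pxx[int(np.argmin(np.abs(f - freq_hz)))])
    return float(np.sqrt(v)) if amplitude else v


def marker_table(spectra: dict[str, IntervalSpectrum]) -> "object":
    """Long-format table of all descriptive and entropy markers per subject."""
    import pandas as pd

    rows = []
    for sid, s in spectra.items():
        d = descriptive_markers(s)
        hs, hmin = entropy_markers(s)
        d.update({"shannon_entropy": hs, "min_entropy": hmin})
        for kind, value in d.items():
            rows.append({"subject_id": sid, "marker_kind": kind,
                         "value": value})
    return pd.DataFrame(rows)
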