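"""Zero-phase FIR band-pass filtering on a 1-Hz parameter grid.

Filters are designed by frequency sampling (``scipy.signal.firwin2``, the
equivalent of MATLAB's ``fir2``): unit target gain inside the passband,
zero outside, with a linear transition of configurable width (default
1 Hz).  They are applied forward and backward, so the effective magnitude
response is the square of the single-pass response and the group delay is
zero.  Edges are handled by point-symmetric (odd) reflection padding of
one filter length, which keeps the signal continuous through the segment
boundary and avoids spurious zero-crossings there.

The forward-backward pass is computed by FFT convolution; for the long
recordings and ~100-band search grids used here this is orders of
magnitude faster than direct convolution with 500-tap kernels and is
numerically identical to ``filtfilt`` with the same padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve, firwin2, freqz


@dataclass(frozen=True)
class BandPass:
    """Integer passband edges in Hz; ``lo == 0`` denotes a pure low-pass."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"need 0 <= lo < hi, got [{self.lo}, {self.hi}]")

    def validate(self, fs: float) -> None:
        if self.hi > fs / 2:
            raise ValueError(
                f"upper edge {self.hi} Hz exceeds Nyquist {fs / 2} Hz")

    def __str__(self) -> str:  # e.g. "[4-13 Hz]"
        return f"[{self.lo}-{self.hi} Hz]"


@dataclass(frozen=True)
class FirFilter:
    """A linear-phase FIR band-pass (symmetric coefficient vector)."""

    taps: np.ndarray
    band: BandPass
    fs: float

    @property
    def design_order(self) -> int:
        return len(self.taps) - 1

    def response(self, freqs: np.ndarray) -> np.ndarray:
        """Single-pass magnitude response at the given frequencies (Hz)."""
        _, h = freqz(self.taps, worN=np.asarray(freqs, float), fs=self.fs)
        return np.abs(h)


def design_bandpass(
    band: BandPass,
    fs: float,
    order: int = 500,
    transition_hz: float = 1.0,
) -> FirFilter:
    """Frequency-sampling design of a linear-phase band-pass FIR filter.

    The target response is 1 on ``[lo, hi]``, 0 beyond one transition
    width outside, with linear ramps between.  ``order`` is taps − 1 and
    must resolve the transition: the impulse response (order/fs seconds)
    must span at least two transition periods.
    """
    band.validate(fs)
    nyq = fs / 2
    min_order = int(np.ceil(2 * fs / transition_hz))
    if order < min_order:
        raise ValueError(
            f"order {order} too small for a {transition_hz} Hz transition "
            f"at fs={fs}; need >= {min_order}")
    lo, hi = float(band.lo), float(band.hi)
    freq: list[float] = [0.0]
    gain: list[float] = []
    if lo == 0:
        gain.append(1.0)
    else:
        gain.append(0.0)
        f0 = max(lo - transition_hz, 0.0)
        if f0 > 0:
            freq.append(f0)
            gain.append(0.0)
        freq.append(lo)
        gain.append(1.0)
    if hi + transition_hz < nyq:
        freq += [hi, hi + transition_hz, nyq]
        gain += [1.0, 0.0, 0.0]
    else:
        freq += [hi, nyq]
        gain += [1.0, 0.0 if hi < nyq else 1.0]
    ntaps = order + 1
    if ntaps % 2 == 0:  # type-I (odd length) keeps the design symmetric
        ntaps += 1
    taps = firwin2(ntaps, freq, gain, fs=fs)
    return FirFilter(taps=taps, band=band, fs=fs)


@lru_cache(maxsize=256)
def _cached_filter(lo: int, hi: int, fs: float, order: int,
                   transition_hz: float) -> FirFilter:
    return design_bandpass(BandPass(lo, hi), fs, order, transition_hz)


def get_filter(band: BandPass, fs: float, order: int = 500,
               transition_hz: float = 1.0) -> FirFilter:
    """Cached filter design (the search grid reuses each band many times)."""
    return _cached_filter(band.lo, band.hi, float(fs), order, transition_hz)


def apply_zero_phase_bank(
    x: np.ndarray,
    bank: "list[FirFilter]",
) -> list[np.ndarray]:
    """Forward-backward filter one signal block through a whole filter bank.

    Equivalent to ``[apply_zero_phase(x, f) for f in bank]`` but the FFT of
    the (padded) input is computed once and reused across bands, which is
    the dominant cost when scanning a ~100-band search grid.  All filters
    must share their tap count.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    x = np.asarray(x, dtype=np.float64)
    one_d = x.ndim == 1
    if one_d:
        x = x[None, :]
    if not bank:
        return []
    ntaps = len(bank[0].taps)
    if any(len(f.taps) != ntaps for f in bank):
        raise ValueError("filter bank must share a tap count")
    n = x.shape[1]
    if n <= 3 * ntaps:
        raise ValueError(
            f"signal too short for zero-phase filtering: {n} samples, "
            f"need > {3 * ntaps}")
    pad = ntaps
    left = 2 * x[:, :1] - x[:, pad:0:-1]
    right = 2 * x[:, -1:] - x[:, -2:-pad - 2:-1]
    padded = np.concatenate([left, x, right], axis=1)
    npad = padded.shape[1]
    klen = 2 * ntaps - 1          # conv(taps, taps), symmetric
    nfft = next_fast_len(npad + klen - 1)
    X = rfft(padded, nfft, axis=1)
    out = []
    offset = (klen - 1) // 2      # centre of the zero-phase kernel
    for f in bank:
        kernel = np.convolve(f.taps, f.taps)
        K = rfft(kernel, nfft)
        y = irfft(X * K[None, :], nfft, axis=1)
        y = y[:, offset + pad:offset + pad + n]
        out.append(y[0] if one_d else y)
    return out


def apply_zero_phase(x: np.ndarray, f: FirFilter) -> np.ndarray:
    """Forward-backward filtering with odd-reflection edge padding.

    Accepts a 1-D signal or a ``channels × samples`` matrix and returns an
    array of identical shape.  Requires ``n_samples > 3 × tap count``.
    """
    x = np.asarray(x, dtype=np.float64)
    one_d = x.ndim == 1
    if one_d:
        x = x[None, :]
    n = x.shape[1]
    ntaps = len(f.taps)
    if n <= 3 * ntaps:
        raise ValueError(
            f"signal too short for zero-phase filtering: {n} samples, "
            f"need > {3 * ntaps}")
    pad = ntaps
    left = 2 * x[:, :1] - x[:, pad:0:-1]
    right = 2 * x[:, -1:] - x[:, -2:-pad - 2:-1]
    padded = np.concatenate([left, x, right], axis=1)
    # forward+backward with a symmetric kernel == one pass of taps*taps
    kernel = fftconvolve(f.taps, f.taps)[None, :]
    y = fftconvolve(padded, kernel, mode="same", axes=1)
    y = y[:, pad:pad + n]
    return y[0] if one_d else y
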