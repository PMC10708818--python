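"""Zero-phase FIR filtering primitives.

Every filter in the package — the broadband pre-processing band-pass,
the power-line notch, and both stages of the AM filter bank — shares one
mechanism: a linear-phase Hamming-window FIR applied in two successive
passes in opposing directions on a mirror-padded copy of the signal, so
the net response has exactly zero group delay and the effective
magnitude is the square of the single-pass magnitude.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .bands import BandSpec

#: Hamming-window main-lobe factor: transition width ~ 3.3 * fs / numtaps.
_HAMMING_TW = 3.3


def _transition_width(f_lo: float) -> float:
    """Transition width in Hz for a band with lower edge ``f_lo``.

    Half the lower edge, clipped to [1, 2] Hz: narrow slow bands get a
    proportionally narrow transition (so a 1-4 Hz band still rejects
    4-8 Hz content) without the filter length exploding, and no skirt
    ever reaches past an adjacent band's near edge — the classical EEG
    bands are contiguous, so transitions wider than 2 Hz would leak
    neighbouring-band energy into the envelope stage.
    """
    return float(np.clip(0.5 * f_lo, 1.0, 2.0))


def _numtaps(fs: float, width: float) -> int:
    n = int(np.ceil(_HAMMING_TW * fs / width))
    return n + 1 if n % 2 == 0 else n  # odd length -> type-I linear phase


def design_band_filter(band: BandSpec, fs: float) -> np.ndarray:
    """Design a linear-phase band-pass FIR for one filter-bank band.

    The -6 dB cutoffs sit half a transition width outside [f_lo, f_hi],
    so the band edges themselves are near unity gain and attenuation
    reaches the stopband one transition width outside the band.

    Returns the filter taps (odd length, symmetric).
    """
    band.check_nyquist(fs)
    width = _transition_width(band.f_lo)
    lo = band.f_lo - width / 2
    hi = band.f_hi + width / 2
    if hi >= fs / 2:
        raise ValueError(
            f"band {band.name!r}: upper transition edge {hi:.1f} Hz reaches "
            f"Nyquist at fs={fs}; raise fs or narrow the band"
        )
    numtaps = _numtaps(fs, width)
    if lo <= 0:
        # degenerate low edge: fall back to a low-pass
        return sps.firwin(numtaps, hi, window="hamming", fs=fs)
    return sps.firwin(numtaps, [lo, hi], window="hamming", pass_zero=False, fs=fs)


def design_bandstop(f_lo: float, f_hi: float, fs: float,
                    width: float = 1.0) -> np.ndarray:
    """Linear-phase band-stop FIR (used for the power-line notch)."""
    if f_hi >= fs / 2:
        raise ValueError(
            f"stopband [{f_lo}, {f_hi}] Hz needs fs > {2 * f_hi} Hz, got {fs}"
        )
    numtaps = _numtaps(fs, width)
    return sps.firwin(numtaps, [f_lo, f_hi], window="hamming",
                      pass_zero=True, fs=fs)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply FIR ``taps`` forward and backward on a mirror-padded signal.

    Output has the length of the input, zero group delay, and squared
    single-pass magnitude response.  Requires ``len(x) > 3 * len(taps)``
    so the mirror padding and filter transients never dominate.
    """
    x = np.asarray(x, dtype=float)
    n, L = x.shape[-1], len(taps)
    if n <= 3 * L:
        raise ValueError(
            f"signal length {n} too short for filter length {L} "
            f"(need > {3 * L} samples)"
        )
    pad = min(L, n - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    y = sps.fftconvolve(xp, np.atleast_2d(taps) if x.ndim == 2 else taps,
                        mode="same", axes=-1)
    y = y[..., ::-1]
    y = sps.fftconvolve(y, np.atleast_2d(taps) if x.ndim == 2 else taps,
                        mode="same", axes=-1)
    y = y[..., ::-1]
    return y[..., pad:pad + n]


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal: |x + i * H(x)|.

    Nonnegative, same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite input to hilbert_envelope")
    return np.abs(sps.hilbert(x, axis=-1))


def frequency_response(taps: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Single-pass magnitude response |H(f)| at the given frequencies."""
    _, h = sps.freqz(taps, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h)
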