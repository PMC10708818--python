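"""Baseline power-spectral-density features.

Epochs are tiled with non-overlapping 1 s windows (16 per trial); each
window's spectrum is estimated by Welch's method with Hamming-tapered
segments of at most 1 s (a single segment for the default 1 s window:
sub-second segments would give 2 Hz bins, too coarse to separate the
2 Hz-wide alpha sub-bands) and normalized so the bins sum to one.  Features
are relative band powers over a conventional band set (theta, split
alpha and beta sub-bands, and two broad bands) plus the alpha/beta and
theta/beta power ratios, all log-scaled with a small floor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import PSD_BANDS, PSD_RATIOS, BandSpec
from .data import Epoch

logger = logging.getLogger(__name__)

LOG_EPS = 1e-10
WINDOW_S = 1.0


def welch_psd(window_signal: np.ndarray, fs: float,
              on_zero: str = "warn") -> tuple[np.ndarray, np.ndarray]:
    """Normalized one-sided Welch spectrum of a 1 s window.

    Returns (freqs, power) with ``power.sum() == 1`` for any non-zero
    input.  A zero window yields an all-zero spectrum with a warning
    (``on_zero="error"`` raises).
    """
    x = np.asarray(window_signal, dtype=float)
    n_expected = int(round(WINDOW_S * fs))
    if x.shape[-1] != n_expected:
        raise ValueError(
            f"window must be {n_expected} samples (1 s at fs={fs}), "
            f"got {x.shape[-1]}"
        )
    nperseg = max(8, min(x.shape[-1], int(round(fs))))
    freqs, p = sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                         noverlap=nperseg // 2)
    total = p.sum()
    if total == 0:
        if on_zero == "error":
            raise ValueError("zero window has no spectrum")
        logger.warning("zero signal window: emitting all-zero spectrum")
        return freqs, p
    return freqs, p / total


def band_powers(freqs: np.ndarray, spectrum: np.ndarray,
                bands=PSD_BANDS) -> dict[str, float]:
    """Relative power per band: sum of normalized bins in [f_lo, f_hi)."""
    out = {}
    for b in bands:
        mask = (freqs >= b.f_lo) & (freqs < b.f_hi)
        out[b.name] = float(spectrum[mask].sum())
    return out


def power_ratios_and_log(powers: dict[str, float],
                         ratios=PSD_RATIOS,
                         eps: float = LOG_EPS) -> dict[str, float]:
    """Append the configured power ratios and log-scale every feature.

    Ratios are built from sub-band sums (alpha = alpha1 + alpha2,
    beta = beta1 + beta2); every feature is mapped x -> log(x + eps) so
    zero powers stay finite.
    """
    vals = dict(powers)
    composite = {
        (8.0, 12.0): powers.get("alpha1", 0.0) + powers.get("alpha2", 0.0),
        (12.0, 30.0): powers.get("beta1", 0.0) + powers.get("beta2", 0.0),
        (4.0, 8.0): powers.get("theta", 0.0),
    }
    for name, (num_edges, den_edges) in ratios.items():
        num = composite.get(num_edges)
        den = composite.get(den_edges)
        if num is None or den is None:
            raise KeyError(f"ratio {name} references undefined band edges")
        vals[name] = num / den if den > 0 else num / eps
    return {k: float(np.log(v + eps)) for k, v in vals.items()}


def psd_features(epoch: Epoch, bands=PSD_BANDS,
                 ratios=PSD_RATIOS) -> pd.DataFrame:
    """PSD feature table for one epoch: 16 windows x (bands + ratios)
    x channels, long format.

    The ``frame`` column here indexes the 1 s window (0-15 on the
    epoch's own axis); alignment to AMP frames is done downstream.
    """
    n_win = int(epoch.duration // WINDOW_S)
    n_samp = int(round(WINDOW_S * epoch.fs))
    rows = []
    for ci, ch in enumerate(epoch.channel_labels):
        for w in range(n_win):
            seg = epoch.signal[ci, w * n_samp:(w + 1) * n_samp]
            freqs, spec = welch_psd(seg, epoch.fs)
            feats = power_ratios_and_log(band_powers(freqs, spec, bands),
                                         ratios)
            for name, v in feats.items():
                rows.append((epoch.participant, epoch.session, epoch.trial,
                             epoch.task, w, f"PSD__{ch}__{name}", v))
    return pd.DataFrame(rows, columns=[
        "participant", "session", "trial", "task", "frame",
        "feature_name", "value",
    ])


def align_psd_to_frames(psd_table: pd.DataFrame,
                        frame_starts_s: tuple[float, ...],
                        window_s: float = 4.0,
                        epoch_t0: float = -1.0) -> pd.DataFrame:
    """Re-index PSD windows onto the AMP frame grid.

    A classification sample is one AMP frame; its PSD features are those
    of the 1 s window ending at the frame's end time (the freshest
    spectrum available when the frame's decision is made).
    """
    out = []
    for f, start in enumerate(frame_starts_s):
        end = start + window_s
        w = int(round((end - epoch_t0) / WINDOW_S)) - 1
        sub = psd_table[psd_table["frame"] == w].copy()
        sub["frame"] = f
        out.append(sub)
    return pd.concat(out, ignore_index=True)
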