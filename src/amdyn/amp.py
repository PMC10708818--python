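"""Windowed amplitude-modulation power (AMP) features.

Each 16 s epoch is covered by 4 s analysis frames advancing in 1 s
steps (3 s overlap), so a fresh decision frame is available every
second after the initial buffer; 11 frames are retained per trial.
Within a frame, each valid AM series contributes its mean-square power,
and the 14 powers of one channel/frame are normalized to sum to one —
AMP features are relative modulation power, invariant to overall signal
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .am import AMSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 4.0   # s
DEFAULT_HOP = 1.0      # s
DEFAULT_N_FRAMES = 11


@dataclass(frozen=True)
class FrameGrid:
    """Placement of analysis frames within an epoch.

    ``starts``/``ends`` are in seconds on the epoch's time axis
    (task onset = 0, epoch begins at -1 s); windows are half-open.
    """

    window: float
    hop: float
    starts: tuple[float, ...]

    @property
    def ends(self) -> tuple[float, ...]:
        return tuple(s + self.window for s in self.starts)

    @property
    def n_frames(self) -> int:
        return len(self.starts)

    def sample_slices(self, fs: float, t0: float, n_samples: int):
        """Half-open sample ranges for each frame at sampling rate fs."""
        out = []
        for s in self.starts:
            i0 = int(round((s - t0) * fs))
            i1 = i0 + int(round(self.window * fs))
            if i0 < 0 or i1 > n_samples:
                raise IndexError(
                    f"frame [{s}, {s + self.window}) s outside epoch of "
                    f"{n_samples} samples starting at {t0} s"
                )
            out.append(slice(i0, i1))
        return out


def frame_windows(epoch_duration: float = 16.0,
                  window: float = DEFAULT_WINDOW,
                  hop: float = DEFAULT_HOP,
                  t0: float = -1.0,
                  n_frames: int | None = DEFAULT_N_FRAMES) -> FrameGrid:
    """Build the frame grid for an epoch.

    The first window starts at the epoch start and subsequent windows
    advance by ``hop``; of the windows that fit, the first ``n_frames``
    are retained (default 11 on a 16 s epoch: starts -1, 0, ..., +9 s).
    ``n_frames=None`` keeps every window that fits (dense placement).
    """
    if window > epoch_duration:
        raise ValueError(
            f"window {window} s exceeds epoch duration {epoch_duration} s"
        )
    n_fit = int(np.floor((epoch_duration - window) / hop + 1e-9)) + 1
    if n_frames is None:
        n_keep = n_fit
    else:
        if n_frames > n_fit:
            raise ValueError(
                f"requested {n_frames} frames but only {n_fit} windows of "
                f"{window} s at hop {hop} s fit in {epoch_duration} s"
            )
        n_keep = n_frames
    starts = tuple(t0 + i * hop for i in range(n_keep))
    return FrameGrid(window=window, hop=hop, starts=starts)


def amp_power(am_series: np.ndarray, grid: FrameGrid, fs: float,
              t0: float = -1.0) -> np.ndarray:
    """Per-frame raw AM power: mean of squared samples in each window."""
    am_series = np.asarray(am_series, dtype=float)
    slices = grid.sample_slices(fs, t0, am_series.shape[-1])
    return np.array([np.mean(am_series[sl] ** 2) for sl in slices])


def normalize_frame(powers: np.ndarray) -> np.ndarray:
    """Normalize one channel/frame's AM powers to sum to one.

    An all-zero frame is returned as zeros with a warning rather than
    dividing by zero.
    """
    powers = np.asarray(powers, dtype=float)
    if (powers < 0).any():
        raise ValueError("AM powers must be nonnegative")
    total = powers.sum()
    if total == 0:
        logger.warning("all-zero AM power frame: emitting zeros")
        return np.zeros_like(powers)
    return powers / total


def amp_features(amset: AMSet, grid: FrameGrid | None = None,
                 log_scale: bool = False) -> pd.DataFrame:
    """AMP feature table for one epoch's AM decomposition.

    Returns a long-format frame with columns participant, session,
    trial, task, frame, feature_name, value.  Feature names follow
    ``AMP__<channel>__<carrier>_m<modulant>``.
    """
    if grid is None:
        grid = frame_windows()
    ep = amset.epoch
    if ep is None:
        raise ValueError("AMSet was built without its source epoch")
    rows = []
    for ch in amset.channel_labels:
        raw = np.stack([
            amp_power(amset.series[ch][name], grid, amset.fs, ep.t0)
            for name in amset.pair_names
        ])  # (n_pairs, n_frames)
        for f in range(grid.n_frames):
            vals = normalize_frame(raw[:, f])
            if log_scale:
                vals = np.log(vals + 1e-10)
            for name, v in zip(amset.pair_names, vals):
                rows.append((ep.participant, ep.session, ep.trial, ep.task,
                             f, f"AMP__{ch}__{name}", v))
    return pd.DataFrame(rows, columns=[
        "participant", "session", "trial", "task", "frame",
        "feature_name", "value",
    ])
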