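"""Feature-extraction pipeline: epochs -> long feature table -> wide matrix.

A classification *sample* is one 4 s analysis frame of one trial; its
AMP and CCORAM features are computed on that frame and its PSD features
are those of the 1 s window ending at the frame's end.  Long tables use
columns (participant, session, trial, task, frame, feature_name, value)
and are written/read as plain CSV.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .am import CANONICAL_BANK, am_decompose
from .amp import FrameGrid, amp_features, frame_windows
from .ccoram import DEFAULT_ELECTRODES, ccoram_features
from .data import Epoch
from .psd import align_psd_to_frames, psd_features

logger = logging.getLogger(__name__)

SAMPLE_COLS = ["participant", "session", "trial", "frame"]


def extract_feature_table(epochs: Iterable[Epoch],
                          kinds: Sequence[str] = ("AMP", "PSD"),
                          bank=CANONICAL_BANK,
                          grid: FrameGrid | None = None,
                          electrodes=DEFAULT_ELECTRODES) -> pd.DataFrame:
    """Extract the requested feature kinds for every epoch.

    ``kinds`` is any subset of {"AMP", "CCORAM", "PSD"}.  The AM
    decomposition is shared between AMP and CCORAM.
    """
    kinds = tuple(k.upper() for k in kinds)
    unknown = set(kinds) - {"AMP", "CCORAM", "PSD"}
    if unknown:
        raise ValueError(f"unknown feature kinds {sorted(unknown)}")
    if grid is None:
        grid = frame_windows()
    parts: list[pd.DataFrame] = []
    for ep in epochs:
        amset = None
        if "AMP" in kinds or "CCORAM" in kinds:
            amset = am_decompose(ep, bank)
        if "AMP" in kinds:
            parts.append(amp_features(amset, grid))
        if "CCORAM" in kinds:
            parts.append(ccoram_features(amset, electrodes, grid))
        if "PSD" in kinds:
            tbl = psd_features(ep)
            parts.append(align_psd_to_frames(tbl, grid.starts, grid.window,
                                             ep.t0))
    return pd.concat(parts, ignore_index=True)


def to_wide(long_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot a long feature table into (X, y).

    X is samples x features; y is the task label per sample.  Features
    that are NaN for a sample (degenerate connectivity frames) stay NaN
    and are expected to be handled by the selection stage.
    """
    wide = (long_table.set_index(SAMPLE_COLS + ["task", "feature_name"])
            ["value"].unstack("feature_name"))
    y = wide.index.get_level_values("task").to_series(index=wide.index)
    X = wide.reset_index(drop=True)
    X.columns.name = None
    y = y.reset_index(drop=True)
    return X, y


def filter_kinds(X: pd.DataFrame, kinds: Sequence[str]) -> pd.DataFrame:
    """Column subset of a wide matrix by feature-type prefix."""
    prefixes = tuple(f"{k.upper()}__" for k in kinds)
    cols = [c for c in X.columns if c.startswith(prefixes)]
    return X[cols]
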