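"""Phase circular correlation of AM signals (CCORAM) connectivity.

For an electrode pair, the instantaneous phases of the two channels'
AM series in one band are compared with the Jammalamadaka-SenGupta
circular correlation coefficient.  Unlike phase-locking value, the
statistic measures phase *co-variation* about the circular means, so
coincidental constant-lag synchrony at a shared rhythm does not by
itself saturate it.  Phases are computed per 4 s analysis frame (the
same grid as the AMP features) from the mean-removed AM series.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .am import AMSet
from .amp import FrameGrid, frame_windows

logger = logging.getLogger(__name__)

#: Default electrode subset: a spatial-span-maximizing selection of ten
#: electrodes from the 10-20 layout avoiding adjacent sites.
DEFAULT_ELECTRODES: tuple[str, ...] = (
    "F7", "F8", "T7", "T8", "C3", "C4", "P7", "P8", "O1", "O2",
)


def instantaneous_phase(am_series: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal of the mean-removed AM series.

    Radians, wrapped to (-pi, pi].  A constant series has no phase and
    raises.
    """
    x = np.asarray(am_series, dtype=float)
    x = x - x.mean()
    if np.ptp(x) == 0:
        raise ValueError("constant AM series has no instantaneous phase")
    return np.angle(sps.hilbert(x))


def _circular_mean(phi: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * phi))))


def circular_correlation(phi1: np.ndarray, phi2: np.ndarray) -> float:
    """Jammalamadaka-SenGupta circular correlation of two phase series.

    rho = sum sin(phi1 - mu1) sin(phi2 - mu2) /
          sqrt(sum sin^2(phi1 - mu1) * sum sin^2(phi2 - mu2))

    with mu_i the circular means; rho is in [-1, 1].
    """
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    if phi1.shape != phi2.shape:
        raise ValueError("phase series must have equal length")
    if phi1.size < 8:
        raise ValueError("need at least 8 phase samples")
    s1 = np.sin(phi1 - _circular_mean(phi1))
    s2 = np.sin(phi2 - _circular_mean(phi2))
    denom = np.sqrt(np.sum(s1 ** 2) * np.sum(s2 ** 2))
    if denom == 0:
        raise ValueError("degenerate phase series (all at circular mean)")
    rho = float(np.sum(s1 * s2) / denom)
    return float(np.clip(rho, -1.0, 1.0))


def ccoram_pair_frame(x1: np.ndarray, x2: np.ndarray) -> float:
    """CCORAM of two AM-series windows; NaN when a window is degenerate."""
    try:
        return circular_correlation(instantaneous_phase(x1),
                                    instantaneous_phase(x2))
    except ValueError:
        return float("nan")


def ccoram_features(amset: AMSet,
                    electrodes=DEFAULT_ELECTRODES,
                    grid: FrameGrid | None = None) -> pd.DataFrame:
    """CCORAM feature table for one epoch's AM decomposition.

    For each frame, each unordered electrode pair, and each valid AM
    band: the circular correlation of the two windowed phase series.
    Degenerate frames are emitted as NaN (dropped with a logged count at
    the selection stage).  Feature names follow
    ``CCORAM__<ch1>-<ch2>__<carrier>_m<modulant>``.
    """
    if grid is None:
        grid = frame_windows()
    ep = amset.epoch
    if ep is None:
        raise ValueError("AMSet was built without its source epoch")
    missing = [ch for ch in electrodes if ch not in amset.channel_labels]
    if missing:
        raise KeyError(f"electrode subset channels absent from AMSet: {missing}")
    slices = grid.sample_slices(amset.fs, ep.t0,
                                next(iter(amset.series[electrodes[0]].values())).shape[-1])
    rows = []
    n_degenerate = 0
    for ch1, ch2 in combinations(electrodes, 2):
        for name in amset.pair_names:
            s1 = amset.series[ch1][name]
            s2 = amset.series[ch2][name]
            for f, sl in enumerate(slices):
                rho = ccoram_pair_frame(s1[sl], s2[sl])
                if np.isnan(rho):
                    n_degenerate += 1
                rows.append((ep.participant, ep.session, ep.trial, ep.task,
                             f, f"CCORAM__{ch1}-{ch2}__{name}", rho))
    if n_degenerate:
        logger.warning("%d degenerate CCORAM frames emitted as NaN",
                       n_degenerate)
    return pd.DataFrame(rows, columns=[
        "participant", "session", "trial", "task", "frame",
        "feature_name", "value",
    ])
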