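"""Continuous-recording pre-processing and epoching.

The standard chain for a raw recording is: re-reference (single channel
or common average), 59-61 Hz power-line notch, 0.1-50 Hz band-pass,
optional resampling to the 256 Hz working rate, then extraction of 16 s
epochs running from 1 s before each task onset to 15 s after it.  An
``artifact_hook`` slot accepts an external epochs-in/epochs-out callable
(e.g. an ICA-based cleaner); the package itself performs no artifact
rejection.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .data import EPOCH_T_END, EPOCH_T_START, Epoch, EventTable, Recording
from .filters import design_bandstop, zero_phase_filter

logger = logging.getLogger(__name__)

#: Default working sampling rate, Hz.  Comfortably above twice the 50 Hz
#: analysis ceiling while keeping filter lengths and runtime bounded.
WORKING_FS = 256.0


def rereference(rec: Recording, mode: str = "common_average",
                channel: str | None = None) -> Recording:
    """Re-reference a recording.

    ``mode="single_channel"`` subtracts the named channel's signal from
    every channel; ``mode="common_average"`` subtracts the per-sample
    mean across channels.
    """
    if mode == "single_channel":
        if channel is None:
            raise ValueError("single_channel mode requires a channel label")
        idx = rec.channel_index(channel)
        ref = rec.data[idx]
        return rec.copy_with(data=rec.data - ref, reference=channel)
    if mode == "common_average":
        return rec.copy_with(data=rec.data - rec.data.mean(axis=0),
                             reference="common_average")
    raise ValueError(f"unknown re-reference mode {mode!r}")


def notch_filter(rec: Recording, f_lo: float = 59.0,
                 f_hi: float = 61.0) -> Recording:
    """Zero-phase band-stop removing power-line interference."""
    taps = design_bandstop(f_lo, f_hi, rec.fs)
    return rec.copy_with(data=zero_phase_filter(rec.data, taps))


def bandpass_fir(rec: Recording, f_lo: float = 0.1,
                 f_hi: float = 50.0) -> Recording:
    """Zero-phase broadband FIR band-pass (drift and HF noise removal).

    A 0.1 Hz lower edge at a practical filter length leaves the cutoff
    transition straddling DC, so after the windowed design the taps are
    adjusted to exact zero DC gain (subtracting the tap mean); the
    perturbation elsewhere is a fraction of a percent while constant
    offsets and slow drift are removed completely.
    """
    if f_hi >= rec.fs / 2:
        raise ValueError(f"f_hi={f_hi} not below Nyquist for fs={rec.fs}")
    from scipy import signal as sps

    width = 2.0
    numtaps = int(np.ceil(3.3 * rec.fs / width))
    numtaps += 1 - numtaps % 2
    taps = sps.firwin(numtaps, [max(f_lo, 1e-3), f_hi + width / 2],
                      window="hamming", pass_zero=False, fs=rec.fs)
    taps = taps - taps.sum() / len(taps)  # exact DC null
    return rec.copy_with(data=zero_phase_filter(rec.data, taps))


def resample(rec: Recording, fs_new: float = WORKING_FS) -> Recording:
    """Polyphase resampling to the working rate (no-op if already there)."""
    if abs(rec.fs - fs_new) < 1e-9:
        return rec
    from fractions import Fraction

    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return rec.copy_with(data=data, fs=float(fs_new))


def extract_epochs(rec: Recording, events: EventTable,
                   t_start: float = EPOCH_T_START,
                   t_end: float = EPOCH_T_END,
                   on_out_of_bounds: str = "skip") -> list[Epoch]:
    """Slice one epoch per event on the half-open window
    [onset + t_start, onset + t_end).

    Onsets are mapped to the nearest sample (0-based).  Events whose
    window falls outside the recording are skipped with a warning by
    default (``on_out_of_bounds="error"`` raises instead).
    """
    n_win = int(round((t_end - t_start) * rec.fs))
    epochs: list[Epoch] = []
    skipped = 0
    for trial, row in enumerate(events.table.itertuples(index=False)):
        start = int(round((row.onset_s + t_start) * rec.fs))
        stop = start + n_win
        if start < 0 or stop > rec.n_samples:
            if on_out_of_bounds == "error":
                raise ValueError(
                    f"event at {row.onset_s} s: window [{start}, {stop}) "
                    f"outside recording of {rec.n_samples} samples"
                )
            logger.warning("skipping event at %.3f s: epoch window out of "
                           "bounds", row.onset_s)
            skipped += 1
            continue
        epochs.append(Epoch(
            signal=rec.data[:, start:stop].copy(),
            fs=rec.fs,
            channel_labels=list(rec.channel_labels),
            task=str(row.task),
            participant=str(row.participant),
            session=str(row.session),
            trial=trial,
            t0=t_start,
        ))
    logger.info("extracted %d epochs (%d skipped) from %d events",
                len(epochs), skipped, len(events))
    return epochs


def preprocess(rec: Recording, events: EventTable, *,
               reference: str = "common_average",
               reference_channel: str | None = None,
               notch: tuple[float, float] | None = (59.0, 61.0),
               bandpass: tuple[float, float] = (0.1, 50.0),
               working_fs: float = WORKING_FS,
               channel_mask: Sequence[str] | None = None,
               artifact_hook: Callable[[list[Epoch]], list[Epoch]] | None = None,
               ) -> list[Epoch]:
    """Full default chain: mask -> re-reference -> notch -> band-pass ->
    resample -> epoch -> optional artifact hook."""
    if channel_mask is not None:
        keep = [i for i, c in enumerate(rec.channel_labels)
                if c not in set(channel_mask)]
        rec = rec.copy_with(
            data=rec.data[keep],
            channel_labels=[rec.channel_labels[i] for i in keep],
        )
    rec = rereference(rec, mode=reference, channel=reference_channel)
    if notch is not None and notch[1] < rec.fs / 2:
        rec = notch_filter(rec, *notch)
    rec = bandpass_fir(rec, *bandpass)
    rec = resample(rec, working_fs)
    epochs = extract_epochs(rec, events)
    if artifact_hook is not None:
        epochs = artifact_hook(epochs)
    return epochs
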