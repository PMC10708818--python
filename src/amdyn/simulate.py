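"""Synthetic multi-task EEG with known amplitude-modulation ground truth.

A recording is 1/f^beta background noise plus, during each 15 s task
segment, band-limited oscillatory components whose envelopes are driven
by a sinusoidal modulator of prescribed frequency and depth:

    x(t) = amplitude * (1 + depth * sin(phi_m(t))) * carrier(t)

The carrier is narrowband-filtered Gaussian noise centred on
``carrier_hz`` (a pure-tone mode exists for closed-form tests); the
modulator phase ``phi_m`` advances at 2*pi*modulant_hz plus a Wiener
phase-diffusion term, so modulators on different channels decorrelate
unless the channels are placed in a coupling group sharing one phase
process.  The trial protocol mirrors a typical mental-task session:
30 s leading baseline, randomized task order, 15 s task segments, and
rest gaps drawn uniformly from 10-15 s.

Everything is reproducible from (specs, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bands import BandSpec
from .data import TASKS, EventTable, Recording
from .filters import design_band_filter, hilbert_envelope, zero_phase_filter

logger = logging.getLogger(__name__)

DEFAULT_CHANNELS: tuple[str, ...] = (
    "F7", "F8", "T7", "T8", "C3", "C4", "P7", "P8", "O1", "O2",
)

TASK_S = 15.0          # task segment length, s
REST_RANGE = (10.0, 15.0)
BASELINE_S = 30.0


@dataclass(frozen=True)
class ComponentSpec:
    """One amplitude-modulated oscillatory component."""

    carrier_hz: float
    modulant_hz: float
    depth: float
    amplitude: float = 1.0
    carrier_bw: float = 4.0        # Hz, full bandwidth of the noise carrier
    pure_tone: bool = False
    phase_diffusion: float = 0.5   # rad^2/s Wiener rate of the modulator

    def __post_init__(self) -> None:
        if not 0 <= self.depth <= 1:
            raise ValueError(f"modulation depth must be in [0, 1], got {self.depth}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class TaskSpec:
    """Signal recipe for one mental task."""

    task: str
    components: tuple[ComponentSpec, ...]
    channel_gains: tuple[tuple[str, float], ...] | None = None  # None -> 1.0
    coupling_groups: tuple[frozenset, ...] = ()
    background_exponent: float = 1.0
    background_level: float = 1.0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task {self.task!r} not in {TASKS}")
        if self.channel_gains is not None:
            for _, g in self.channel_gains:
                if g < 0:
                    raise ValueError("channel gains must be >= 0")

    def gain(self, channel: str) -> float:
        if self.channel_gains is None:
            return 1.0
        return dict(self.channel_gains).get(channel, 0.0)


@dataclass
class SyntheticDataset:
    """A generated recording with its ground-truth recipe."""

    recording: Recording
    events: EventTable
    specs: tuple[TaskSpec, ...]
    seed: int


def modulator_phase(modulant_hz: float, n: int, fs: float,
                    rng: np.random.Generator,
                    phase_diffusion: float = 0.5) -> np.ndarray:
    """Modulator phase 2*pi*f_m*t + phi0 + W(t) (Wiener diffusion)."""
    t = np.arange(n) / fs
    phi0 = rng.uniform(0, 2 * np.pi)
    if phase_diffusion > 0:
        steps = rng.normal(0, np.sqrt(phase_diffusion / fs), n)
        walk = np.cumsum(steps)
    else:
        walk = 0.0
    return 2 * np.pi * modulant_hz * t + phi0 + walk


def _narrowband_carrier(carrier_hz: float, bw: float, n: int, fs: float,
                        rng: np.random.Generator) -> np.ndarray:
    band = BandSpec("carrier", max(carrier_hz - bw / 2, 0.1),
                    carrier_hz + bw / 2)
    taps = design_band_filter(band, fs)
    white = rng.standard_normal(n + 2 * len(taps))
    x = zero_phase_filter(white, taps)[len(taps):len(taps) + n]
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synth_component(spec: ComponentSpec, duration: float, fs: float,
                    rng: np.random.Generator,
                    phase_m: np.ndarray | None = None,
                    carrier: np.ndarray | None = None) -> np.ndarray:
    """Generate one AM component.

    ``phase_m`` and ``carrier`` inject a shared modulator phase and
    carrier realization (coupling groups: one source seen at several
    electrodes); when omitted fresh processes are drawn from ``rng``.
    """
    nyq = fs / 2
    if spec.carrier_hz + spec.carrier_bw / 2 >= nyq or spec.modulant_hz >= nyq:
        raise ValueError("carrier or modulant outside Nyquist")
    n = int(round(duration * fs))
    if phase_m is None:
        phase_m = modulator_phase(spec.modulant_hz, n, fs, rng,
                                  spec.phase_diffusion)
    envelope = 1.0 + spec.depth * np.sin(phase_m)
    if carrier is None:
        if spec.pure_tone:
            phi_c = rng.uniform(0, 2 * np.pi)
            t = np.arange(n) / fs
            carrier = np.sin(2 * np.pi * spec.carrier_hz * t + phi_c)
        else:
            carrier = _narrowband_carrier(spec.carrier_hz, spec.carrier_bw,
                                          n, fs, rng)
    return spec.amplitude * envelope * carrier


def one_over_f_noise(n: int, fs: float, rng: np.random.Generator,
                     exponent: float = 1.0) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^exponent amplitude spectrum."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = (rng.standard_normal(len(freqs))
            + 1j * rng.standard_normal(len(freqs)))
    with np.errstate(divide="ignore"):
        shape = np.where(freqs > 0, freqs ** (-exponent / 2), 0.0)
    x = np.fft.irfft(spec * shape, n)
    return x / np.sqrt(np.mean(x ** 2))


def _segment_sources(spec: TaskSpec, comp: ComponentSpec, channels,
                     duration: float, fs: float, rng: np.random.Generator):
    """One AM source (modulator phase + carrier realization) per channel.

    Channels in the same coupling group share one source — the
    common-cortical-source picture of inter-channel AM phase coupling —
    while every other channel draws an independent source.  Draw order
    is fixed by channel order so output is deterministic."""
    group_of = {}
    for gi, grp in enumerate(spec.coupling_groups):
        for ch in grp:
            group_of[ch] = gi
    group_sig: dict[int, np.ndarray] = {}
    out = {}
    for ch in channels:
        if spec.gain(ch) == 0:
            continue
        gi = group_of.get(ch)
        if gi is None:
            out[ch] = synth_component(comp, duration, fs, rng)
        else:
            if gi not in group_sig:
                group_sig[gi] = synth_component(comp, duration, fs, rng)
            out[ch] = group_sig[gi]
    return out


def generate_dataset(specs, n_trials_per_task: int, fs: float = 256.0,
                     seed: int = 0, channels=DEFAULT_CHANNELS,
                     rest_range: tuple[float, float] = REST_RANGE,
                     baseline_s: float = BASELINE_S) -> SyntheticDataset:
    """Generate a continuous multi-task recording with event markers."""
    specs = tuple(specs)
    if not specs:
        raise ValueError("need at least one TaskSpec")
    if n_trials_per_task < 1:
        raise ValueError("n_trials_per_task must be >= 1")
    exps = {s.background_exponent for s in specs}
    lvls = {s.background_level for s in specs}
    if len(exps) > 1 or len(lvls) > 1:
        raise ValueError("background settings must agree across task specs")
    channels = tuple(channels)
    rng = np.random.default_rng(seed)

    order = [s for s in specs for _ in range(n_trials_per_task)]
    rng.shuffle(order)

    onsets = []
    t = baseline_s
    for _ in order:
        onsets.append(t)
        t += TASK_S + rng.uniform(*rest_range)
    total_s = t + 5.0
    n_total = int(round(total_s * fs))

    data = np.empty((len(channels), n_total))
    for ci in range(len(channels)):
        data[ci] = specs[0].background_level * one_over_f_noise(
            n_total, fs, rng, specs[0].background_exponent)

    n_seg = int(round(TASK_S * fs))
    ramp_n = int(round(0.25 * fs))
    taper = np.ones(n_seg)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n)))
    taper[:ramp_n] = ramp
    taper[-ramp_n:] = ramp[::-1]

    for onset, spec in zip(onsets, order):
        i0 = int(round(onset * fs))
        for comp in spec.components:
            sources = _segment_sources(spec, comp, channels, TASK_S, fs, rng)
            for ci, ch in enumerate(channels):
                g = spec.gain(ch)
                if g == 0:
                    continue
                data[ci, i0:i0 + n_seg] += g * taper * sources[ch]

    events = EventTable.from_rows([
        (onset, spec.task, "S1", "1") for onset, spec in zip(onsets, order)
    ])
    rec = Recording(channel_labels=list(channels), fs=float(fs), data=data,
                    reference="synthetic")
    return SyntheticDataset(recording=rec, events=events, specs=specs,
                            seed=seed)


def estimate_depth(x: np.ndarray, fs: float, trim_s: float = 1.0) -> float:
    """Estimate sinusoidal modulation depth from the Hilbert envelope.

    For env = A(1 + d sin phi), d = sqrt(2) * std(env) / mean(env) on
    the interior (edges trimmed).
    """
    env = hilbert_envelope(np.asarray(x, dtype=float))
    k = int(round(trim_s * fs))
    env = env[k:-k] if k > 0 else env
    return float(np.sqrt(2) * env.std() / env.mean())


# ---------------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------------

def am_contrast_specs(depth: float = 0.7, amplitude: float = 1.0,
                      carrier_hz: float = 40.0, carrier_bw: float = 2.0,
                      modulants: tuple[float, float] = (2.0, 6.0),
                      background_level: float = 1.0,
                      tasks: tuple[str, str] = ("ROT", "WORD"),
                      ) -> tuple[TaskSpec, TaskSpec]:
    """The AM-only contrast: two tasks with identical band powers that
    differ only in modulant frequency.

    The carrier sits at 39-41 Hz, inside the 30-50 Hz region where the
    baseline PSD band set has no sub-band resolution.  The narrow 2 Hz
    carrier bandwidth keeps all half-power spectral content — carrier,
    filter skirts, and modulation sidebands at the fastest modulant —
    inside 31-49 Hz, so every PSD band power is identical across tasks
    by construction; only the AM decomposition (gamma-mdelta vs
    gamma-mtheta) can tell them apart.
    """
    def spec(task, f_m):
        return TaskSpec(
            task=task,
            components=(ComponentSpec(carrier_hz=carrier_hz,
                                      modulant_hz=f_m, depth=depth,
                                      amplitude=amplitude,
                                      carrier_bw=carrier_bw),),
            background_level=background_level,
        )
    return spec(tasks[0], modulants[0]), spec(tasks[1], modulants[1])


def coupling_specs(coupled: frozenset = frozenset({"C3", "C4"}),
                   carrier_hz: float = 10.0, modulant_hz: float = 2.0,
                   depth: float = 0.8, amplitude: float = 2.0,
                   task: str = "MI",
                   background_level: float = 0.5,
                   phase_diffusion: float = 5.0) -> tuple[TaskSpec]:
    """Planted inter-channel AM phase coupling: every channel carries an
    alpha-band AM component, but only the coupled set shares one source.

    The modulator diffuses at 5 rad^2/s so independent channels' AM
    phases wander apart by several radians within one 4 s analysis
    frame; without that, same-frequency modulators would differ only by
    a constant offset and spuriously correlate.
    """
    return (TaskSpec(
        task=task,
        components=(ComponentSpec(carrier_hz=carrier_hz,
                                  modulant_hz=modulant_hz, depth=depth,
                                  amplitude=amplitude, carrier_bw=2.0,
                                  phase_diffusion=phase_diffusion),),
        coupling_groups=(frozenset(coupled),),
        background_level=background_level,
    ),)
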