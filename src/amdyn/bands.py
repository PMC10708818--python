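"""Frequency-band definitions used throughout the package.

Two band sets coexist: the five-band amplitude-modulation filter bank
(delta/theta/alpha/beta/gamma) used for the two-stage AM decomposition,
and the finer band set used for the baseline power-spectral-density
features (alpha and beta split into sub-bands, plus two broad bands and
two power ratios).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi}]"
            )

    @property
    def bandwidth(self) -> float:
        return self.f_hi - self.f_lo

    def check_nyquist(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_hi} Hz is not below "
                f"Nyquist ({fs / 2} Hz) for fs={fs}"
            )


#: The canonical five-band AM filter bank.
CANONICAL_BANK: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 50.0),
)


def validate_bank(bank: tuple[BandSpec, ...] | list[BandSpec]) -> tuple[BandSpec, ...]:
    """Check a filter bank is ordered by lower edge; return it as a tuple."""
    bank = tuple(bank)
    if not bank:
        raise ValueError("filter bank is empty")
    los = [b.f_lo for b in bank]
    if los != sorted(los):
        raise ValueError("filter bank bands must be ordered by f_lo")
    return bank


#: Bands for the baseline PSD features.  broad1 is printed as
#: "theta to beta (8-30 Hz)" in the source band table and broad2 as
#: "delta to gamma (0-50 Hz)"; both are implemented literally by edge.
PSD_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha1", 8.0, 10.0),
    BandSpec("alpha2", 10.0, 12.0),
    BandSpec("beta1", 12.0, 21.0),
    BandSpec("beta2", 21.0, 30.0),
    BandSpec("broad1", 8.0, 30.0),
    BandSpec("broad2", 0.0, 50.0),
)

#: Ratio features: name -> (numerator band edges, denominator band edges).
PSD_RATIOS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "alpha_beta_ratio": ((8.0, 12.0), (12.0, 30.0)),
    "theta_beta_ratio": ((4.0, 8.0), (12.0, 30.0)),
}
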