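"""Canonical EEG frequency bands.

Bands follow the conventional clinical partition: delta, theta, alpha, beta,
gamma.  The delta lower edge is set to 0.5 Hz (not 0) so that every sub-band
filter is a proper band-pass, and the gamma upper edge to 50 Hz to match the
acquisition band of the recordings the simulator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band ``[f_lo, f_hi)`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi})"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


DELTA = BandSpec("delta", 0.5, 4.0)
THETA = BandSpec("theta", 4.0, 8.0)
ALPHA = BandSpec("alpha", 8.0, 13.0)
BETA = BandSpec("beta", 13.0, 30.0)
GAMMA = BandSpec("gamma", 30.0, 50.0)

#: All five bands, in ascending frequency order.
ALL_BANDS: tuple[BandSpec, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

#: The four sub-bands used for the nonlinear feature set and the band-power
#: ratio features (gamma excluded).
SUB_BANDS: tuple[BandSpec, ...] = (DELTA, THETA, ALPHA, BETA)

BAND_BY_NAME: dict[str, BandSpec] = {b.name: b for b in ALL_BANDS}
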