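"""Electrode montage and frequency-band conventions.

The 32-channel layout follows the DEAP recording order; the 14 homologous
(right, left) electrode pairs are the classic hemispheric-asymmetry pairs,
listed right-hemisphere channel first so that an asymmetry feature is
``right - left``.
"""

from __future__ import annotations

from dataclasses import dataclass

#: DEAP EEG channel order (indices 0..31 of the data array's channel axis).
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Homologous (right, left) electrode pairs used for asymmetry features.
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp2", "Fp1"), ("AF4", "AF3"), ("F4", "F3"), ("F8", "F7"),
    ("FC6", "FC5"), ("FC2", "FC1"), ("C4", "C3"), ("T8", "T7"),
    ("CP6", "CP5"), ("CP2", "CP1"), ("P4", "P3"), ("P8", "P7"),
    ("PO4", "PO3"), ("O2", "O1"),
)


@dataclass(frozen=True)
class BandDef:
    """A frequency band ``[f_lo, f_hi)`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )


#: Canonical band set, in feature order.
BANDS: tuple[BandDef, ...] = (
    BandDef("theta", 4.0, 8.0),
    BandDef("slow_alpha", 8.0, 10.0),
    BandDef("alpha", 8.0, 12.0),
    BandDef("beta", 12.0, 30.0),
    BandDef("gamma", 30.0, 45.0),
)

#: Bands entering the asymmetry features (slow-alpha excluded).
ASYM_BANDS: tuple[BandDef, ...] = tuple(
    b for b in BANDS if b.name in ("theta", "alpha", "beta", "gamma")
)

BAND_BY_NAME: dict[str, BandDef] = {b.name: b for b in BANDS}

CHANNEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(CHANNELS_32)}
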