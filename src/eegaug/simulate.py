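"""Synthetic DEAP-shaped EEG generator.

Every trial is a sum of band-limited oscillatory components (zero-phase
4th-order Butterworth-filtered white noise per band) plus broadband noise,
with amplitudes coupled to a latent two-dimensional emotion state:

* ``arousal_level`` scales beta and gamma amplitude up and alpha amplitude
  down (coupling coefficients live in :attr:`SynthConfig.band_effects`);
* ``valence_level`` tilts the right/left alpha amplitude ratio on the 14
  homologous channel pairs (:attr:`SynthConfig.asym_effect`).

These couplings are a simulator convention chosen so that all three feature
families (band PSD, hemispheric asymmetry, time-domain statistics) carry a
recoverable signal; they are not a neurophysiological claim.  Self-assessment
ratings on the 0-9 scale are noisy affine readouts of the latent levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import signal as _sig

from .channels import BAND_BY_NAME, CHANNELS_32, HOMOLOGOUS_PAIRS
from .io import ParticipantRecord

__all__ = [
    "SynthConfig",
    "LatentEmotion",
    "generate_trial",
    "generate_dataset",
    "iter_participants",
    "save_dataset",
]

#: Ratings column order used throughout (DEAP convention).
RATING_COLUMNS = ("valence", "arousal", "dominance", "liking")

#: Latent column order as drawn internally.
LATENT_COLUMNS = ("arousal", "valence", "dominance", "liking")


class ConfigurationError(ValueError):
    """Raised for an invalid :class:`SynthConfig`."""


@dataclass(frozen=True)
class LatentEmotion:
    """Latent emotion state in the unit square of the arousal-valence plane."""

    arousal_level: float
    valence_level: float

    def __post_init__(self) -> None:
        for name in ("arousal_level", "valence_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _default_band_effects() -> dict[str, tuple[float, float]]:
    # band -> (base amplitude, arousal coupling coefficient)
    return {
        "theta": (1.0, 0.0),
        "alpha": (1.5, -0.5),
        "beta": (0.8, 0.8),
        "gamma": (0.5, 0.6),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic EEG dataset generator.

    Defaults reproduce the DEAP recording geometry: 32 participants x 40
    trials x 32 channels x 8064 samples at 128 Hz (63 s per trial, of which
    the first 3 s are a pre-stimulus baseline).
    """

    n_participants: int = 32
    n_trials: int = 40
    n_channels: int = 32
    fs: float = 128.0
    duration_s: float = 63.0
    band_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_band_effects
    )
    asym_effect: float = 0.4
    noise_sd: float = 0.3
    rating_noise_sd: float = 0.5
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def validate(self) -> None:
        for name in ("n_participants", "n_trials", "n_channels"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.fs <= 2 * 45.0:
            raise ConfigurationError(
                f"fs must exceed twice the highest band edge (90 Hz), got {self.fs}"
            )
        if abs(self.duration_s * self.fs - round(self.duration_s * self.fs)) > 1e-9:
            raise ConfigurationError("duration_s * fs must be an integer")
        if self.noise_sd < 0 or self.rating_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        for name in self.band_effects:
            if name not in BAND_BY_NAME:
                raise ConfigurationError(f"unknown band {name!r} in band_effects")
        for name, (base, coup) in self.band_effects.items():
            if base < 0:
                raise ConfigurationError(f"band {name!r}: base amplitude must be >= 0")
            if abs(coup) >= 1:
                raise ConfigurationError(
                    f"band {name!r}: |arousal coupling| must be < 1 to keep "
                    "amplitudes positive"
                )

    @staticmethod
    def strong_coupling(**overrides) -> "SynthConfig":
        """Preset with strong emotion couplings and noiseless ratings.

        Used for planted-signal recovery checks where the latent state should
        be recoverable from features with high fidelity.
        """
        cfg = SynthConfig(
            band_effects={
                "theta": (1.0, 0.0),
                "alpha": (1.5, -0.7),
                "beta": (0.8, 0.9),
                "gamma": (0.5, 0.9),
            },
            asym_effect=1.0,
            noise_sd=0.1,
            rating_noise_sd=0.0,
        )
        return replace(cfg, **overrides) if overrides else cfg


#: Fractional inset of the Butterworth design edges inside the nominal band,
#: so that the -3 dB points sit inside [f_lo, f_hi] and spectral leakage
#: past the nominal edges is negligible.
_EDGE_INSET = 0.10


def _band_filter_gain(cfg: SynthConfig, f_lo: float, f_hi: float) -> np.ndarray:
    """Squared-magnitude (zero-phase, forward-backward) response of a
    4th-order Butterworth band-pass on the rFFT grid, normalised so
    unit-variance white noise filters to unit-variance output."""
    ns = cfg.n_samples
    freqs = np.fft.rfftfreq(ns, d=1.0 / cfg.fs)
    w = f_hi - f_lo
    sos = _sig.butter(
        4,
        [f_lo + _EDGE_INSET * w, f_hi - _EDGE_INSET * w],
        btype="bandpass",
        fs=cfg.fs,
        output="sos",
    )
    _, h = _sig.sosfreqz(sos, worN=freqs, fs=cfg.fs)
    h2 = np.abs(h) ** 2  # forward-backward filtering applies |H|^2
    # output variance for unit white noise = mean over the full FFT grid of h2^2
    wts = np.full(ns // 2 + 1, 2.0)
    wts[0] = 1.0
    if ns % 2 == 0:
        wts[-1] = 1.0
    var = float(np.sum(wts * h2**2) / ns)
    return h2 / np.sqrt(var)


def _pair_masks(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Boolean channel masks (right members, left members) of the 14 pairs."""
    right = np.zeros(cfg.n_channels, dtype=bool)
    left = np.zeros(cfg.n_channels, dtype=bool)
    if cfg.n_channels == len(CHANNELS_32):
        idx = {name: i for i, name in enumerate(CHANNELS_32)}
        for r, l in HOMOLOGOUS_PAIRS:
            right[idx[r]] = True
            left[idx[l]] = True
    else:
        # non-standard montage: alternate halves so the mechanism still exists
        half = cfg.n_channels // 2
        left[:half] = True
        right[half : 2 * half] = True
    return right, left


def _generate_block(
    latents: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Generate ``(n, n_channels, n_samples)`` EEG for latent rows
    ``latents[:, (arousal, valence)]``.

    Band components are synthesised spectrally: the rFFT of band-filtered
    white noise is a complex Gaussian with per-bin standard deviation
    proportional to the zero-phase filter gain, so each component is drawn
    directly in the frequency domain (on the bins where the gain is
    non-negligible) and all bands share one inverse FFT.  Draws are float32
    (EEG-scale data, dominated by physiological variability, does not
    benefit from double precision here).
    """
    from scipy import fft as _fft

    n = latents.shape[0]
    ns = cfg.n_samples
    nc = cfg.n_channels
    right, left = _pair_masks(cfg)
    arous = latents[:, 0]
    val = latents[:, 1]
    spec = np.zeros((n, nc, ns // 2 + 1), dtype=np.complex64)
    scale = np.sqrt(ns / 2.0)  # per-component sd of rfft of unit white noise
    for name, (base, coup) in cfg.band_effects.items():
        band = BAND_BY_NAME[name]
        h2 = _band_filter_gain(cfg, band.f_lo, band.f_hi)
        support = np.flatnonzero(h2 > 1e-8 * h2.max())
        support = support[(support > 0) & (support < ns // 2)]
        k = support.size
        amp = np.repeat(
            (base * (1.0 + coup * (2.0 * arous - 1.0)))[:, None], nc, axis=1
        )
        if name == "alpha" and cfg.asym_effect != 0.0:
            tilt = cfg.asym_effect * (2.0 * val - 1.0)  # (n,)
            amp[:, right] *= (1.0 + tilt / 2.0)[:, None]
            amp[:, left] *= (1.0 - tilt / 2.0)[:, None]
        re = rng.standard_normal((n, nc, k), dtype=np.float32)
        im = rng.standard_normal((n, nc, k), dtype=np.float32)
        comp = (re + 1j * im).astype(np.complex64)
        comp *= (scale * h2[support]).astype(np.float32)
        comp *= amp[:, :, None].astype(np.float32)
        spec[..., support] += comp
    out = _fft.irfft(spec, n=ns, axis=-1).astype(np.float64)
    if cfg.noise_sd > 0:
        out += cfg.noise_sd * rng.standard_normal((n, nc, ns), dtype=np.float32)
    return out


def generate_trial(
    latent: LatentEmotion, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Generate one trial of shape ``(n_channels, n_samples)``."""
    cfg.validate()
    lat = np.array([[latent.arousal_level, latent.valence_level]])
    return _generate_block(lat, cfg, rng)[0]


def _ratings_from_latents(
    latents: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Noisy 0-9 ratings in DEAP column order (valence, arousal, dom, liking)
    from latents in (arousal, valence, dominance, liking) order."""
    reorder = [1, 0, 2, 3]
    base = 9.0 * latents[:, reorder]
    if cfg.rating_noise_sd > 0:
        base = base + rng.normal(0.0, cfg.rating_noise_sd, size=base.shape)
    return np.clip(base, 0.0, 9.0)


def iter_participants(
    cfg: SynthConfig,
) -> Iterator[tuple[ParticipantRecord, np.ndarray]]:
    """Yield ``(record, latents)`` one participant at a time.

    ``latents`` is an ``(n_trials, 4)`` array in ``LATENT_COLUMNS`` order.
    Streaming keeps peak memory at one participant's data block; the full
    default geometry would otherwise hold ~2.6 GB at once.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    for pid in range(1, cfg.n_participants + 1):
        latents = rng.uniform(0.0, 1.0, size=(cfg.n_trials, 4))
        data = _generate_block(latents[:, :2], cfg, rng)
        ratings = _ratings_from_latents(latents, cfg, rng)
        yield ParticipantRecord(f"s{pid:02d}", data, ratings), latents


def generate_dataset(cfg: SynthConfig):
    """Generate the full dataset.

    Returns ``(records, latent_table)`` where ``records`` is a list of
    :class:`~eegaug.io.ParticipantRecord` and ``latent_table`` is a pandas
    DataFrame of the hidden per-trial latent levels (for parameter-recovery
    tests; it is never written next to feature files).
    """
    import pandas as pd

    records = []
    rows = []
    for record, latents in iter_participants(cfg):
        records.append(record)
        for t in range(cfg.n_trials):
            rows.append((record.participant_id, t, *latents[t]))
    latent_table = pd.DataFrame(
        rows, columns=["participant_id", "trial_index", *LATENT_COLUMNS]
    )
    return records, latent_table


def save_dataset(cfg: SynthConfig, out_dir: str | Path, write_latents: bool = True):
    """Generate and write one ``.npz`` per participant plus sidecar metadata.

    Each container holds two named arrays, ``data`` (trials x channels x
    samples) and ``ratings`` (trials x 4).  The hidden latent table, if
    requested, goes to a separate ``latents.csv``.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    paths = []
    for record, latents in iter_participants(cfg):
        path = out / f"{record.participant_id}.npz"
        np.savez(path, data=record.data, ratings=record.ratings)
        paths.append(path)
        for t in range(cfg.n_trials):
            rows.append((record.participant_id, t, *latents[t]))
    meta = {
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "n_trials": cfg.n_trials,
        "n_channels": cfg.n_channels,
        "fs": cfg.fs,
        "duration_s": cfg.duration_s,
        "band_effects": {k: list(v) for k, v in cfg.band_effects.items()},
        "asym_effect": cfg.asym_effect,
        "noise_sd": cfg.noise_sd,
        "rating_noise_sd": cfg.rating_noise_sd,
        "rating_columns": list(RATING_COLUMNS),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    if write_latents:
        pd.DataFrame(
            rows, columns=["participant_id", "trial_index", *LATENT_COLUMNS]
        ).to_csv(out / "latents.csv", index=False)
    return paths
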