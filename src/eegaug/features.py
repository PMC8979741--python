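"""344-dimensional per-trial feature vector from 32-channel EEG.

Layout (channel order and pair order in :mod:`eegaug.channels`):

* ``[0, 160)``   band-averaged Welch PSD, channel-major over 32 channels,
  band-minor over (theta, slow_alpha, alpha, beta, gamma);
* ``[160, 216)`` hemispheric asymmetry: right minus left band-averaged PSD
  for the 14 homologous pairs, pair-major, band-minor over
  (theta, alpha, beta, gamma);
* ``[216, 344)`` time-domain statistics per channel, channel-major over
  (mean, variance, zero-crossing count, mean absolute first difference).

The 344-feature layout reserves 128 slots for time-domain statistics, but
the classic trio (mean, variance, zero crossings) fills only 96 of them;
the mean absolute first difference is this package's choice of fourth
statistic, and ``statistics=("mean", "variance", "zcr")`` selects the
96-feature variant.

PSD estimation is Welch with 1-s Hann windows and 50 % overlap (1 Hz
resolution, so the 2-Hz-wide slow-alpha band always covers >= 2 bins), and
"average PSD" is the arithmetic mean of the density over the band's bins
using the half-open convention ``f_lo <= f < f_hi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .channels import ASYM_BANDS, BANDS, CHANNELS_32, CHANNEL_INDEX, BandDef
from .io import ShapeError, TrialTable

__all__ = [
    "PSDEstimate",
    "WelchParams",
    "compute_psd",
    "band_average_psd",
    "psd_features",
    "asymmetry_features",
    "zero_crossing_count",
    "time_domain_features",
    "extract_features",
    "feature_names",
    "FeatureScaler",
]

TIME_STATS_DEFAULT = ("mean", "variance", "zcr", "mean_abs_diff")


class ResolutionError(ValueError):
    """Band has no PSD bins; a longer Welch window is needed."""


@dataclass(frozen=True)
class WelchParams:
    window_s: float = 1.0
    overlap: float = 0.5
    window: str = "hann"


@dataclass
class PSDEstimate:
    """Welch PSD: frequency grid (Hz) and density (units^2/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray
    params: WelchParams = field(default_factory=WelchParams)


def compute_psd(
    x: np.ndarray, fs: float, params: WelchParams = WelchParams()
) -> PSDEstimate:
    """Welch averaged-periodogram PSD along the last axis.

    The integral of the density over [0, fs/2] approximates the signal's
    variance (Parseval) for stationary inputs.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(params.window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than the Welch window ({nperseg})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    freqs, psd = _sig.welch(
        x,
        fs=fs,
        window=params.window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * params.overlap)),
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return PSDEstimate(freqs, psd, params)


def band_average_psd(est: PSDEstimate, band: BandDef) -> np.ndarray:
    """Mean density over the band's bins (``f_lo <= f < f_hi``)."""
    mask = (est.freqs >= band.f_lo) & (est.freqs < band.f_hi)
    if not mask.any():
        raise ResolutionError(
            f"band {band.name!r} ({band.f_lo}-{band.f_hi} Hz) covers no PSD bins; "
            "use a longer Welch window"
        )
    return est.psd[..., mask].mean(axis=-1)


def _check_trial(trial: np.ndarray) -> np.ndarray:
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[0] != len(CHANNELS_32):
        raise ShapeError(
            f"trial must be ({len(CHANNELS_32)}, n_samples), got {trial.shape}"
        )
    return trial


def psd_features(
    trial: np.ndarray,
    fs: float,
    bands: tuple[BandDef, ...] = BANDS,
    params: WelchParams = WelchParams(),
) -> np.ndarray:
    """Band-averaged PSD per channel: 32 channels x 5 bands = 160 values,
    channel-major."""
    trial = _check_trial(trial)
    est = compute_psd(trial, fs, params)
    cols = np.stack([band_average_psd(est, b) for b in bands], axis=1)  # (32, nb)
    return cols.ravel()


def asymmetry_features(
    trial: np.ndarray,
    fs: float,
    bands: tuple[BandDef, ...] = ASYM_BANDS,
    params: WelchParams = WelchParams(),
) -> np.ndarray:
    """Right-minus-left band-averaged PSD for the 14 homologous pairs:
    14 pairs x 4 bands = 56 values, pair-major."""
    from .channels import HOMOLOGOUS_PAIRS

    trial = _check_trial(trial)
    est = compute_psd(trial, fs, params)
    band_avg = np.stack([band_average_psd(est, b) for b in bands], axis=1)
    out = np.empty((len(HOMOLOGOUS_PAIRS), len(bands)))
    for i, (r, l) in enumerate(HOMOLOGOUS_PAIRS):
        out[i] = band_avg[CHANNEL_INDEX[r]] - band_avg[CHANNEL_INDEX[l]]
    return out.ravel()


def zero_crossing_count(x: np.ndarray) -> int:
    """Count positive<->negative sign transitions; exact zeros are
    transparent (they neither create nor destroy a crossing)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D signal of length >= 2")
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _zcr_rows(trial: np.ndarray) -> np.ndarray:
    """Vectorised zero-transparent crossing count per channel row."""
    s = np.sign(trial)
    out = np.empty(trial.shape[0])
    for i in range(trial.shape[0]):  # per-channel; nonzero masks differ
        si = s[i][s[i] != 0]
        out[i] = np.count_nonzero(si[1:] != si[:-1]) if si.size > 1 else 0
    return out


def time_domain_features(
    trial: np.ndarray, statistics: tuple[str, ...] = TIME_STATS_DEFAULT
) -> np.ndarray:
    """Per-channel time-domain statistics, channel-major: default
    (mean, variance, zero-crossing count, mean |first difference|) -> 128."""
    trial = _check_trial(trial)
    if trial.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    values = {}
    if "mean" in statistics:
        values["mean"] = trial.mean(axis=1)
    if "variance" in statistics:
        values["variance"] = trial.var(axis=1)
    if "zcr" in statistics:
        values["zcr"] = _zcr_rows(trial)
    if "mean_abs_diff" in statistics:
        values["mean_abs_diff"] = np.abs(np.diff(trial, axis=1)).mean(axis=1)
    unknown = set(statistics) - set(values)
    if unknown:
        raise ValueError(f"unknown time-domain statistics: {sorted(unknown)}")
    return np.stack([values[s] for s in statistics], axis=1).ravel()


def feature_names(
    bands: tuple[BandDef, ...] = BANDS,
    asym_bands: tuple[BandDef, ...] = ASYM_BANDS,
    statistics: tuple[str, ...] = TIME_STATS_DEFAULT,
) -> list[str]:
    """Canonical column names: [PSD | asymmetry | time-domain]."""
    from .channels import HOMOLOGOUS_PAIRS

    names = [f"psd_{ch}_{b.name}" for ch in CHANNELS_32 for b in bands]
    names += [
        f"asym_{r}_{l}_{b.name}" for (r, l) in HOMOLOGOUS_PAIRS for b in asym_bands
    ]
    names += [f"td_{ch}_{s}" for ch in CHANNELS_32 for s in statistics]
    return names


def _extract_chunk(data, fs, bands, asym_bands, statistics, params, log10):
    """Feature rows for an (m, 32, seg) chunk sharing one Welch pass."""
    from .channels import HOMOLOGOUS_PAIRS

    est = compute_psd(data, fs, params)  # psd shape (m, 32, n_bins)
    all_bands = list(dict.fromkeys([*bands, *asym_bands]))
    avg = {b.name: band_average_psd(est, b) for b in all_bands}  # each (m, 32)
    psd_part = np.stack([avg[b.name] for b in bands], axis=2).reshape(
        data.shape[0], -1
    )
    if log10:
        psd_part = np.log10(psd_part + 1e-12)
    asym_cols = []
    for r, l in HOMOLOGOUS_PAIRS:
        for b in asym_bands:
            asym_cols.append(
                avg[b.name][:, CHANNEL_INDEX[r]] - avg[b.name][:, CHANNEL_INDEX[l]]
            )
    asym_part = np.stack(asym_cols, axis=1)
    td_part = np.stack(
        [time_domain_features(data[i], statistics) for i in range(data.shape[0])]
    )
    return np.hstack([psd_part, asym_part, td_part])


def extract_features(
    trials,
    fs: float = 128.0,
    segment_s: float | None = 60.0,
    bands: tuple[BandDef, ...] = BANDS,
    asym_bands: tuple[BandDef, ...] = ASYM_BANDS,
    statistics: tuple[str, ...] = TIME_STATS_DEFAULT,
    params: WelchParams = WelchParams(),
    log10: bool = False,
    chunk_size: int = 64,
) -> pd.DataFrame:
    """Extract the full feature matrix from trials.

    ``trials`` may be a :class:`~eegaug.io.TrialTable`, an ``(n, 32,
    n_samples)`` array, or a single ``(32, n_samples)`` trial.  Features are
    computed on the final ``segment_s`` seconds of each trial (the 3-s
    pre-stimulus baseline of a 63-s trial is discarded by the default 60-s
    segment); ``segment_s=None`` uses the whole trial.  Trials are processed
    in chunks so the Welch segment buffer stays modest.

    Returns an ``n x 344`` DataFrame (under defaults) with canonical
    column names.
    """
    if isinstance(trials, TrialTable):
        data = trials.data
    else:
        data = np.asarray(trials, dtype=float)
        if data.ndim == 2:
            data = data[None]
    if data.ndim != 3:
        raise ShapeError("trials must be (n, channels, samples)")
    if data.ndim == 3 and data.shape[1] != len(CHANNELS_32):
        raise ShapeError(
            f"trials must have {len(CHANNELS_32)} channels, got {data.shape[1]}"
        )
    if segment_s is not None:
        n_seg = int(round(segment_s * fs))
        if n_seg > data.shape[-1]:
            raise ValueError(
                f"segment of {n_seg} samples exceeds trial length {data.shape[-1]}"
            )
        data = data[..., -n_seg:]
    names = feature_names(bands, asym_bands, statistics)
    if data.shape[0] == 0:
        return pd.DataFrame(np.empty((0, len(names))), columns=names)
    rows = np.vstack([
        _extract_chunk(
            data[start : start + chunk_size], fs, bands, asym_bands,
            statistics, params, log10,
        )
        for start in range(0, data.shape[0], chunk_size)
    ])
    return pd.DataFrame(rows, columns=names)


class FeatureScaler:
    """Per-column min-max map onto [-1, 1], fitted on training rows only.

    Constant columns map to 0 and invert back to their constant.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None
        self.columns_: list[str] | None = None

    def fit(self, train: pd.DataFrame | np.ndarray) -> "FeatureScaler":
        arr = np.asarray(train, dtype=float)
        if arr.size == 0:
            raise ValueError("cannot fit a scaler on an empty matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("features contain non-finite values")
        self.min_ = arr.min(axis=0)
        self.max_ = arr.max(axis=0)
        self.columns_ = (
            list(train.columns) if isinstance(train, pd.DataFrame) else None
        )
        return self

    def _check(self) -> None:
        if self.min_ is None:
            raise RuntimeError("scaler is not fitted")

    def transform(self, x) -> np.ndarray:
        self._check()
        arr = np.asarray(x, dtype=float)
        span = self.max_ - self.min_
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (arr - self.min_) / safe - 1.0
        return np.where(span == 0, 0.0, out)

    def inverse_transform(self, z) -> np.ndarray:
        self._check()
        arr = np.asarray(z, dtype=float)
        span = self.max_ - self.min_
        return np.where(span == 0, self.min_, (arr + 1.0) / 2.0 * span + self.min_)

    def fit_transform(self, train):
        return self.fit(train).transform(train)
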