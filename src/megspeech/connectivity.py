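"""Pairwise sensor correlation and amplitude-envelope-correlation (AEC)
functional connectivity.

Sensor correlation is plain Pearson correlation between channel signals,
computed per trial and averaged across trials arithmetically on r.  AEC
band-passes each channel with a zero-phase 4th-order Butterworth filter,
takes the magnitude of the analytic (Hilbert) signal as the amplitude
envelope, trims 100 ms from each envelope edge to bound filter-transient
leakage, and correlates the envelopes — either per trial with the
matrices averaged afterwards, or on trials concatenated end-to-end before
envelope extraction (the per-subject variant).  No leakage
orthogonalization is applied; the measure is sensor-space AEC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import BandSpec, EpochSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "trial_correlation",
    "mean_correlation",
    "correlation_density",
    "strong_pair_count",
    "strong_sensor_count",
    "correlation_range",
    "aec",
    "connectivity_density",
]

EDGE_TRIM_S = 0.1  # envelope edge trim, seconds per side


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel matrix of a stated coupling measure."""

    values: np.ndarray
    measure: str  # "pearson" | "aec"
    band: str = "broadband"
    segment: str = ""
    aggregation: str = "single-trial-averaged"  # or "concatenated"

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def upper_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries, the unit of all summaries."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


def _corr_stack(x: np.ndarray) -> np.ndarray:
    """Pearson correlation matrices for a (trials, channels, samples) stack.

    Zero-variance channels yield NaN rows/columns (logged once)."""
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1)
    n_zero = int((sd == 0).sum())
    if n_zero:
        logger.warning("%d zero-variance channel instance(s); pairs set to NaN", n_zero)
    cov = np.einsum("tcs,tds->tcd", x, x) / x.shape[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / (sd[:, :, None] * sd[:, None, :])
    return np.clip(corr, -1.0, 1.0, out=corr)


def trial_correlation(es: EpochSet) -> np.ndarray:
    """Per-trial Pearson correlation matrices, shape (trials, ch, ch)."""
    if es.n_samples < 2:
        raise ValidationError("trial_correlation: need at least 2 samples per trial")
    return _corr_stack(np.asarray(es.data, dtype=np.float64))


def mean_correlation(es: EpochSet, segment_name: str = "") -> ConnectivityMatrix:
    """Trial-averaged sensor correlation (arithmetic mean on r)."""
    return ConnectivityMatrix(
        values=trial_correlation(es).mean(axis=0),
        measure="pearson",
        segment=segment_name,
    )


def _check_square(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1] or values.shape[0] < 2:
        raise ValidationError(f"expected a square matrix of >= 2 channels, got {values.shape}")


def correlation_density(cm: ConnectivityMatrix | np.ndarray) -> float:
    """Mean absolute off-diagonal correlation: sum |r_ij| over the number of
    unordered sensor pairs.  Lies in [0, 1]."""
    values = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm)
    _check_square(values)
    iu = np.triu_indices(values.shape[0], k=1)
    return float(np.nanmean(np.abs(values[iu])))


def connectivity_density(cm: ConnectivityMatrix | np.ndarray) -> float:
    """Mean signed off-diagonal value: sum of AEC values over sensor pairs."""
    values = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm)
    _check_square(values)
    iu = np.triu_indices(values.shape[0], k=1)
    upper = values[iu]
    if np.isnan(upper).all():
        raise ValidationError("connectivity matrix is entirely undefined (NaN)")
    return float(np.nanmean(upper))


def strong_pair_count(cm: ConnectivityMatrix | np.ndarray, thresh: float = 0.5) -> int:
    """Number of unordered sensor pairs with |r| strictly above ``thresh``."""
    values = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm)
    _check_square(values)
    iu = np.triu_indices(values.shape[0], k=1)
    return int((np.abs(values[iu]) > thresh).sum())


def strong_sensor_count(cm: ConnectivityMatrix | np.ndarray, thresh: float = 0.5) -> int:
    """Number of sensors participating in at least one strong pair."""
    values = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm)
    _check_square(values)
    off = np.abs(values - np.diag(np.diag(values)))
    return int(((off > thresh).any(axis=1)).sum())


def correlation_range(
    values: np.ndarray,
    coverage: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Central interval containing ``coverage`` of the pooled correlation
    distribution, by seeded bootstrap of the sample quantiles."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 10:
        raise ValidationError(f"need >= 10 correlation values, got {values.size}")
    if not 0 < coverage < 1:
        raise ValidationError(f"coverage must be in (0, 1), got {coverage}")
    rng = np.random.default_rng(seed)
    qlo, qhi = (1 - coverage) / 2, (1 + coverage) / 2
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    quantiles = np.quantile(values[idx], [qlo, qhi], axis=1)
    return float(quantiles[0].mean()), float(quantiles[1].mean())


def aec(
    es: EpochSet,
    band: BandSpec,
    mode: str = "single-trial-averaged",
    segment_name: str = "",
    edge_trim_s: float = EDGE_TRIM_S,
) -> ConnectivityMatrix:
    """Amplitude-envelope correlation across all channel pairs for one band."""
    band.validate_for_fs(es.fs)
    min_samples = int(np.ceil(2 * es.fs / band.lo))
    if es.n_samples < min_samples:
        raise ValidationError(
            f"trials of {es.n_samples} samples are shorter than 2 periods of "
            f"{band.lo} Hz ({min_samples} samples)"
        )
    if mode not in ("single-trial-averaged", "concatenated"):
        raise ValidationError(f"unknown AEC mode {mode!r}")
    sos = signal.butter(4, [band.lo, band.hi], btype="bandpass", fs=es.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, np.asarray(es.data, dtype=np.float64), axis=-1)
    trim = int(round(edge_trim_s * es.fs))

    def envelope(x: np.ndarray) -> np.ndarray:
        env = np.abs(signal.hilbert(x, axis=-1))
        return env[..., trim : env.shape[-1] - trim] if trim else env

    if mode == "single-trial-averaged":
        matrix = _corr_stack(envelope(filtered)).mean(axis=0)
    else:
        joined = filtered.transpose(1, 0, 2).reshape(es.n_channels, -1)
        matrix = _corr_stack(envelope(joined)[np.newaxis])[0]
    return ConnectivityMatrix(
        values=matrix,
        measure="aec",
        band=band.name,
        segment=segment_name,
        aggregation=mode,
    )
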