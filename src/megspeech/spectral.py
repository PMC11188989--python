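"""Canonical-band power estimation.

Average band power per trial and channel is the integral of a Welch power
spectral density over the band interval.  Welch parameters: 1 s Hann
windows with 50% overlap (or a single window when the segment is 1 s, as
for the covert window).  Integration uses the trapezoidal rule on the
closed interval [lo, hi], which makes power additive across bands that
share an edge (delta|theta|alpha|beta) and keeps the sum of disjoint band
powers below the total signal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import BandSpec, EpochSet, ValidationError, COHORTS

__all__ = ["BandPowerTable", "GroupMeans", "psd", "band_power", "group_mean_band_power"]


def _welch_params(n_samples: int, fs: float) -> dict:
    nperseg = min(n_samples, int(round(fs)))
    return dict(
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )


def psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD along the last axis.

    Returns (freqs, density); the integral of the density over frequency
    recovers the signal variance (Parseval, within the Welch bias).
    """
    x = np.asarray(x)
    if x.shape[-1] < 2:
        raise ValidationError(
            f"signal too short for a spectral estimate: {x.shape[-1]} samples (need >= 2)"
        )
    return signal.welch(x, **_welch_params(x.shape[-1], fs))


def _band_integral(freqs: np.ndarray, density: np.ndarray, band: BandSpec) -> np.ndarray:
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"band {band.name!r}: fewer than 2 spectral bins in [{band.lo}, {band.hi}] Hz "
            f"at resolution {freqs[1] - freqs[0]:g} Hz"
        )
    return np.trapezoid(density[..., mask], freqs[mask], axis=-1)


@dataclass
class BandPowerTable:
    """Mean power per trial, channel, and band (signal-units squared)."""

    values: np.ndarray  # (n_trials, n_channels, n_bands)
    bands: tuple[BandSpec, ...]
    channel_ids: list[str]
    trials: pd.DataFrame
    segment: str = ""

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    def band_index(self, name: str) -> int:
        try:
            return self.band_names.index(name)
        except ValueError:
            raise ValidationError(
                f"band {name!r} not in table (has {self.band_names})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (trial, channel, band)."""
        t, c, b = self.values.shape
        meta = self.trials.loc[self.trials.index.repeat(c * b)].reset_index(drop=True)
        frame = pd.DataFrame(
            {
                "channel": np.tile(np.repeat(self.channel_ids, b), t),
                "band": np.tile(self.band_names, t * c),
                "power": self.values.ravel(),
            }
        )
        return pd.concat([meta, frame], axis=1)


def band_power(
    es: EpochSet,
    bands: tuple[BandSpec, ...],
    segment_name: str = "",
) -> BandPowerTable:
    """Welch-integrated mean power for every trial, channel, and band."""
    for b in bands:
        b.validate_for_fs(es.fs)
    freqs, density = psd(es.data, es.fs)
    values = np.stack([_band_integral(freqs, density, b) for b in bands], axis=-1)
    return BandPowerTable(
        values=values,
        bands=tuple(bands),
        channel_ids=list(es.channel_ids),
        trials=es.trials.copy(),
        segment=segment_name,
    )


@dataclass
class GroupMeans:
    """Band power averaged over all trials of all participants in a cohort,
    per phrase: shape (cohort, phrase, channel, band)."""

    values: np.ndarray
    cohorts: tuple[str, ...]
    phrases: tuple[int, ...]
    channel_ids: list[str]
    bands: tuple[BandSpec, ...]

    def cohort_phrase(self, cohort: str, phrase: int) -> np.ndarray:
        """(channel, band) mean power for one cohort and phrase."""
        return self.values[self.cohorts.index(cohort), self.phrases.index(phrase)]


def group_mean_band_power(bpt: BandPowerTable) -> GroupMeans:
    """Average band powers across trials and participants per (cohort, phrase)."""
    cohorts = tuple(c for c in COHORTS if c in set(bpt.trials["cohort"]))
    phrases = tuple(sorted(bpt.trials["phrase_id"].unique()))
    n_ch, n_b = bpt.values.shape[1:]
    out = np.empty((len(cohorts), len(phrases), n_ch, n_b))
    for i, cohort in enumerate(cohorts):
        for j, phrase in enumerate(phrases):
            mask = (
                (bpt.trials["cohort"] == cohort) & (bpt.trials["phrase_id"] == phrase)
            ).to_numpy()
            if not mask.any():
                raise ValidationError(f"empty group cell: cohort={cohort!r}, phrase={phrase}")
            out[i, j] = bpt.values[mask].mean(axis=0)
    return GroupMeans(
        values=out,
        cohorts=cohorts,
        phrases=phrases,
        channel_ids=list(bpt.channel_ids),
        bands=bpt.bands,
    )
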