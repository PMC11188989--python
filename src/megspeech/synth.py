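"""Two-cohort synthetic MEG generator.

Emulates the statistical structure the downstream analyses assume: per
channel a sum of band-limited oscillatory sources over a 1/f (pink)
background plus 60 Hz line noise, with inter-channel coupling induced by one
shared source per band.  Within each band the channel signal is

    x_c = sigma_b * ( sqrt(1 - rho^2) * p_cb + rho * s_b )

where ``p_cb`` is a private unit-variance band-limited source, ``s_b`` a
shared one, and ``rho`` the cohort coupling.  The sqrt(1 - rho^2) private
weight keeps the per-band channel variance independent of ``rho``, so the
expected in-band correlation between any two channels is exactly ``rho**2``
while band power is controlled solely by ``sigma_b`` — connectivity and
power effects can be dialled independently.

The patient cohort differs from the healthy one only through a beta-band
amplitude gain ``g_beta`` and its coupling ``rho_patient``; the null
configuration (``g_beta = 1``, equal coupling) makes the cohorts
statistically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal

from .core_io import CANONICAL_BANDS, BandSpec, EpochSet, ValidationError

__all__ = [
    "SynthParams",
    "null_preset",
    "beta_effect_preset",
    "bandlimited_source",
    "pink_noise",
    "generate_cohorts",
]

#: Per-band source amplitudes (signal units).  The declining profile mimics
#: the usual 1/f-like drop of oscillatory power with frequency.
DEFAULT_BAND_AMPLITUDES: Mapping[str, float] = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 0.7,
    "beta": 0.6,
    "gamma": 0.4,
    "highgamma": 0.3,
}


@dataclass
class SynthParams:
    """Generator parameters.  Defaults are the reduced desk scale
    (32 channels, 20 trials/phrase); the full recording layout uses
    196 channels and 60 trials/phrase."""

    n_channels: int = 32
    fs: float = 1000.0
    t_start: float = -0.5
    t_end: float = 4.5
    participants_per_cohort: int = 3
    n_phrases: int = 5
    trials_per_phrase: int = 20
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    rho_healthy: float = 0.3
    rho_patient: float = 0.3
    g_beta: float = 1.0
    pink_amplitude: float = 1.0
    line_amplitude: float = 0.5
    line_freq: float = 60.0
    overt_gain: float = 1.3
    overt_window: tuple[float, float] = (2.0, 4.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ValidationError("n_channels: need at least 2 channels")
        if self.fs <= 0:
            raise ValidationError(f"fs: must be > 0, got {self.fs}")
        if not self.t_start < self.t_end:
            raise ValidationError("epoch window: t_start must be < t_end")
        for name, sigma in self.band_amplitudes.items():
            if sigma < 0:
                raise ValidationError(f"band_amplitudes[{name!r}]: must be >= 0")
        for label, rho in (("rho_healthy", self.rho_healthy), ("rho_patient", self.rho_patient)):
            if not 0 <= rho < 1:
                raise ValidationError(f"{label}: must be in [0, 1), got {rho}")
        if self.g_beta < 1:
            raise ValidationError(f"g_beta: must be >= 1, got {self.g_beta}")
        if self.participants_per_cohort < 1 or self.n_phrases < 1 or self.trials_per_phrase < 1:
            raise ValidationError("participants/phrases/trials: must all be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round((self.t_end - self.t_start) * self.fs))


def null_preset(**overrides) -> SynthParams:
    """Cohorts share every generative parameter (no group effect)."""
    return SynthParams(**overrides)


def beta_effect_preset(**overrides) -> SynthParams:
    """Patient cohort with elevated beta amplitude and stronger coupling."""
    defaults = dict(g_beta=1.5, rho_patient=0.6, rho_healthy=0.3)
    defaults.update(overrides)
    return SynthParams(**defaults)


# ---------------------------------------------------------------------------
# Elementary sources
# ---------------------------------------------------------------------------


def _band_sos(band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    band.validate_for_fs(fs)
    return signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def _standardize(x: np.ndarray) -> np.ndarray:
    """Remove the mean and scale to unit sample variance along the last axis."""
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def bandlimited_source(
    band: BandSpec,
    n_samples: int,
    fs: float,
    seed: int | np.random.Generator = 0,
    sigma: float = 1.0,
) -> np.ndarray:
    """A zero-mean band-limited noise source with sample variance sigma**2.

    White noise is band-passed with a zero-phase 4th-order Butterworth
    filter, then standardized; >= 90% of its spectral mass lies in
    [lo, hi].
    """
    if n_samples <= 0:
        raise ValidationError(f"n_samples: must be > 0, got {n_samples}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sos = _band_sos(band, fs)
    white = rng.standard_normal(n_samples)
    return sigma * _standardize(signal.sosfiltfilt(sos, white))


def pink_noise(
    n_samples: int,
    fs: float = 1000.0,
    seed: int | np.random.Generator = 0,
    sigma: float = 1.0,
) -> np.ndarray:
    """Zero-mean 1/f noise (spectral density ~ 1/f), unit variance x sigma.

    Built by shaping the rFFT of white noise with 1/sqrt(f); the DC bin is
    zeroed.  The fitted log-log periodogram slope over 1-100 Hz is -1.
    """
    if n_samples <= 0:
        raise ValidationError(f"n_samples: must be > 0, got {n_samples}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    white = rng.standard_normal(n_samples)
    return sigma * _shape_pink(white[np.newaxis, :], fs)[0]


def _shape_pink(white: np.ndarray, fs: float) -> np.ndarray:
    """Apply 1/sqrt(f) spectral shaping along the last axis and standardize."""
    n = white.shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    return _standardize(shaped)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------


def _expected_gain_variance(g: np.ndarray, n: int) -> float:
    """Variance of ``irfft(rfft(white) * g)`` for unit white noise of length n."""
    interior = g[1:-1] if n % 2 == 0 else g[1:]
    tail = g[-1] ** 2 if n % 2 == 0 else 0.0
    return float((g[0] ** 2 + 2 * np.sum(interior**2) + tail) / n)


def _unit_band_gains(p: SynthParams) -> dict[str, np.ndarray]:
    """Per-band zero-phase Butterworth magnitude responses on the rFFT grid,
    scaled so shaping unit white noise yields unit variance."""
    freqs = np.fft.rfftfreq(p.n_samples, d=1.0 / p.fs)
    gains: dict[str, np.ndarray] = {}
    for band in CANONICAL_BANDS:
        sos = _band_sos(band, p.fs)
        _, h = signal.sosfreqz(sos, worN=freqs, fs=p.fs)
        g = np.abs(h) ** 2  # forward-backward application squares the magnitude
        gains[band.name] = g / np.sqrt(_expected_gain_variance(g, p.n_samples))
    g_pink = np.zeros_like(freqs)
    g_pink[1:] = 1.0 / np.sqrt(freqs[1:])
    gains["pink"] = g_pink / np.sqrt(_expected_gain_variance(g_pink, p.n_samples))
    return gains


def _shape(white: np.ndarray, gain: np.ndarray) -> np.ndarray:
    n = white.shape[-1]
    if white.dtype == np.float32:
        gain = gain.astype(np.float32)
    return sfft.irfft(sfft.rfft(white, axis=-1) * gain, n=n, axis=-1)


def _participant_block(
    p: SynthParams,
    rho: float,
    beta_gain: float,
    rng: np.random.Generator,
    gains: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Signals for one participant: (n_phrases*trials, channels, samples).

    The sum of the independent private band sources is one Gaussian process
    with the summed per-band PSD, so the whole private oscillatory part is
    produced by a single spectral shaping of white noise; shared sources are
    shaped per band and broadcast across channels.
    """
    n_trials = p.n_phrases * p.trials_per_phrase
    shape = (n_trials, p.n_channels, p.n_samples)
    times = p.t_start + np.arange(p.n_samples) / p.fs
    overt_mask = (times >= p.overt_window[0]) & (times < p.overt_window[1])

    sigmas = {}
    for band in CANONICAL_BANDS:
        sigma = p.band_amplitudes.get(band.name, 0.0)
        if band.name == "beta":
            sigma *= beta_gain
        sigmas[band.name] = sigma

    combined = np.sqrt(
        (1.0 - rho**2)
        * sum(sigmas[name] ** 2 * gains[name] ** 2 for name in sigmas)
    )
    sources = _shape(rng.standard_normal(shape, dtype=np.float32), combined)
    if rho > 0:
        for name, sigma in sigmas.items():
            if sigma == 0.0:
                continue
            shared = _shape(
                rng.standard_normal((n_trials, 1, p.n_samples), dtype=np.float32),
                gains[name],
            )
            sources += (rho * sigma) * shared

    # overt articulation boosts the oscillatory sources but not the noise floor
    sources[..., overt_mask] *= p.overt_gain

    out = sources
    if p.pink_amplitude > 0:
        out += p.pink_amplitude * _shape(
            rng.standard_normal(shape, dtype=np.float32), gains["pink"]
        )
    if p.line_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += (p.line_amplitude * np.sin(2 * np.pi * p.line_freq * times + phase)).astype(
            np.float32
        )
    return out


def generate_cohorts(p: SynthParams) -> EpochSet:
    """Generate the two-cohort epoched dataset described by ``p``.

    Deterministic given ``p.seed``: each (cohort, participant) pair draws
    from its own spawned random stream, so changing the number of trials of
    one participant does not perturb the others.
    """
    p.validate()
    ss = np.random.SeedSequence(p.seed)
    children = ss.spawn(2 * p.participants_per_cohort)
    gains = _unit_band_gains(p)

    blocks: list[np.ndarray] = []
    meta: list[pd.DataFrame] = []
    stream = iter(children)
    for cohort, rho, gain, prefix in (
        ("healthy", p.rho_healthy, 1.0, "H"),
        ("patient", p.rho_patient, p.g_beta, "A"),
    ):
        for i in range(p.participants_per_cohort):
            rng = np.random.default_rng(next(stream))
            pid = f"{prefix}{i + 1}"
            blocks.append(_participant_block(p, rho, gain, rng, gains))
            meta.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "cohort": cohort,
                        "phrase_id": np.repeat(
                            np.arange(1, p.n_phrases + 1), p.trials_per_phrase
                        ),
                        "trial_index": np.tile(
                            np.arange(1, p.trials_per_phrase + 1), p.n_phrases
                        ),
                        "valid": True,
                    }
                )
            )

    return EpochSet(
        data=np.concatenate(blocks, axis=0),
        fs=p.fs,
        t0=p.t_start,
        channel_ids=[f"MEG{i:03d}" for i in range(1, p.n_channels + 1)],
        trials=pd.concat(meta, ignore_index=True),
    )
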