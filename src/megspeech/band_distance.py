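"""Healthy-vs-patient band-power distance heatmaps and the per-band
dissimilarity summary.

Each heatmap cell (i, j) compares the cohort-mean band power of healthy
channel i with patient channel j.  Two variants are provided: the
per-phrase scalar distance |P_h(i) - P_p(j)| (the one-dimensional Euclidean
case) and the across-phrase distance, the Euclidean norm of the
5-phrase power-difference vector.  The per-band summary feeds the 6-band
one-way ANOVA with the phrases as samples, followed by Tukey HSD;
min-max normalization across bands is presentation-only and never enters
the inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import ValidationError
from .spectral import GroupMeans
from .stats import TestResult, TukeyComparison, one_way_anova, tukey_hsd

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "distance_matrix_across_phrases",
    "normalize_heatmaps",
    "band_dissimilarity_summary",
    "DissimilaritySummary",
]


@dataclass
class DistanceMatrix:
    """Non-negative healthy-channel x patient-channel distance matrix."""

    values: np.ndarray
    band: str
    phrase_scope: str  # "phrase:<k>" or "across-phrases"
    normalized: bool = False


def _cohort_vectors(gm: GroupMeans, band: str) -> tuple[np.ndarray, np.ndarray]:
    for cohort in ("healthy", "patient"):
        if cohort not in gm.cohorts:
            raise ValidationError(f"group means missing cohort {cohort!r}")
    b = [bb.name for bb in gm.bands].index(band)
    h = gm.values[gm.cohorts.index("healthy"), :, :, b]  # (phrase, channel)
    p = gm.values[gm.cohorts.index("patient"), :, :, b]
    return h, p


def distance_matrix(gm: GroupMeans, band: str, phrase: int) -> DistanceMatrix:
    """Scalar distance |P_healthy(i) - P_patient(j)| for one phrase."""
    h, p = _cohort_vectors(gm, band)
    if phrase not in gm.phrases:
        raise ValidationError(f"phrase {phrase} not present (has {gm.phrases})")
    k = gm.phrases.index(phrase)
    values = np.abs(h[k][:, None] - p[k][None, :])
    return DistanceMatrix(values=values, band=band, phrase_scope=f"phrase:{phrase}")


def distance_matrix_across_phrases(gm: GroupMeans, band: str) -> DistanceMatrix:
    """Euclidean distance between the per-phrase power vectors of healthy
    channel i and patient channel j."""
    h, p = _cohort_vectors(gm, band)  # (phrase, channel)
    diff = h.T[:, None, :] - p.T[None, :, :]  # (ch_h, ch_p, phrase)
    values = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(values=values, band=band, phrase_scope="across-phrases")


def normalize_heatmaps(dms: Mapping[str, DistanceMatrix]) -> dict[str, DistanceMatrix]:
    """Joint min-max scaling of a set of band matrices to [0, 1].

    The shared scale preserves cross-band comparability; constant input
    maps to all zeros with a warning.
    """
    if not dms:
        raise ValidationError("normalize_heatmaps: no matrices given")
    lo = min(dm.values.min() for dm in dms.values())
    hi = max(dm.values.max() for dm in dms.values())
    if hi == lo:
        logger.warning("all distance values equal (%g); normalized heatmaps are zero", lo)
        scale = lambda v: np.zeros_like(v)  # noqa: E731
    else:
        scale = lambda v: (v - lo) / (hi - lo)  # noqa: E731
    return {
        name: DistanceMatrix(
            values=scale(dm.values),
            band=dm.band,
            phrase_scope=dm.phrase_scope,
            normalized=True,
        )
        for name, dm in dms.items()
    }


@dataclass
class DissimilaritySummary:
    """Per-band mean distances and the band-wise ANOVA / Tukey verdict."""

    band_names: tuple[str, ...]
    phrase_means: np.ndarray  # (band, phrase) mean distance
    anova: TestResult
    tukey: list[TukeyComparison]
    argmax_band: str

    def band_flagged_vs_rest(self, band: str, alpha: float = 0.05) -> bool:
        """True when Tukey rejects this band against every other band."""
        k = self.band_names.index(band)
        relevant = [c for c in self.tukey if k in (c.group_a, c.group_b)]
        return all(c.p_adj < alpha for c in relevant)


def band_dissimilarity_summary(
    gm: GroupMeans,
    bands: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> DissimilaritySummary:
    """One-way ANOVA + Tukey over per-band mean distances, with the phrases
    as the samples of each band group (unnormalized distances)."""
    names = tuple(bands) if bands is not None else tuple(b.name for b in gm.bands)
    if len(names) < 2:
        raise ValidationError("band_dissimilarity_summary: need >= 2 bands")
    table = np.empty((len(names), len(gm.phrases)))
    for i, band in enumerate(names):
        for j, phrase in enumerate(gm.phrases):
            table[i, j] = distance_matrix(gm, band, phrase).values.mean()
    anova = one_way_anova(table)
    comparisons = tukey_hsd(table, alpha=alpha)
    return DissimilaritySummary(
        band_names=names,
        phrase_means=table,
        anova=anova,
        tukey=comparisons,
        argmax_band=names[int(np.argmax(table.mean(axis=1)))],
    )
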