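"""Signal conditioning and trial bookkeeping.

Fixed stage order: low-pass/resample -> power-line notch -> segment parsing
-> channel exclusion / trial rejection.  All IIR filters are applied
zero-phase (forward-backward), which doubles the effective order of the
stated designs but removes phase distortion that would bias band-power
timing.  Visual artifact rejection is replaced by a deterministic
peak-amplitude threshold; ICA cleanup is exposed only as a hook taking an
externally computed keep/drop mask.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from .core_io import EpochSet, SegmentSpec, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "lowpass_and_resample",
    "notch_line",
    "parse_segment",
    "exclude_channels",
    "reject_and_cap_trials",
    "apply_trial_mask",
]


def lowpass_and_resample(
    es: EpochSet,
    cutoff: float = 250.0,
    order: int = 4,
    target_fs: float = 1000.0,
) -> EpochSet:
    """Zero-phase Butterworth low-pass followed by polyphase resampling.

    The low-pass (default 250 Hz, 4th order) doubles as the anti-alias
    guard; the polyphase stage uses its own FIR at the target Nyquist.
    With ``target_fs == fs`` only the filter is applied.
    """
    if target_fs > es.fs:
        raise ValidationError(f"target_fs={target_fs} exceeds input rate {es.fs}")
    if cutoff >= target_fs / 2:
        raise ValidationError(
            f"cutoff={cutoff} Hz is at or above the target Nyquist ({target_fs / 2} Hz)"
        )
    sos = signal.butter(order, cutoff, btype="lowpass", fs=es.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, es.data, axis=-1)
    if target_fs == es.fs:
        return es.replace(data=filtered)
    ratio = Fraction(target_fs / es.fs).limit_denominator(1000)
    resampled = signal.resample_poly(filtered, ratio.numerator, ratio.denominator, axis=-1)
    return es.replace(data=resampled, fs=target_fs)


def _notch_sos(base: float, fs: float, bandwidth: float, max_harmonic: int | None = None):
    """Stacked biquad notches at ``base`` and its harmonics below Nyquist."""
    harmonics = []
    k = 1
    while k * base < fs / 2 and (max_harmonic is None or k <= max_harmonic):
        harmonics.append(k * base)
        k += 1
    if not harmonics:
        raise ValidationError(f"notch base {base} Hz is at or above Nyquist ({fs / 2} Hz)")
    sections = []
    for f0 in harmonics:
        b, a = signal.iirnotch(f0, f0 / bandwidth, fs=fs)
        sections.append(signal.tf2sos(b, a))
    return np.vstack(sections)


def notch_line(
    es: EpochSet,
    base: float = 60.0,
    bandwidth: float = 2.0,
    max_harmonic: int | None = None,
) -> EpochSet:
    """Remove the power line and its harmonics with 2nd-order IIR notches.

    Each notch has a fixed -3 dB bandwidth (default 2 Hz) so neighbours
    5 Hz away pass essentially unattenuated; zero-phase application
    deepens the stopband.
    """
    sos = _notch_sos(base, es.fs, bandwidth, max_harmonic)
    return es.replace(data=signal.sosfiltfilt(sos, es.data, axis=-1))


def parse_segment(es: EpochSet, seg: SegmentSpec) -> EpochSet:
    """Cut a named sub-window out of every epoch and re-anchor the time axis."""
    t_end = es.t0 + es.n_samples / es.fs
    if seg.start_s < es.t0 - 1e-9 or seg.end_s > t_end + 1e-9:
        raise ValidationError(
            f"segment {seg.name!r} [{seg.start_s}, {seg.end_s}] s lies outside "
            f"the epoch window [{es.t0}, {t_end}] s"
        )
    i0 = int(round((seg.start_s - es.t0) * es.fs))
    i1 = i0 + int(round((seg.end_s - seg.start_s) * es.fs))
    return es.replace(data=es.data[..., i0:i1], t0=seg.start_s)


def exclude_channels(es: EpochSet, bad: Sequence[str]) -> EpochSet:
    """Drop channels by label, preserving the order of the survivors.

    Duplicate labels in ``bad`` are deduplicated with a warning; an unknown
    label is an error naming it.
    """
    seen: list[str] = []
    for label in bad:
        if label in seen:
            logger.warning("duplicate channel %r in bad list; ignoring repeat", label)
            continue
        seen.append(label)
    unknown = [c for c in seen if c not in es.channel_ids]
    if unknown:
        raise ValidationError(f"unknown channel label(s) in bad list: {unknown}")
    keep = [i for i, c in enumerate(es.channel_ids) if c not in seen]
    return es.replace(
        data=es.data[:, keep, :],
        channel_ids=[es.channel_ids[i] for i in keep],
    )


def reject_and_cap_trials(
    es: EpochSet,
    amp_thresh: float | None = None,
    cap: int = 60,
    thresh_factor: float = 5.0,
) -> EpochSet:
    """Amplitude-based trial rejection, then a per-cell trial cap.

    Trials whose peak absolute amplitude exceeds ``amp_thresh`` are dropped;
    when ``amp_thresh`` is None it defaults to ``thresh_factor`` times the
    median trial peak (a deterministic stand-in for visual inspection).  Of
    the survivors, the first ``cap`` trials per (participant, phrase) cell
    in original order are kept.  A cell left with zero trials is an error.
    """
    if cap < 1:
        raise ValidationError(f"cap: must be >= 1, got {cap}")
    peaks = np.max(np.abs(es.data), axis=(1, 2))
    if amp_thresh is None:
        amp_thresh = thresh_factor * float(np.median(peaks))
    ok = peaks <= amp_thresh

    keep_mask = np.zeros(es.n_trials, dtype=bool)
    for (pid, phrase), cell in es.trials.groupby(["participant_id", "phrase_id"], sort=False):
        idx = cell.index.to_numpy()
        surviving = idx[ok[idx]]
        if surviving.size == 0:
            raise ValidationError(
                f"all trials rejected for participant {pid!r}, phrase {phrase}"
            )
        keep_mask[surviving[:cap]] = True
    return es.select_trials(np.flatnonzero(keep_mask))


def apply_trial_mask(es: EpochSet, keep: Sequence[bool]) -> EpochSet:
    """Hook for externally supplied per-trial keep/drop decisions
    (e.g. an ICA-based artifact screen computed elsewhere)."""
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (es.n_trials,):
        raise ValidationError(
            f"trial mask length {keep.size} does not match {es.n_trials} trials"
        )
    return es.select_trials(np.flatnonzero(keep))
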