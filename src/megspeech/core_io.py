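"""Domain types, the portable epoch container, and configuration.

The central object is :class:`EpochSet`, a labelled trial x channel x sample
block of sensor signals with cohort / participant / phrase metadata attached
per trial.  Epoch sets are serialized to an HDF5 layout with one group per
participant and one dataset per phrase, which round-trips the signal array
bit-exactly and the metadata field-for-field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

COHORTS = ("healthy", "patient")

_SCHEMA = "megspeech-epochs"
_SCHEMA_VERSION = 1

#: Metadata columns every EpochSet carries, one row per trial.
TRIAL_COLUMNS = ("participant_id", "cohort", "phrase_id", "trial_index", "valid")


class ValidationError(ValueError):
    """An invariant of a domain type was violated; the message names the field."""


@dataclass(frozen=True)
class BandSpec:
    """A named frequency interval in Hz, ``lo < hi``."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValidationError(
                f"band {self.name!r}: requires 0 < lo < hi, got lo={self.lo}, hi={self.hi}"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValidationError(
                f"band {self.name!r}: hi={self.hi} Hz is at or above Nyquist ({fs / 2} Hz)"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: The six canonical oscillation bands.  They tile 1-59 and 61-119 Hz;
#: the 60 Hz power-line frequency falls in none of them.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 16.0),
    BandSpec("beta", 16.0, 30.0),
    BandSpec("gamma", 30.0, 59.0),
    BandSpec("highgamma", 61.0, 119.0),
)

#: Broadband variants for classification: the 1-119 Hz span of the canonical
#: bands (default) and the wide acquisition span.
BROADBAND_CANONICAL = BandSpec("broadband", 1.0, 119.0)
BROADBAND_WIDE = BandSpec("broadband", 0.3, 250.0)


@dataclass(frozen=True)
class SegmentSpec:
    """A named sub-window of the epoch, in seconds relative to stimulus onset."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"segment {self.name!r}: start_s must be < end_s "
                f"(got {self.start_s}, {self.end_s})"
            )


COVERT = SegmentSpec("covert", 1.0, 2.0)
OVERT = SegmentSpec("overt", 2.0, 4.5)
FULL = SegmentSpec("full", -0.5, 4.5)
SEGMENTS: Mapping[str, SegmentSpec] = {s.name: s for s in (COVERT, OVERT, FULL)}


@dataclass
class EpochSet:
    """Epoched multichannel recordings with per-trial labels.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_samples).
    fs
        Sampling rate in Hz, > 0.
    t0
        Time of the first sample relative to stimulus onset, in seconds.
    channel_ids
        Ordered channel labels; channel identity is by label, not position.
    trials
        DataFrame with one row per trial and columns
        ``participant_id, cohort, phrase_id, trial_index, valid``.
    """

    data: np.ndarray
    fs: float
    t0: float
    channel_ids: list[str]
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_ids = [str(c) for c in self.channel_ids]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs: sampling rate must be > 0, got {self.fs}")
        if self.data.ndim != 3:
            raise ValidationError(
                f"data: expected 3-D (trial, channel, sample), got ndim={self.data.ndim}"
            )
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValidationError(
                f"channel_ids: {len(self.channel_ids)} labels for "
                f"{self.data.shape[1]} channels"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("channel_ids: labels must be unique")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValidationError(f"trials: missing metadata columns {missing}")
        if len(self.trials) != self.data.shape[0]:
            raise ValidationError(
                f"trials: {len(self.trials)} metadata rows for "
                f"{self.data.shape[0]} trials"
            )
        bad_cohort = set(self.trials["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise ValidationError(f"cohort: unknown labels {sorted(bad_cohort)}")

    # -- conveniences ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def select_trials(self, index: np.ndarray | Sequence[int]) -> "EpochSet":
        """A new EpochSet restricted to the given trial positions (order kept)."""
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            fs=self.fs,
            t0=self.t0,
            channel_ids=list(self.channel_ids),
            trials=self.trials.iloc[index].reset_index(drop=True),
        )

    def replace(self, **kwargs) -> "EpochSet":
        return dataclasses.replace(self, **kwargs)

    def iter_cells(self) -> Iterable[tuple[tuple[str, int], "EpochSet"]]:
        """Yield ((participant_id, phrase_id), sub-EpochSet) per cell."""
        for key, sub in self.trials.groupby(["participant_id", "phrase_id"], sort=True):
            yield key, self.select_trials(sub.index.to_numpy())


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Knobs shared by the analysis stages, with study defaults."""

    bands: tuple[BandSpec, ...] = CANONICAL_BANDS
    broadband_mode: str = "canonical"  # "canonical" (1-119 Hz) or "wide" (0.3-250 Hz)
    lowpass_cutoff: float = 250.0
    lowpass_order: int = 4
    resample_fs: float = 1000.0
    notch_base: float = 60.0
    notch_order: int = 2
    notch_bandwidth: float = 2.0
    strong_pair_threshold: float = 0.5
    trial_cap: int = 60
    amp_thresh_factor: float = 5.0
    log_power: bool = False
    fisher_z: bool = False
    gamma_grid: tuple[float, ...] = (0.0, 0.01, 0.1, 0.3, 0.5, 1.0)
    delta_grid: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    cv_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.broadband_mode not in ("canonical", "wide"):
            raise ValidationError(
                f"broadband_mode: expected 'canonical' or 'wide', got {self.broadband_mode!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError(f"seed: must be an integer, got {self.seed!r}")
        for b in self.bands:
            if not isinstance(b, BandSpec):
                raise ValidationError(f"bands: expected BandSpec entries, got {b!r}")

    @property
    def broadband(self) -> BandSpec:
        return BROADBAND_CANONICAL if self.broadband_mode == "canonical" else BROADBAND_WIDE

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    Absent keys take their defaults; unknown keys raise an error listing the
    valid key set.  ``bands`` entries are mappings with name/lo/hi.
    """
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return AnalysisConfig()
    if not isinstance(raw, dict):
        raise ValidationError(f"config: expected a mapping at top level, got {type(raw).__name__}")
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValidationError(
            f"config: unknown keys {sorted(unknown)}; valid keys are {sorted(valid)}"
        )
    kwargs = dict(raw)
    if "bands" in kwargs:
        bands = []
        for entry in kwargs["bands"]:
            try:
                bands.append(BandSpec(str(entry["name"]), float(entry["lo"]), float(entry["hi"])))
            except (KeyError, TypeError) as exc:
                raise ValidationError(f"config: malformed band entry {entry!r}") from exc
        kwargs["bands"] = tuple(bands)
    for key in ("gamma_grid", "delta_grid"):
        if key in kwargs:
            kwargs[key] = tuple(float(v) for v in kwargs[key])
    return AnalysisConfig(**kwargs)


# ---------------------------------------------------------------------------
# HDF5 epoch container
# ---------------------------------------------------------------------------

_KNOWN_ROOT_ATTRS = {"schema", "schema_version", "fs", "t0", "n_samples"}


def write_epochs(es: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet to an HDF5 container (one group per participant,
    one dataset per phrase).  Round-trips bit-exactly through
    :func:`read_epochs`."""
    es.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _SCHEMA
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["fs"] = float(es.fs)
        f.attrs["t0"] = float(es.t0)
        f.attrs["n_samples"] = int(es.n_samples)
        f.create_dataset("channel_ids", data=np.array(es.channel_ids, dtype="S"))
        part_grp = f.create_group("participants")
        order = np.arange(es.n_trials)
        for pid, sub in es.trials.groupby("participant_id", sort=True):
            g = part_grp.create_group(str(pid))
            cohorts = sub["cohort"].unique()
            if len(cohorts) != 1:
                raise ValidationError(
                    f"participant {pid!r} appears in multiple cohorts: {sorted(cohorts)}"
                )
            g.attrs["cohort"] = str(cohorts[0])
            for phrase, cell in sub.groupby("phrase_id", sort=True):
                idx = cell.index.to_numpy()
                ds = g.create_dataset(f"phrase_{int(phrase)}", data=es.data[idx])
                ds.attrs["phrase_id"] = int(phrase)
                ds.attrs["trial_index"] = cell["trial_index"].to_numpy(dtype=np.int64)
                ds.attrs["valid"] = cell["valid"].to_numpy(dtype=bool)
                ds.attrs["order"] = order[idx]
    return path


class ContainerError(IOError):
    """The file is missing, truncated, or not a recognized epoch container."""


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`.

    Unknown extra attributes are ignored with a logged warning; a schema
    version mismatch or a corrupt file raises :class:`ContainerError`.
    """
    path = Path(path)
    if not path.exists():
        raise ContainerError(f"no such file: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerError(f"cannot open {path} as an epoch container: {exc}") from exc
    with f:
        if f.attrs.get("schema") != _SCHEMA:
            raise ContainerError(f"{path}: not a {_SCHEMA} container")
        version = int(f.attrs.get("schema_version", -1))
        if version != _SCHEMA_VERSION:
            raise ContainerError(
                f"{path}: schema version {version} not supported (expected {_SCHEMA_VERSION})"
            )
        extras = set(f.attrs) - _KNOWN_ROOT_ATTRS
        if extras:
            logger.warning("ignoring unknown container attributes: %s", sorted(extras))
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs["t0"])
        channel_ids = [c.decode() for c in f["channel_ids"][()]]
        blocks: list[tuple[np.ndarray, np.ndarray, pd.DataFrame]] = []
        for pid in f["participants"]:
            g = f["participants"][pid]
            cohort = str(g.attrs["cohort"])
            for name in g:
                ds = g[name]
                meta = pd.DataFrame(
                    {
                        "participant_id": pid,
                        "cohort": cohort,
                        "phrase_id": int(ds.attrs["phrase_id"]),
                        "trial_index": np.asarray(ds.attrs["trial_index"], dtype=np.int64),
                        "valid": np.asarray(ds.attrs["valid"], dtype=bool),
                    }
                )
                blocks.append((np.asarray(ds.attrs["order"]), ds[()], meta))
    order = np.concatenate([b[0] for b in blocks])
    data = np.concatenate([b[1] for b in blocks], axis=0)
    trials = pd.concat([b[2] for b in blocks], ignore_index=True)
    perm = np.argsort(order)
    return EpochSet(
        data=data[perm],
        fs=fs,
        t0=t0,
        channel_ids=channel_ids,
        trials=trials.iloc[perm].reset_index(drop=True),
    )
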