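"""Single-trial cohort classification with regularized LDA and
leave-one-participant-pair-out cross-validation.

The model is a two-class linear discriminant with two regularizers: a
shrinkage weight gamma in [0, 1] pulling the pooled covariance toward its
diagonal, S_gamma = (1 - gamma) S + gamma diag(S), and a coefficient
threshold delta >= 0 that zeroes discriminant weights with |w_j| <= delta.
Features (per-channel band power for one band, or broadband) are
standardized with training-fold statistics only, so the delta scale is
comparable across bands.

Hyperparameters are tuned per outer fold by an exhaustive seeded grid
search scored with stratified 10-fold accuracy on the training data; ties
break toward more regularization (larger gamma, then larger delta).  Each
outer fold holds out one healthy and one patient participant entirely —
9 folds for 3 + 3 participants — so the reported accuracy measures
generalization to unseen participants.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core_io import COHORTS, ValidationError
from .spectral import BandPowerTable

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "RLDAModel",
    "Fold",
    "FoldResult",
    "CVReport",
    "extract_features",
    "fit_rlda",
    "tune_hyperparams",
    "lopo_folds",
    "lopo_cv",
]

DEFAULT_GAMMA_GRID = (0.0, 0.01, 0.1, 0.3, 0.5, 1.0)
DEFAULT_DELTA_GRID = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class FeatureMatrix:
    """Trial x feature array with cohort labels and trial metadata."""

    X: np.ndarray
    y: np.ndarray  # cohort label per trial ("healthy" / "patient")
    meta: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)
    band: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValidationError(f"X: expected 2-D, got ndim={self.X.ndim}")
        if len(self.y) != len(self.X) or len(self.meta) != len(self.X):
            raise ValidationError("X, y and meta must have one row per trial")
        if not np.isfinite(self.X).all():
            raise ValidationError("X contains non-finite values")


def extract_features(
    bpt: BandPowerTable,
    bands: str | Sequence[str],
    log10: bool = False,
) -> FeatureMatrix:
    """One row per trial, one column per channel (columns concatenated over
    bands when several are requested); optional log10 transform."""
    names = [bands] if isinstance(bands, str) else list(bands)
    cols = [bpt.values[:, :, bpt.band_index(b)] for b in names]
    X = np.concatenate(cols, axis=1)
    if log10:
        if (X <= 0).any():
            raise ValidationError("log10 transform requires strictly positive powers")
        X = np.log10(X)
    feature_names = [f"{b}:{c}" for b in names for c in bpt.channel_ids]
    return FeatureMatrix(
        X=X,
        y=bpt.trials["cohort"].to_numpy(),
        meta=bpt.trials.copy(),
        feature_names=feature_names,
        band="+".join(names),
    )


# ---------------------------------------------------------------------------
# Regularized LDA
# ---------------------------------------------------------------------------


@dataclass
class RLDAModel:
    classes: tuple[str, str]
    means: np.ndarray  # (2, p)
    gamma: float
    delta: float
    priors: np.ndarray
    weights: np.ndarray
    bias: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision(X)
        if not self.weights.any():
            # all coefficients thresholded away: fall back to the prior-majority class
            majority = self.classes[int(np.argmax(self.priors))]
            return np.full(len(scores), majority, dtype=object)
        return np.where(scores > 0, self.classes[1], self.classes[0])


def fit_rlda(
    fm: FeatureMatrix | None = None,
    gamma: float = 0.0,
    delta: float = 0.0,
    *,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    priors: Sequence[float] | None = None,
) -> RLDAModel:
    """Fit the two-class shrinkage LDA.

    weights = S_gamma^{-1} (mu_1 - mu_0) with
    S_gamma = (1 - gamma) S + gamma diag(S); coefficients with
    |w_j| <= delta are zeroed.  At gamma = 0 a singular pooled covariance
    (e.g. more features than trials) is an explicit error recommending
    gamma > 0.
    """
    if fm is not None:
        X, y = fm.X, fm.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 0 <= gamma <= 1:
        raise ValidationError(f"gamma must be in [0, 1], got {gamma}")
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    classes = tuple(sorted(np.unique(y)))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    masks = [y == c for c in classes]
    counts = np.array([m.sum() for m in masks])
    if (counts < 2).any():
        raise ValidationError("need >= 2 trials per class")
    means = np.stack([X[m].mean(axis=0) for m in masks])
    centered = X.copy()
    for m, mu in zip(masks, means):
        centered[m] -= mu
    pooled = centered.T @ centered / (len(X) - 2)
    s_gamma = (1 - gamma) * pooled + gamma * np.diag(np.diag(pooled))
    diff = means[1] - means[0]
    try:
        low = np.linalg.cholesky(s_gamma + 0.0)
        weights = np.linalg.solve(low.T, np.linalg.solve(low, diff))
    except np.linalg.LinAlgError:
        raise ValidationError(
            "regularized covariance is singular (features may outnumber trials); "
            "use gamma > 0"
        ) from None
    weights = np.where(np.abs(weights) <= delta, 0.0, weights)
    pri = (
        counts / counts.sum()
        if priors is None
        else np.asarray(priors, dtype=float) / np.sum(priors)
    )
    bias = -0.5 * weights @ (means[0] + means[1]) + np.log(pri[1] / pri[0])
    return RLDAModel(
        classes=classes,
        means=means,
        gamma=gamma,
        delta=delta,
        priors=pri,
        weights=weights,
        bias=float(bias),
    )


class _Standardizer:
    """Mean/sd scaling fitted on training folds only."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        self.sd = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def tune_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive grid search scored by stratified k-fold accuracy.

    Grid points that cannot be fitted (singular covariance at gamma = 0)
    score minus infinity and are never selected; ties break toward larger
    gamma, then larger delta.
    """
    grid = list(itertools.product(gamma_grid, delta_grid))
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    _, counts = np.unique(y, return_counts=True)
    k = min(k, int(counts.min()))
    if k < 2:
        raise ValidationError("not enough trials per class for inner cross-validation")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = [
        (tr, te)
        for tr, te in splitter.split(X, y)
    ]
    folds = []
    for tr, te in splits:
        scaler = _Standardizer().fit(X[tr])
        folds.append((scaler.transform(X[tr]), y[tr], scaler.transform(X[te]), y[te]))
    scores: dict[tuple[float, float], float] = {}
    for gamma, delta in grid:
        accs = []
        try:
            for Xtr, ytr, Xte, yte in folds:
                model = fit_rlda(X=Xtr, y=ytr, gamma=gamma, delta=delta)
                accs.append(float(np.mean(model.predict(Xte) == yte)))
            scores[(gamma, delta)] = float(np.mean(accs))
        except ValidationError:
            scores[(gamma, delta)] = -np.inf
    best = max(scores, key=lambda gd: (scores[gd], gd[0], gd[1]))
    if scores[best] == -np.inf:
        raise ValidationError("no feasible hyperparameter grid point")
    return best


# ---------------------------------------------------------------------------
# Leave-one-participant-pair-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class Fold:
    test_pair: tuple[str, str]  # (healthy participant, patient participant)
    train_idx: np.ndarray
    test_idx: np.ndarray


def lopo_folds(meta: pd.DataFrame) -> list[Fold]:
    """One fold per (healthy, patient) participant pair held out for testing."""
    cohort_of = meta.groupby("participant_id")["cohort"].unique()
    multi = [p for p, c in cohort_of.items() if len(c) > 1]
    if multi:
        raise ValidationError(f"participant(s) {multi} appear in both cohorts")
    healthy = sorted(p for p, c in cohort_of.items() if c[0] == "healthy")
    patient = sorted(p for p, c in cohort_of.items() if c[0] == "patient")
    if len(healthy) < 2 or len(patient) < 2:
        raise ValidationError(
            f"need >= 2 participants per cohort, got {len(healthy)} healthy / "
            f"{len(patient)} patient"
        )
    pid = meta["participant_id"].to_numpy()
    folds = []
    for h, a in itertools.product(healthy, patient):
        test = np.flatnonzero((pid == h) | (pid == a))
        train = np.flatnonzero((pid != h) & (pid != a))
        folds.append(Fold(test_pair=(h, a), train_idx=train, test_idx=test))
    return folds


@dataclass
class FoldResult:
    test_pair: tuple[str, str]
    n_train: int
    n_test: int
    accuracy: float
    gamma: float
    delta: float
    predictions: np.ndarray | None = None


@dataclass
class CVReport:
    band: str
    folds: list[FoldResult]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "median_accuracy": self.median_accuracy,
            "folds": [
                {
                    "test_pair": list(f.test_pair),
                    "n_train": f.n_train,
                    "n_test": f.n_test,
                    "accuracy": f.accuracy,
                    "gamma": f.gamma,
                    "delta": f.delta,
                }
                for f in self.folds
            ],
        }


def lopo_cv(
    fm: FeatureMatrix,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
    k: int = 10,
    seed: int = 0,
    keep_predictions: bool = False,
) -> CVReport:
    """Leave-one-participant-pair-out cross-validation of the shrinkage LDA.

    Hyperparameters are re-tuned inside every fold on training data only;
    features are standardized with training-fold statistics.  The summary
    statistic is the median fold accuracy.
    """
    folds = lopo_folds(fm.meta)
    results = []
    for i, fold in enumerate(folds):
        Xtr, ytr = fm.X[fold.train_idx], fm.y[fold.train_idx]
        Xte, yte = fm.X[fold.test_idx], fm.y[fold.test_idx]
        gamma, delta = tune_hyperparams(
            Xtr, ytr, gamma_grid, delta_grid, k=k, seed=seed + i
        )
        scaler = _Standardizer().fit(Xtr)
        model = fit_rlda(X=scaler.transform(Xtr), y=ytr, gamma=gamma, delta=delta)
        pred = model.predict(scaler.transform(Xte))
        results.append(
            FoldResult(
                test_pair=fold.test_pair,
                n_train=len(fold.train_idx),
                n_test=len(fold.test_idx),
                accuracy=float(np.mean(pred == yte)),
                gamma=gamma,
                delta=delta,
                predictions=pred if keep_predictions else None,
            )
        )
    return CVReport(band=fm.band, folds=results)
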