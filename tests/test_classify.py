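import numpy as np
import pandas as pd
import pytest

from megspeech.classify import (
    FeatureMatrix,
    _Standardizer,
    extract_features,
    fit_rlda,
    lopo_cv,
    lopo_folds,
    tune_hyperparams,
)
from megspeech.core_io import CANONICAL_BANDS, ValidationError
from megspeech.spectral import BandPowerTable


def make_meta(participants, trials_each, phrases=(1,)):
    rows = []
    for pid in participants:
        cohort = "healthy" if pid.startswith("H") else "patient"
        for phrase in phrases:
            for t in range(trials_each):
                rows.append((pid, cohort, phrase, t + 1, True))
    return pd.DataFrame(
        rows, columns=["participant_id", "cohort", "phrase_id", "trial_index", "valid"]
    )


def make_bpt(rng, n_trials=10, n_channels=4):
    values = rng.uniform(0.5, 1.5, size=(n_trials, n_channels, len(CANONICAL_BANDS)))
    return BandPowerTable(
        values=values,
        bands=CANONICAL_BANDS,
        channel_ids=[f"c{i}" for i in range(n_channels)],
        trials=make_meta(["H1", "A1"], n_trials // 2),
    )


def gaussian_fm(rng, n=200, p=2, sep=5.0, participants=("H1", "A1")):
    X = np.vstack([rng.normal(0, 1, (n, p)), rng.normal(sep, 1, (n, p))])
    meta = pd.concat(
        [make_meta([participants[0]], n), make_meta([participants[1]], n)],
        ignore_index=True,
    )
    return FeatureMatrix(X=X, y=meta["cohort"].to_numpy(), meta=meta)


class TestExtractFeatures:
    def test_one_column_per_channel(self, rng):
        bpt = make_bpt(rng)
        fm = extract_features(bpt, "beta")
        assert fm.X.shape == (10, 4)
        assert fm.band == "beta"

    def test_log_transform_of_unit_powers_is_zero(self, rng):
        bpt = make_bpt(rng)
        bpt.values[:] = 1.0
        fm = extract_features(bpt, "beta", log10=True)
        assert not fm.X.any()

    def test_two_band_concatenation_doubles_columns(self, rng):
        fm = extract_features(make_bpt(rng), ["beta", "delta"])
        assert fm.X.shape == (10, 8)
        assert fm.feature_names[0].startswith("beta:")
        assert fm.feature_names[4].startswith("delta:")

    def test_missing_band_rejected(self, rng):
        with pytest.raises(ValidationError, match="broadband"):
            extract_features(make_bpt(rng), "broadband")


class TestFitRlda:
    def test_separable_classes_fit_near_perfectly(self, rng):
        fm = gaussian_fm(rng)
        model = fit_rlda(fm)
        assert np.mean(model.predict(fm.X) == fm.y) >= 0.99

    def test_full_shrinkage_equals_diagonal_closed_form(self, rng):
        fm = gaussian_fm(rng)
        model = fit_rlda(fm, gamma=1.0)
        mu0 = fm.X[fm.y == "healthy"].mean(axis=0)
        mu1 = fm.X[fm.y == "patient"].mean(axis=0)
        centered = fm.X.copy()
        centered[fm.y == "healthy"] -= mu0
        centered[fm.y == "patient"] -= mu1
        pooled_diag = np.diag(centered.T @ centered / (len(fm.X) - 2))
        np.testing.assert_allclose(model.weights, (mu1 - mu0) / pooled_diag)

    def test_threshold_above_max_weight_predicts_prior_majority(self, rng):
        fm = gaussian_fm(rng)
        base = fit_rlda(fm)
        model = fit_rlda(fm, delta=np.max(np.abs(base.weights)) + 1.0)
        assert not model.weights.any()
        majority = model.classes[int(np.argmax(model.priors))]
        assert set(model.predict(fm.X)) == {majority}

    def test_singular_covariance_at_zero_gamma_recommends_shrinkage(self, rng):
        fm = gaussian_fm(rng, n=5, p=20)  # more features than trials
        with pytest.raises(ValidationError, match="gamma"):
            fit_rlda(fm, gamma=0.0)
        fit_rlda(fm, gamma=0.5)  # shrinkage makes it well-posed

    def test_gamma_zero_predictions_invariant_to_feature_scaling(self, rng):
        fm = gaussian_fm(rng, sep=1.0)
        scales = np.array([100.0, 0.01])
        m1 = fit_rlda(fm)
        m2 = fit_rlda(X=fm.X * scales, y=fm.y)
        np.testing.assert_array_equal(m1.predict(fm.X), m2.predict(fm.X * scales))


class TestTuning:
    def test_single_point_grid_returned_directly(self, rng):
        fm = gaussian_fm(rng, n=20)
        assert tune_hyperparams(fm.X, fm.y, [0.3], [0.001], k=5) == (0.3, 0.001)

    def test_singular_grid_points_never_selected(self, rng):
        fm = gaussian_fm(rng, n=12, p=40, sep=0.1)  # p > n in every inner fold
        gamma, _ = tune_hyperparams(fm.X, fm.y, [0.0, 0.5], [0.0], k=3, seed=0)
        assert gamma == 0.5

    def test_separable_data_tie_breaks_to_most_regularized(self, rng):
        fm = gaussian_fm(rng, n=50, sep=20.0)
        gamma, delta = tune_hyperparams(
            fm.X, fm.y, [0.0, 0.5, 1.0], [0.0, 1e-3], k=5, seed=0
        )
        assert (gamma, delta) == (1.0, 1e-3)


class TestLopoCv:
    def test_fold_structure_for_three_plus_three(self):
        meta = make_meta(["H1", "H2", "H3", "A1", "A2", "A3"], 60, phrases=range(1, 6))
        folds = lopo_folds(meta)
        assert len(folds) == 9
        for fold in folds:
            assert len(fold.train_idx) == 1200
            assert len(fold.test_idx) == 600
        pairs = {f.test_pair for f in folds}
        assert len(pairs) == 9  # exhaustive healthy x patient pairing

    def test_participant_in_both_cohorts_rejected(self):
        meta = make_meta(["H1", "H2", "A1"], 4)
        meta.loc[meta.index[-1], "participant_id"] = "H1"
        with pytest.raises(ValidationError, match="both cohorts"):
            lopo_folds(meta)

    def test_fewer_than_two_per_cohort_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 participants"):
            lopo_folds(make_meta(["H1", "A1", "A2"], 4))

    def _separable_fm(self, rng, n_per=30):
        parts = ["H1", "H2", "A1", "A2"]
        metas, Xs = [], []
        for pid in parts:
            metas.append(make_meta([pid], n_per))
            mean = 0.0 if pid.startswith("H") else 4.0
            Xs.append(rng.normal(mean, 1.0, (n_per, 3)))
        meta = pd.concat(metas, ignore_index=True)
        return FeatureMatrix(np.vstack(Xs), meta["cohort"].to_numpy(), meta)

    def test_no_information_leak_from_test_pair(self, rng):
        """Dropping the held-out pair's trials from the container leaves the
        fold's fitted weights byte-identical."""
        fm = self._separable_fm(rng)
        folds = lopo_folds(fm.meta)
        fold = folds[0]
        gamma, delta = tune_hyperparams(
            fm.X[fold.train_idx], fm.y[fold.train_idx], k=5, seed=3
        )
        scaler = _Standardizer().fit(fm.X[fold.train_idx])
        full = fit_rlda(
            X=scaler.transform(fm.X[fold.train_idx]),
            y=fm.y[fold.train_idx],
            gamma=gamma,
            delta=delta,
        )
        keep = np.ones(len(fm.X), dtype=bool)
        keep[fold.test_idx] = False
        reduced_fm = FeatureMatrix(
            fm.X[keep], fm.y[keep], fm.meta[keep].reset_index(drop=True)
        )
        gamma2, delta2 = tune_hyperparams(reduced_fm.X, reduced_fm.y, k=5, seed=3)
        scaler2 = _Standardizer().fit(reduced_fm.X)
        reduced = fit_rlda(
            X=scaler2.transform(reduced_fm.X), y=reduced_fm.y, gamma=gamma2, delta=delta2
        )
        assert (gamma, delta) == (gamma2, delta2)
        assert full.weights.tobytes() == reduced.weights.tobytes()

    def test_separable_participants_classified_perfectly(self, rng):
        fm = self._separable_fm(rng)
        report = lopo_cv(fm, gamma_grid=[0.1], delta_grid=[0.0], k=5, seed=0)
        assert len(report.folds) == 4
        assert report.median_accuracy == 1.0

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        """Shuffling features within participants (null association) drives the
        median fold accuracy to the balanced-chance level."""
        parts = ["H1", "H2", "A1", "A2"]
        n_per = 60
        meta = pd.concat([make_meta([p], n_per) for p in parts], ignore_index=True)
        X = rng.normal(size=(len(meta), 5))  # features carry no cohort signal
        fm = FeatureMatrix(X, meta["cohort"].to_numpy(), meta)
        report = lopo_cv(fm, gamma_grid=[0.1, 1.0], delta_grid=[0.0], k=5, seed=0)
        accs = report.accuracies
        se = np.sqrt(0.25 / (2 * n_per))
        assert abs(np.median(accs) - 0.5) <= 3 * max(se, accs.std(ddof=1))
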