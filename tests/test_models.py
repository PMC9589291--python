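"""Class balancing, grid-search cross-validation and final evaluation."""

import numpy as np
import pytest
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from coldcre.genes import GeneRecord
from coldcre.models import (
    HyperparameterGrid,
    _fit_forest,
    balance,
    downsample,
    grid_search_cv,
    smote,
    tfbm_feature_matrix,
    train_final_and_test,
)
from coldcre.pwm import TFBMRecord, kmer_to_pwm
from coldcre.simulate import InsufficientExamplesError


class TestGrid:
    def test_exactly_sixty_combinations(self):
        assert len(HyperparameterGrid().combinations()) == 60

    def test_axes_as_specified(self):
        g = HyperparameterGrid()
        assert g.max_depth == (3, 5, 10)
        assert g.max_features == (0.1, 0.5, "sqrt", "log2", None)
        assert g.n_estimators == (10, 100, 500, 1000)


class TestBalancing:
    def test_smote_balances_counts(self, rng):
        X = rng.random((50, 5))
        y = np.array([1] * 10 + [0] * 40)
        Xb, yb = smote(X, y, rng=rng)
        assert (yb == 1).sum() == (yb == 0).sum() == 40
        assert len(Xb) == 80

    def test_smote_identical_minority_points_reproduced(self, rng):
        X = np.vstack([np.ones((2, 4)), np.zeros((10, 4))])
        y = np.array([1] * 2 + [0] * 10)
        Xb, yb = smote(X, y, rng=rng)
        assert np.allclose(Xb[yb == 1], 1.0)

    def test_smote_interpolates_between_minority_neighbours(self, rng):
        X = np.vstack([np.zeros((3, 2)), [[1, 1]] * 2, np.full((20, 2), 5.0)])
        y = np.array([1] * 5 + [0] * 20)
        Xb, yb = smote(X, y, rng=rng)
        synth = Xb[len(X):]
        # synthetic points lie in the convex hull of the minority points
        assert (synth >= 0).all() and (synth <= 1).all()

    def test_downsample_deterministic_and_subset(self, rng):
        X = rng.random((60, 3))
        y = np.array([1] * 20 + [0] * 40)
        X1, y1 = balance(X, y, method="downsample", seed=9)
        X2, y2 = balance(X, y, method="downsample", seed=9)
        assert np.array_equal(X1, X2)
        assert (y1 == 1).sum() == (y1 == 0).sum() == 20
        # every kept row is an original row
        orig = {tuple(r) for r in X}
        assert all(tuple(r) in orig for r in X1)

    def test_single_class_rejected(self, rng):
        with pytest.raises(InsufficientExamplesError):
            smote(rng.random((5, 2)), np.ones(5), rng=rng)


SMALL_GRID = HyperparameterGrid(max_depth=(3, 5), max_features=("sqrt", 0.5),
                                n_estimators=(10, 50))


class TestGridSearchCV:
    def test_every_gene_validated_exactly_once(self, rng):
        X = rng.integers(0, 2, (60, 8)).astype(np.uint8)
        y = np.array([1] * 30 + [0] * 30)
        _, diag = grid_search_cv(X, y, grid=SMALL_GRID, seed=0)
        fold_of = diag["fold_of"]
        assert (fold_of >= 0).all()
        assert sum(diag["validation_sizes"]) == 60

    def test_validation_portions_never_resampled(self, rng):
        # leakage guard: balanced training sizes reflect the training folds
        # only; validation fold sizes are untouched
        X = rng.integers(0, 2, (60, 8)).astype(np.uint8)
        y = np.array([1] * 20 + [0] * 40)
        _, diag = grid_search_cv(X, y, grid=SMALL_GRID, seed=0)
        for bal_n, va_n in zip(diag["balanced_train_sizes"],
                               diag["validation_sizes"]):
            assert bal_n == 2 * 32  # 4/5 of 40 negatives, up-sampled pos
            assert va_n == 12

    def test_separable_data_reaches_perfect_cv_f1(self, rng):
        y = np.array([1] * 30 + [0] * 30)
        X = np.column_stack([y, rng.integers(0, 2, (60, 5))]).astype(np.uint8)
        _, diag = grid_search_cv(X, y, grid=SMALL_GRID, seed=0)
        assert max(r["mean_f1"] for r in diag["results"]) == pytest.approx(1.0)

    def test_matches_per_combination_fits(self, rng):
        # the shared-forest evaluation equals naive one-fit-per-combination
        X = rng.integers(0, 2, (50, 6)).astype(np.uint8)
        y = np.array([1] * 25 + [0] * 25)
        rng.shuffle(y)
        _, diag = grid_search_cv(X, y, grid=SMALL_GRID, folds=5, seed=3)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        splits = list(skf.split(X, y))
        bal = [balance(X[tr], y[tr], seed=3 + f)
               for f, (tr, _) in enumerate(splits)]
        for r in diag["results"]:
            naive = []
            for f, ((tr, va), (Xb, yb)) in enumerate(zip(splits, bal)):
                clf = _fit_forest(Xb, yb, r["hyperparameters"], seed=3 + 1000 * f)
                naive.append(f1_score(y[va], clf.predict(X[va]),
                                      zero_division=0.0))
            assert np.allclose(naive, r["fold_f1"])

    def test_tie_break_prefers_smaller_model(self, rng):
        y = np.array([1] * 30 + [0] * 30)
        X = np.column_stack([y]).astype(np.uint8)  # trivially separable
        best, _ = grid_search_cv(X, y, grid=SMALL_GRID, seed=0)
        assert best["n_estimators"] == 10
        assert best["max_depth"] == 3

    def test_too_few_genes_rejected(self, rng):
        X = rng.integers(0, 2, (6, 3)).astype(np.uint8)
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(InsufficientExamplesError):
            grid_search_cv(X, y, grid=SMALL_GRID, folds=5)


class TestFinalModel:
    def test_separable_test_f1_is_one(self, rng):
        y = np.array([1] * 20 + [0] * 20)
        X = np.column_stack([y, rng.integers(0, 2, (40, 3))]).astype(np.uint8)
        hp = {"max_depth": 3, "max_features": None, "n_estimators": 10}
        rep = train_final_and_test(X, y, X, y, hp, seed=0)
        assert rep.test_f1 == pytest.approx(1.0)
        assert not rep.degenerate

    def test_uninformative_features_all_negative_flagged(self, rng):
        # constant features + negative majority -> forest predicts negative
        y_tr = np.array([1] * 10 + [0] * 30)
        X_tr = np.zeros((40, 3), dtype=np.uint8)
        y_te = np.array([1] * 5 + [0] * 15)
        X_te = np.zeros((20, 3), dtype=np.uint8)
        hp = {"max_depth": 3, "max_features": None, "n_estimators": 10}
        rep = train_final_and_test(X_tr, y_tr, X_te, y_te, hp, seed=0,
                                   balance_method="downsample")
        if rep.degenerate:
            assert rep.test_f1 == 0.0

    def test_importances_minmax_scaled(self, rng):
        y = np.array([1] * 25 + [0] * 25)
        X = np.column_stack([y, rng.integers(0, 2, (50, 4))]).astype(np.uint8)
        hp = {"max_depth": 5, "max_features": None, "n_estimators": 50}
        rep = train_final_and_test(X, y, X, y, hp, seed=0)
        assert rep.importances_scaled.min() == pytest.approx(0.0)
        assert rep.importances_scaled.max() == pytest.approx(1.0)
        assert rep.importances_scaled.argmax() == 0  # the label-copy feature


class TestTfbmFeatures:
    def _genes(self, rng, n=16, motif="GATTACA"):
        genes, carries = [], []
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), 80))
            if i % 2 == 0:
                seq = seq[:30] + motif + seq[30 + len(motif):]
            genes.append(GeneRecord(f"g{i}", upstream_seq=seq))
            carries.append(i % 2 == 0)
        return genes, np.array(carries)

    def test_planted_pwm_matches_carrier_genes(self, rng):
        genes, carries = self._genes(rng)
        lib = [
            TFBMRecord("tf0", "FA", kmer_to_pwm("GATTACA", "tf0")),
            TFBMRecord("tf1", "FA", kmer_to_pwm("GATCACA", "tf1")),
        ]
        X, names = tfbm_feature_matrix(genes, lib)
        assert names[0] == "tf0"
        # genes carrying the exact consensus score pcc 1 > family background
        assert np.array_equal(X[:, 0].astype(bool), carries)

    def test_empty_library_rejected(self, rng):
        genes, _ = self._genes(rng, n=4)
        with pytest.raises(ValueError, match="no-features"):
            tfbm_feature_matrix(genes, [])

    def test_tfbm_model_learns_from_planted_motif(self, rng):
        from coldcre.models import tfbm_model

        genes, carries = self._genes(rng, n=60)
        y = carries.astype(int)
        lib = [
            TFBMRecord("tf0", "FA", kmer_to_pwm("GATTACA", "tf0")),
            TFBMRecord("tf1", "FA", kmer_to_pwm("GATCACA", "tf1")),
        ]
        grid = HyperparameterGrid(max_depth=(3,), max_features=(None,),
                                  n_estimators=(10,))
        rep = tfbm_model(genes, lib, y, grid=grid, seed=0)
        assert rep.test_f1 >= 0.8  # motif presence is fully informative
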