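import numpy as np
import pytest

import rxnmix as rx
from rxnmix.som import (
    CONFLICT,
    EMPTY,
    SOMClassifier,
    _find_winners,
    _init_weights,
    _torus_distance_matrix,
    load_som,
    majority_vote,
    save_som,
    toroidal_distance,
)


class TestToroidalDistance:
    def test_corner_wraparound(self):
        assert toroidal_distance((0, 0), (48, 48), 49, 49) == 1

    def test_antipodal(self):
        assert toroidal_distance((0, 0), (24, 24), 49, 49) == 24

    def test_identity(self):
        assert toroidal_distance((5, 7), (5, 7), 49, 49) == 0

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError):
            toroidal_distance((0, 0), (49, 0), 49, 49)

    @pytest.mark.parametrize("d", [1, 3, 10, 24])
    def test_neighborhood_cardinality(self, d):
        """On the torus every neuron sees (2d+1)^2 cells within distance d."""
        dmat = _torus_distance_matrix(49, 49)
        counts = (dmat <= d).sum(axis=1)
        assert np.all(counts == (2 * d + 1) ** 2)

    def test_distance_matrix_agrees_with_scalar(self):
        rows, cols = 7, 5
        dmat = _torus_distance_matrix(rows, cols)
        rng = np.random.default_rng(0)
        for _ in range(30):
            i, j = rng.integers(0, rows * cols, 2)
            assert dmat[i, j] == toroidal_distance(
                divmod(int(i), cols), divmod(int(j), cols), rows, cols
            )


class TestWinner:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(25, 8))
        X = rng.normal(size=(200, 8))
        winners = _find_winners(W, X)
        for x, w in zip(X, winners):
            brute = int(np.argmin([np.linalg.norm(x - wv) for wv in W]))
            assert w == brute

    def test_exact_tie_takes_lower_index(self):
        W = np.zeros((4, 3))
        W[1] = W[3] = [1.0, 1.0, 1.0]
        x = np.array([[1.0, 1.0, 1.0]])
        assert _find_winners(W, x)[0] == 1


class TestInitialization:
    def test_constant_column_stays_constant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        X[:, 1] = 4.2
        W = _init_weights(X, 100, np.random.default_rng(0))
        assert W[:, 1] == pytest.approx(4.2)

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(3).normal(size=(40, 5))
        W1 = _init_weights(X, 30, np.random.default_rng(7))
        W2 = _init_weights(X, 30, np.random.default_rng(7))
        assert np.array_equal(W1, W2)

    def test_component_means_match_data(self):
        rng = np.random.default_rng(4)
        X = rng.normal(loc=[0, 5, -2], scale=[1, 2, 0.5], size=(200, 3))
        n = 49 * 49
        W = _init_weights(X, n, np.random.default_rng(0))
        sd = X.std(axis=0)
        assert np.all(np.abs(W.mean(axis=0) - X.mean(axis=0)) < 3 * sd / np.sqrt(n))


class TestTraining:
    def test_bitwise_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = np.array(["a", "b"] * 30, dtype=object)
        m1 = SOMClassifier(rows=5, cols=5, epochs=10, random_state=9).fit(X, y)
        m2 = SOMClassifier(rows=5, cols=5, epochs=10, random_state=9).fit(X, y)
        assert np.array_equal(m1.weights_, m2.weights_)
        assert list(m1.label_map_) == list(m2.label_map_)

    def test_zero_learning_rate_is_noop(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        y = np.array(["a"] * 30, dtype=object)
        som = SOMClassifier(rows=4, cols=4, epochs=5, lr0=0.0, random_state=1).fit(X, y)
        init = _init_weights(X, 16, np.random.default_rng(1))
        assert np.array_equal(som.weights_, init)

    def test_training_contracts_weights_toward_data(self):
        """Longer training pulls some neuron ever closer to each input."""
        X = np.array([[0.0, 0.0, 0.0], [4.0, 4.0, 4.0]])
        y = np.array(["a", "b"], dtype=object)
        init = _init_weights(X, 16, np.random.default_rng(3))

        def quantization_error(W):
            return np.mean([np.min(np.linalg.norm(W - x, axis=1)) for x in X])

        qe = {
            epochs: quantization_error(
                SOMClassifier(rows=4, cols=4, epochs=epochs, random_state=3)
                .fit(X, y)
                .weights_
            )
            for epochs in (10, 50)
        }
        assert qe[50] < qe[10] < quantization_error(init)

    def test_two_clusters_map_to_disjoint_neurons(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(5, 0.3, (40, 2))])
        y = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        som = SOMClassifier(rows=7, cols=7, epochs=25, random_state=2).fit(X, y)
        wins_a = set(_find_winners(som.weights_, X[:40]))
        wins_b = set(_find_winners(som.weights_, X[40:]))
        assert wins_a.isdisjoint(wins_b)

    def test_small_data_warns_about_map_size(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array(["a", "b"] * 5, dtype=object)
        with pytest.warns(UserWarning, match="neurons"):
            SOMClassifier(rows=5, cols=5, epochs=2, random_state=0).fit(X, y)


class TestLabelingAndClassification:
    def _manual_model(self, weights, label_map, effective):
        som = SOMClassifier(rows=2, cols=2)
        som.weights_ = np.asarray(weights, dtype=float)
        som.label_map_ = np.array(label_map, dtype=object)
        som.effective_label_ = np.array(effective, dtype=object)
        som.classes_ = np.array(["C", "G", "N"], dtype=object)
        som.n_features_in_ = som.weights_.shape[1]
        return som

    def test_single_class_data_never_conflicts(self):
        X = np.random.default_rng(1).normal(size=(30, 3))
        y = np.array(["only"] * 30, dtype=object)
        som = SOMClassifier(rows=3, cols=3, epochs=5, random_state=0).fit(X, y)
        assert CONFLICT not in set(som.label_map_)
        non_empty = [l for l in som.label_map_ if l != EMPTY]
        assert set(non_empty) == {"only"}

    def test_duplicate_vectors_of_two_classes_conflict(self):
        X = np.tile([[1.0, 2.0]], (6, 1))
        y = np.array(["a", "b"] * 3, dtype=object)
        som = SOMClassifier(rows=2, cols=2, epochs=3, random_state=0).fit(X, y)
        assert CONFLICT in set(som.label_map_)

    def test_status_fractions_partition_grid(self, small_problem):
        X, y = small_problem["X"][:80], small_problem["y"][:80]
        som = SOMClassifier(rows=5, cols=5, epochs=8, random_state=4).fit(X, y)
        s = som.label_summary()
        assert s["labeled"] + s["empty"] + s["conflict"] == pytest.approx(1.0)

    def test_training_vector_recovers_its_class(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.2, (20, 2)), rng.normal(4, 0.2, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        som = SOMClassifier(rows=5, cols=5, epochs=20, random_state=1).fit(X, y)
        assert list(som.predict(X[:3])) == ["a"] * 3

    def test_empty_winner_falls_back_to_nearest_labeled(self):
        som = self._manual_model(
            weights=[[0, 0], [10, 10], [20, 20], [30, 30]],
            label_map=[EMPTY, "C", EMPTY, EMPTY],
            effective=[None, "C", None, None],
        )
        assert som.predict(np.array([[0.1, 0.1]]))[0] == "C"

    def test_conflict_plurality_class_used(self):
        X = np.tile([[1.0, 1.0]], (4, 1))
        y = np.array(["G", "G", "G", "N"], dtype=object)
        som = SOMClassifier(rows=2, cols=2, epochs=2, random_state=0).fit(X, y)
        # all four identical vectors land on one conflicted neuron; plurality G
        assert som.predict(np.array([[1.0, 1.0]]))[0] == "G"

    def test_conflict_tie_is_undecided(self):
        som = self._manual_model(
            weights=[[0, 0], [10, 10], [20, 20], [30, 30]],
            label_map=[CONFLICT, "C", EMPTY, EMPTY],
            effective=[None, "C", None, None],
        )
        assert som.predict(np.array([[0.1, 0.1]]))[0] == rx.UNDECIDED

    def test_unlabeled_model_rejected(self):
        som = self._manual_model(
            weights=[[0, 0], [1, 1], [2, 2], [3, 3]],
            label_map=[EMPTY] * 4,
            effective=[None] * 4,
        )
        with pytest.raises(ValueError, match="no labeled"):
            som.predict(np.array([[0.0, 0.0]]))


class TestEnsemble:
    def test_plurality(self):
        votes = np.array([["A"], ["A"], ["B"], [rx.UNDECIDED], ["A"]], dtype=object)
        assert majority_vote(votes)[0] == "A"

    def test_tie_is_undecided(self):
        votes = np.array([["A"], ["B"]], dtype=object)
        assert majority_vote(votes)[0] == rx.UNDECIDED

    def test_all_undecided(self):
        votes = np.array([[rx.UNDECIDED]] * 3, dtype=object)
        assert majority_vote(votes)[0] == rx.UNDECIDED

    def test_singleton_ensemble_equals_member(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(4, 0.3, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        ens = rx.SOMEnsemble(n_members=1, rows=5, cols=5, epochs=10, random_state=5).fit(X, y)
        assert list(ens.predict(X)) == list(ens.members_[0].predict(X))


def test_persistence_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(0, 0.3, (20, 3)), rng.normal(4, 0.3, (20, 3))])
    y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
    som = SOMClassifier(rows=4, cols=4, epochs=10, random_state=6).fit(X, y)
    save_som(som, tmp_path / "model")
    back = load_som(tmp_path / "model")
    assert np.array_equal(back.weights_, som.weights_)
    assert list(back.predict(X)) == list(som.predict(X))


def test_label_map_export_shape():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 2))
    y = np.array(["a", "b"] * 15, dtype=object)
    som = SOMClassifier(rows=3, cols=4, epochs=5, random_state=0).fit(X, y)
    df = som.label_map_frame()
    assert len(df) == 12
    assert set(df["status"]) <= {"labeled", EMPTY, CONFLICT}
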