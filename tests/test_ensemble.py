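"""SMOTE expansion, majority partitioning, subdataset construction, voting."""

import warnings

import numpy as np
import pytest

import jprotpred as jp


class TestSmoteExpand:
    def test_twenty_rows_expand_to_sixty_keeping_originals(self):
        rng = np.random.RandomState(0)
        X = rng.standard_normal((20, 6))
        out = jp.smote_expand(X, 60, k=5, seed=1)
        assert out.shape == (60, 6)
        np.testing.assert_array_equal(out[:20], X)

    def test_target_equal_to_size_is_identity(self):
        X = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(jp.smote_expand(X, 4, seed=0), X)

    def test_identical_rows_interpolate_to_identical_rows(self):
        X = np.tile([1.0, 2.0, 3.0], (2, 1))
        out = jp.smote_expand(X, 4, k=1, seed=0)
        assert np.all(out == [1.0, 2.0, 3.0])

    def test_synthetic_rows_are_convex_combinations_of_real_pairs(self):
        rng = np.random.RandomState(2)
        X = rng.standard_normal((10, 4))
        out = jp.smote_expand(X, 30, k=3, seed=3)
        for row in out[10:]:
            # row = x + u (y - x) for some pair (x, y): solve u per pair
            on_segment = False
            for i in range(10):
                for j in range(10):
                    if i == j:
                        continue
                    d = X[j] - X[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    u = (row - X[i]) @ d / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        row, X[i] + u * d, atol=1e-9
                    ):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_shrinking_target_rejected(self):
        with pytest.raises(jp.ValidationError):
            jp.smote_expand(np.zeros((5, 2)), 3)

    def test_single_row_rejected(self):
        with pytest.raises(jp.ValidationError):
            jp.smote_expand(np.zeros((1, 2)), 4)

    def test_oversized_k_clipped_with_warning(self):
        X = np.random.RandomState(0).standard_normal((3, 2))
        with pytest.warns(UserWarning, match="clipped"):
            out = jp.smote_expand(X, 6, k=5, seed=0)
        assert out.shape == (6, 2)

    def test_deterministic_under_seed(self):
        X = np.random.RandomState(1).standard_normal((8, 3))
        a = jp.smote_expand(X, 20, seed=42)
        b = jp.smote_expand(X, 20, seed=42)
        np.testing.assert_array_equal(a, b)


class TestPartitionMajority:
    def test_955_rows_into_20_groups_of_47_or_48(self):
        X = np.arange(955.0)[:, None]
        groups = jp.partition_majority(X, 20, seed=0)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [47] * 5 + [48] * 15
        assert sum(sizes) == 955

    def test_exact_division_gives_equal_groups(self):
        groups = jp.partition_majority(np.zeros((40, 2)), 20, seed=0)
        assert all(len(g) == 2 for g in groups)

    def test_groups_partition_the_input_multiset(self):
        X = np.arange(37.0)[:, None]
        groups = jp.partition_majority(X, 5, seed=3)
        recovered = sorted(float(v) for g in groups for v in g[:, 0])
        assert recovered == list(range(37))

    def test_fewer_rows_than_groups_rejected(self):
        with pytest.raises(jp.ValidationError):
            jp.partition_majority(np.zeros((3, 2)), 5)


class TestBuildSubdatasets:
    def make_data(self, counts):
        rng = np.random.RandomState(0)
        X, y = [], []
        for cls, cnt in counts.items():
            X.append(rng.standard_normal((cnt, 5)))
            y += [cls] * cnt
        return np.vstack(X), np.array(y)

    def test_benchmark_arithmetic_161_plus_47_or_48(self):
        # a training round after the pre-CV expansion of the rarest class:
        # counts {I:57, II:50, III:955, IV:54} -> each subdataset carries
        # the 161 non-majority rows plus one 47-or-48-row majority subpart
        X, y = self.make_data({"I": 57, "II": 50, "III": 955, "IV": 54})
        subs = jp.build_subdatasets(
            X, y, jp.EnsembleConfig(n_subsets=20, smote_target=60, seed=0)
        )
        assert len(subs) == 20
        for sub in subs:
            counts = dict(zip(*np.unique(sub.y, return_counts=True)))
            assert counts["I"] == 57 and counts["II"] == 50
            assert counts["IV"] == 54
            assert counts["I"] + counts["II"] + counts["IV"] == 161
            assert counts["III"] in (47, 48)
        majority_total = sum(
            np.sum(sub.y == "III") for sub in subs
        )
        assert majority_total == 955

    def test_fit_expands_rarest_class_once_when_enabled(
        self, tiny_features, monkeypatch
    ):
        X, y = tiny_features
        seen = {}
        original = jp.ensemble.build_subdatasets

        def spy(Xs, ys, config=None):
            seen["counts"] = dict(zip(*np.unique(ys, return_counts=True)))
            return original(Xs, ys, config)

        monkeypatch.setattr(jp.ensemble, "build_subdatasets", spy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            jp.BalancedSubsetVotingClassifier(
                n_subsets=2, smote_target=12, random_state=0
            ).fit(X, y)
        assert seen["counts"]["IV"] == 12  # rarest class 5 -> 12 at fit
        jp.BalancedSubsetVotingClassifier(
            n_subsets=2, smote_target=12, apply_smote=False, random_state=0
        ).fit(X, y)
        assert seen["counts"]["IV"] == 5  # upstream expansion assumed

    def test_single_subset_contains_whole_training_pool(self):
        X, y = self.make_data({"I": 5, "II": 4, "III": 30, "IV": 3})
        subs = jp.build_subdatasets(
            X, y, jp.EnsembleConfig(n_subsets=1, smote_target=3, seed=0)
        )
        assert len(subs) == 1
        assert len(subs[0].y) == len(y)

    def test_every_subdataset_contains_all_classes(self):
        X, y = self.make_data({"I": 6, "II": 5, "III": 44, "IV": 4})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            subs = jp.build_subdatasets(
                X, y, jp.EnsembleConfig(n_subsets=4, smote_target=8, seed=0)
            )
        for sub in subs:
            assert set(sub.y) == {"I", "II", "III", "IV"}


@pytest.fixture(scope="module")
def fitted(tiny_features):
    X, y = tiny_features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = jp.BalancedSubsetVotingClassifier(
            n_subsets=8, smote_target=10, random_state=0
        ).fit(X, y)
    return clf, X, y


class TestVotingClassifier:
    def test_round_robin_learner_assignment(self, fitted):
        clf, _, _ = fitted
        ids = [learner_id for learner_id, _ in clf.subclassifiers_]
        assert len(ids) == 8
        for family in jp.ensemble.DEFAULT_LEARNER_CYCLE:
            assert ids.count(family) == 2

    def test_vote_tallies_sum_to_n_subsets(self, fitted):
        clf, X, _ = fitted
        tallies = clf.vote_tallies(X)
        assert np.all(tallies.sum(axis=1) == 8)

    def test_refit_with_same_seed_reproduces_predictions(self, tiny_features):
        X, y = tiny_features
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = jp.BalancedSubsetVotingClassifier(
                n_subsets=4, smote_target=8, random_state=11
            ).fit(X, y).predict(X)
            b = jp.BalancedSubsetVotingClassifier(
                n_subsets=4, smote_target=8, random_state=11
            ).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_single_learner_cycle_trains_that_family_only(self, tiny_features):
        X, y = tiny_features
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = jp.BalancedSubsetVotingClassifier(
                n_subsets=1, smote_target=6,
                learner_cycle=("naive-bayes",), random_state=0,
            ).fit(X, y)
        assert [lid for lid, _ in clf.subclassifiers_] == ["naive-bayes"]

    def test_unknown_learner_id_rejected(self):
        with pytest.raises(jp.ValidationError, match="learner"):
            jp.make_learner("decision-stump", seed=0)

    def test_tie_broken_toward_nearest_centroid(self):
        # two tied classes; the sample sits at class "a"'s centroid
        clf = jp.BalancedSubsetVotingClassifier.__new__(
            jp.BalancedSubsetVotingClassifier
        )
        clf.classes_ = np.array(["a", "b", "c"])
        clf.class_centroids_ = np.array(
            [[0.0, 0.0], [10.0, 10.0], [5.0, 5.0]]
        )
        clf.n_features_in_ = 2

        class Stub:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.repeat(self.label, len(X))

        clf.subclassifiers_ = [
            ("stub", Stub("a")), ("stub", Stub("a")),
            ("stub", Stub("b")), ("stub", Stub("b")),
            ("stub", Stub("c")),
        ]
        pred = clf.predict(np.array([[0.5, 0.5], [9.0, 9.0]]))
        assert pred.tolist() == ["a", "b"]
        tallies = clf.vote_tallies(np.array([[0.5, 0.5]]))
        assert tallies.tolist() == [[2, 2, 1]]

    def test_prediction_with_wrong_dimension_rejected(self, fitted):
        clf, X, _ = fitted
        with pytest.raises(ValueError):
            clf.predict(X[:, :10])

    def test_model_roundtrip_through_joblib(self, fitted, tmp_path):
        clf, X, _ = fitted
        jp.save_model(clf, tmp_path / "model.joblib")
        back = jp.load_model(tmp_path / "model.joblib")
        np.testing.assert_array_equal(back.predict(X[:5]), clf.predict(X[:5]))

    def test_sklearn_get_set_params_roundtrip(self):
        clf = jp.BalancedSubsetVotingClassifier(n_subsets=3)
        params = clf.get_params()
        assert params["n_subsets"] == 3
        clf.set_params(smote_target=12)
        assert clf.smote_target == 12
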