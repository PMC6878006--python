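"""Class-weighted SVM: weights, tuning, scoring, degenerate-cluster oracle."""

import numpy as np
import pandas as pd
import pytest

from sfmap import (
    ClassifierSpec,
    MarkerSet,
    compute_class_weights,
    score_all,
    tune_and_train,
)
from sfmap.errors import ConfigurationError
from sfmap.ingest import PROFILE_COLS

from conftest import nearest_centroid_predict


def profile_frame(X, ids):
    return pd.DataFrame(
        np.asarray(X, dtype=float),
        index=pd.Index(ids, name="protein_id"),
        columns=PROFILE_COLS,
    )


def two_point_clusters(n_per=10, jitter=0.0, seed=0):
    """Two classes concentrated at distinct compositional centroids."""
    rng = np.random.default_rng(seed)
    a = np.zeros(20)
    a[0] = a[10] = 1.0
    b = np.zeros(20)
    b[5] = b[15] = 1.0
    X, ids, labels = [], [], {}
    for name, center in (("A", a), ("B", b)):
        for i in range(n_per):
            x = center + jitter * rng.normal(size=20)
            X.append(np.clip(x, 0, None))
            pid = f"{name.lower()}{i}"
            ids.append(pid)
            labels[pid] = name
    return profile_frame(X, ids), labels


class TestComputeClassWeights:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ({"A": 10, "B": 40}, {"A": 1.6, "B": 0.4}),
            ({"A": 5, "B": 5, "C": 5}, {"A": 1.0, "B": 1.0, "C": 1.0}),
            ({"A": 1, "B": 1, "C": 2}, {"A": 1.2, "B": 1.2, "C": 0.6}),
        ],
        ids=["inverse-frequency", "balanced", "hand-normalized"],
    )
    def test_inverse_frequency_mean_one(self, sizes, expected):
        labels = [c for c, n in sizes.items() for _ in range(n)]
        weights = compute_class_weights(labels)
        assert weights == pytest.approx(expected)
        assert np.mean(list(weights.values())) == pytest.approx(1.0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_class_weights([])


class TestTuneAndTrain:
    def test_grid_of_one_pair_is_chosen_without_search(self):
        profiles, labels = two_point_clusters(jitter=0.01)
        markers = MarkerSet(labels, ("A", "B"))
        spec = ClassifierSpec(cost_grid=(2.0,), gamma_grid=(0.5,),
                              cv_outer_rounds=3, cv_inner_folds=2, seed=1)
        trained = tune_and_train(profiles, markers, spec)
        assert (trained.cost, trained.gamma) == (2.0, 0.5)

    def test_separable_degenerate_clusters_reach_perfect_f1(self):
        profiles, labels = two_point_clusters(jitter=0.0)
        markers = MarkerSet(labels, ("A", "B"))
        spec = ClassifierSpec(cost_grid=(0.5, 2.0, 8.0), gamma_grid=(0.5, 2.0),
                              cv_outer_rounds=5, cv_inner_folds=2, seed=1)
        trained = tune_and_train(profiles, markers, spec)
        assert trained.cv_macro_f1 == pytest.approx(1.0)

    def test_single_member_class_rejected(self):
        profiles, labels = two_point_clusters(n_per=3)
        labels["lonely"] = "C"
        profiles.loc["lonely"] = np.eye(20)[7]
        markers = MarkerSet(labels, ("A", "B", "C"))
        spec = ClassifierSpec(cost_grid=(1.0,), gamma_grid=(1.0,),
                              cv_outer_rounds=2, cv_inner_folds=2)
        with pytest.raises(ConfigurationError, match="single member"):
            tune_and_train(profiles, markers, spec)

    def test_fixed_seed_reproducible(self):
        profiles, labels = two_point_clusters(jitter=0.05)
        markers = MarkerSet(labels, ("A", "B"))
        spec = ClassifierSpec(cost_grid=(0.5, 2.0), gamma_grid=(0.5, 2.0),
                              cv_outer_rounds=5, cv_inner_folds=2, seed=9)
        t1 = tune_and_train(profiles, markers, spec)
        t2 = tune_and_train(profiles, markers, spec)
        assert (t1.cost, t1.gamma) == (t2.cost, t2.gamma)
        s1, s2 = score_all(t1, profiles), score_all(t2, profiles)
        pd.testing.assert_frame_equal(s1, s2)


@pytest.fixture(scope="module")
def trained_setup():
    profiles, labels = two_point_clusters(n_per=10, jitter=0.02, seed=3)
    markers = MarkerSet(labels, ("A", "B"))
    spec = ClassifierSpec(cost_grid=(1.0, 4.0), gamma_grid=(1.0,),
                          cv_outer_rounds=5, cv_inner_folds=2, seed=3)
    return profiles, labels, tune_and_train(profiles, markers, spec)


class TestScoreAll:

    def test_scores_are_calibrated_probabilities(self, trained_setup):
        profiles, _, trained = trained_setup
        scores = score_all(trained, profiles)
        per_class = scores[[c for c in scores.columns if c.startswith("score_")]]
        np.testing.assert_allclose(per_class.sum(axis=1), 1.0, atol=1e-9)
        # predicted_class is exactly the argmax; score exactly the max
        for _, row in scores.iterrows():
            assert row["predicted_class"] == max(
                ("A", "B"), key=lambda c: row[f"score_{c}"]
            )
            assert row["score"] == max(row["score_A"], row["score_B"])

    def test_identical_profile_gets_marker_class(self, trained_setup):
        profiles, labels, trained = trained_setup
        query = profiles.loc[["a0"]].rename(index={"a0": "query"})
        assert score_all(trained, query)["predicted_class"].iloc[0] == labels["a0"]

    def test_marker_self_consistency(self, trained_setup):
        profiles, labels, trained = trained_setup
        scores = score_all(trained, profiles)
        correct = np.mean(
            [scores.at[p, "predicted_class"] == c for p, c in labels.items()]
        )
        assert correct >= 0.95

    def test_dimension_mismatch_rejected(self, trained_setup):
        _, _, trained = trained_setup
        bad = pd.DataFrame(np.ones((2, 10)),
                           columns=[f"rep1_ch{i:02d}" for i in range(1, 11)])
        bad.index.name = "protein_id"
        with pytest.raises(Exception):
            score_all(trained, bad)

    def test_zero_noise_svm_equals_nearest_centroid(self):
        """Degenerate clusters: agreement on points from the class templates.

        The equivalence is claimed for profiles generated by the class
        model, not for arbitrary points near the decision midline, where a
        Platt-calibrated boundary may lawfully deviate from the bisector.
        """
        profiles, labels = two_point_clusters(n_per=8, jitter=0.0)
        markers = MarkerSet(labels, ("A", "B"))
        spec = ClassifierSpec(cost_grid=(0.5, 2.0, 8.0), gamma_grid=(0.25, 1.0),
                              cv_outer_rounds=3, cv_inner_folds=2, seed=2)
        trained = tune_and_train(profiles, markers, spec)
        rng = np.random.default_rng(4)
        queries_rows, ids = [], []
        for i in range(30):
            base = profiles.loc["a0"] if i % 2 == 0 else profiles.loc["b0"]
            queries_rows.append(base + 0.01 * rng.normal(size=20))
            ids.append(f"q{i}")
        queries = profile_frame(np.clip(queries_rows, 0, None), ids)
        svm = score_all(trained, queries)["predicted_class"]
        oracle = nearest_centroid_predict(profiles, labels, queries)
        assert (svm == oracle).all()
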