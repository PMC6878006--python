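import numpy as np
import pandas as pd
import pytest

from sfmap import (
    PipelineConfig,
    SimulationConfig,
    default_templates,
    run_pipeline,
    simulate_dataset,
)

#: Reduced hyperparameter grid used for desk-scale end-to-end runs; the
#: full default 9x9 grid is exercised implicitly through unit tests.
REDUCED_CLASSIFIER = {
    "cost_grid": [0.25, 1.0, 4.0, 16.0],
    "gamma_grid": [0.25, 1.0, 4.0],
    "cv_outer_rounds": 100,
    "cv_inner_folds": 5,
}

SMALL_CLASSIFIER = {
    "cost_grid": [1.0, 4.0],
    "gamma_grid": [1.0],
    "cv_outer_rounds": 10,
    "cv_inner_folds": 3,
}


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the reference synthetic experiment (seed 7).

    5 compartment classes, 20 markers + 100 unknowns each, 10 flat-profile
    noise proteins; FDR-mode calibration at the 7.5% target.
    """
    config = PipelineConfig(
        simulation={}, classifier=REDUCED_CLASSIFIER, seed=7
    )
    return run_pipeline(config, write=False)


@pytest.fixture(scope="session")
def zero_noise_run():
    """Pipeline in the zero-noise limit: every profile sits on its template."""
    config = PipelineConfig(
        simulation={
            "template_concentration": 1e7,
            "psm_noise_concentration": 1e7,
            "n_unknowns_per_class": 20,
        },
        classifier=SMALL_CLASSIFIER,
        # fixed published cutoffs: in the degenerate limit all within-class
        # scores coincide up to float noise, so a data-derived threshold
        # would sit exactly on the tie
        calibration={"mode": "fixed"},
        seed=11,
    )
    return run_pipeline(config, write=False)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-degenerate simulated dataset for unit tests."""
    config = SimulationConfig(
        templates=default_templates(),
        n_markers_per_class=5,
        n_unknowns_per_class=10,
        n_noise_proteins=3,
        seed=123,
    )
    return simulate_dataset(config)


def nearest_centroid_predict(
    train_profiles: pd.DataFrame,
    train_labels: dict[str, str],
    query: pd.DataFrame,
) -> pd.Series:
    """Independent oracle: assign each query profile to the closest class centroid."""
    from sfmap import profile_matrix

    labels = pd.Series(train_labels)
    X_train = profile_matrix(train_profiles.loc[labels.index])
    classes = sorted(labels.unique())
    centroids = np.stack(
        [X_train[(labels == c).to_numpy()].mean(axis=0) for c in classes]
    )
    Xq = profile_matrix(query)
    d = ((Xq[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return pd.Series(
        [classes[j] for j in d.argmin(axis=1)], index=query.index
    )


def brute_force_thresholds(
    scores: pd.DataFrame, annotation: dict[str, str], fdr_target: float,
    classes: tuple[str, ...],
) -> dict[str, float]:
    """Exhaustive reference for FDR threshold calibration.

    Enumerates every candidate cutoff (observed scores of annotated
    predictions plus 1.0), computes the empirical FDR of each by direct
    counting, and returns the minimum satisfying cutoff per class.
    """
    from sfmap.calibrate import UNATTAINABLE

    out = {}
    for cls in classes:
        rows = [
            (float(scores.at[p, "score"]), annotation[p] != cls)
            for p in annotation
            if p in scores.index and scores.at[p, "predicted_class"] == cls
        ]
        if not rows:
            out[cls] = UNATTAINABLE
            continue
        candidates = sorted({s for s, _ in rows}) + [1.0]
        satisfying = []
        for t in candidates:
            selected = [wrong for s, wrong in rows if s >= t]
            fdr = (sum(selected) / len(selected)) if selected else 0.0
            if fdr <= fdr_target:
                satisfying.append(t)
        out[cls] = min(satisfying) if satisfying else UNATTAINABLE
    return out


def random_score_instance(rng: np.random.Generator, classes=("A", "B", "C")):
    """A randomized scored-and-annotated instance for calibration tests."""
    n = int(rng.integers(3, 51))
    scores = pd.DataFrame(
        {
            "predicted_class": rng.choice(classes, size=n),
            "score": np.round(rng.uniform(0, 1, size=n), 3),
        },
        index=pd.Index([f"p{i}" for i in range(n)], name="protein_id"),
    )
    annotation = {
        f"p{i}": str(rng.choice(classes))
        for i in range(n)
        if rng.random() < 0.8
    }
    return scores, annotation
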