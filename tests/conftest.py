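"""Shared fixtures: small synthetic cohorts and trained dynamics models.

Heavy fixtures are session-scoped so each model is trained exactly once per
test run.  Problem sizes are kept at desk scale (seconds-long trials, tens
of units) — the generators and estimators are size-agnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gaitsig.cohort import CohortConfig, GroundTruth, generate_cohort
from gaitsig.dynamics import RNNConfig, train_dynamics_model
from gaitsig.pipeline import RunConfig, run_study
from gaitsig.preprocess import GaitEvents, assemble_feature_set


def events_from_truth(truth: GroundTruth) -> GaitEvents:
    """Wrap generator ground truth as a GaitEvents record."""
    return GaitEvents(
        heel_strikes_right=truth.true_heel_strikes_right,
        heel_strikes_left=truth.true_heel_strikes_left,
        toe_offs_right=truth.true_toe_offs_right,
        toe_offs_left=truth.true_toe_offs_left,
    )


def make_cluster_table(
    n_subjects: int,
    trials_per_subject: int,
    dim: int = 20,
    separation: float = 5.0,
    noise: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic signature table: Gaussian cluster per subject."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        center = rng.standard_normal(dim) * separation
        for j in range(trials_per_subject):
            vec = center + rng.standard_normal(dim) * noise
            row = {
                "trial_id": f"S{i:02d}_v{j}",
                "subject_id": f"S{i:02d}",
                "speed": 0.5 + 0.2 * j,
            }
            row.update({f"v{k:04d}": v for k, v in enumerate(vec)})
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 2 speeds, 8 s, single-harmonic noise/jitter-free 3D
    kinematics: smooth deterministic targets for dynamics-model checks."""
    cfg = CohortConfig(
        n_subjects=3, speeds_per_subject=2, speed_min=0.6, speed_max=1.4,
        duration_s=8.0, data_type="kin3d", n_harmonics=1,
        noise_sd=0.0, jitter_sd=0.0, seed=5,
    )
    trials, meta = generate_cohort(cfg)
    feats = [assemble_feature_set(t, "kin3d")[0] for t, _ in trials]
    return cfg, trials, meta, feats


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort):
    _, _, _, feats = tiny_cohort
    rc = RNNConfig(
        hidden_units=32, learning_rate=1e-2, dropout_rate=0.0,
        l2_strength=1e-5, epochs=150, seed=0, early_stopping_patience=150,
    )
    return train_dynamics_model(feats, rc)


@pytest.fixture(scope="session")
def acceptance_config() -> RunConfig:
    """The default identification study: 8 subjects x 6 speeds, 20 s at
    100 Hz, 3D kinematics, 64-unit dynamics model, 20 runs at k in {1, 4}."""
    cohort = CohortConfig(
        n_subjects=8, speeds_per_subject=6, speed_min=0.3, speed_max=2.0,
        duration_s=20.0, fs=100.0, data_type="kin3d", seed=11,
    )
    rnn = RNNConfig(
        hidden_units=64, learning_rate=5e-3, dropout_rate=0.2,
        l2_strength=1e-4, epochs=100, seed=12, early_stopping_patience=30,
    )
    return RunConfig(
        cohort=cohort, rnn=rnn, k_range=(1, 4), n_runs=20,
        required_trials=6, run_bootstrap=False, master_seed=11,
    )


@pytest.fixture(scope="session")
def acceptance_study(acceptance_config):
    import time

    t0 = time.time()
    results = run_study(acceptance_config)
    return results, time.time() - t0
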