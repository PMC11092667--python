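"""End-to-end orchestration: simulate -> preprocess -> train -> signatures ->
discriminate -> map -> speed models -> correlates.

``run_study`` executes the whole chain in memory and returns a results
bundle; ``run_pipeline`` additionally writes every stage output as CSV/JSON
into an output directory together with a manifest (config snapshot, seeds,
library versions, SHA-256 of every artifact).  Re-running with the same
config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gaitsig import __version__
from gaitsig.cohort import (
    CohortConfig,
    GroundTruth,
    TrialTimeSeries,
    generate_cohort,
    write_trial_csv,
)
from gaitsig.correlates import (
    SPATIOTEMPORAL_VARS,
    compute_shifts,
    correlations_to_frame,
    run_correlate_suite,
    spatiotemporal_speed_regressions,
)
from gaitsig.discrimination import (
    filter_complete_subjects,
    speed_generalization_experiment,
)
from gaitsig.dynamics import RNNConfig, extract_latent_states, train_dynamics_model
from gaitsig.gait_map import intra_inter_stats, mds_embed, pairwise_signature_distances
from gaitsig.preprocess import (
    assemble_feature_set,
    compute_spatiotemporal,
    detect_gait_events,
    lowpass_filter,
)
from gaitsig.signatures import (
    build_signatures,
    fit_latent_pca,
    select_n_pcs,
    signatures_to_frame,
    variance_explained_curve,
)
from gaitsig.speed_models import (
    fit_lme_all_coords,
    hierarchical_bootstrap,
    per_subject_linear_fits,
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    The master seed deterministically derives the cohort and model seeds
    (cohort = master, model = master + 1); per-run split seeds inside the
    discrimination experiment are the run numbers.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    rnn: RNNConfig = field(default_factory=RNNConfig)
    n_bins: int = 100
    pca_threshold: float = 0.80
    max_pcs: int | None = None
    k_range: tuple[int, ...] = tuple(range(1, 9))
    n_runs: int = 140
    required_trials: int | None = None  # default: speeds_per_subject
    bootstrap_trial_counts: tuple[int, ...] = (4, 5, 6, 7, 8)
    bootstrap_selections: int = 5
    run_bootstrap: bool = True
    distance_space: str = "mds"  # or "vector"
    lowpass_kinematic_hz: float = 6.0
    lowpass_kinetic_hz: float = 30.0
    master_seed: int = 0

    @classmethod
    def from_master_seed(cls, master_seed: int, **overrides) -> "RunConfig":
        cohort = overrides.pop("cohort", CohortConfig())
        rnn = overrides.pop("rnn", RNNConfig())
        cohort = replace(cohort, seed=master_seed)
        rnn = replace(rnn, seed=master_seed + 1)
        return cls(cohort=cohort, rnn=rnn, master_seed=master_seed, **overrides)


def validate_config(config) -> list[str]:
    """Check every invariant; returns a list of human-readable violations.

    Accepts a ``RunConfig`` or a plain dict of field values (so invalid
    values that dataclass construction would reject can still be reported).
    """
    violations: list[str] = []
    if isinstance(config, dict):
        d = config
        dropout = d.get("dropout_rate")
        if dropout is not None and not 0.0 <= dropout < 1.0:
            violations.append(f"dropout_rate must be in [0, 1), got {dropout}")
        lr = d.get("learning_rate")
        if lr is not None and lr <= 0:
            violations.append(f"learning_rate must be positive, got {lr}")
        smin = d.get("speed_min")
        if smin is not None and smin <= 0:
            violations.append(f"speed_min must be positive, got {smin}")
        k = d.get("k_train")
        tps = d.get("trials_per_subject")
        if k is not None and tps is not None and not 1 <= k <= tps - 1:
            violations.append(
                f"k_train must be in [1, trials_per_subject - 1], got {k} "
                f"with {tps} trials per subject"
            )
        return violations
    if not isinstance(config, RunConfig):
        return [f"unsupported config object {type(config).__name__}"]
    if not 0 < config.pca_threshold <= 1:
        violations.append(
            f"pca_threshold must be in (0, 1], got {config.pca_threshold}"
        )
    if config.n_bins < 2:
        violations.append(f"n_bins must be >= 2, got {config.n_bins}")
    tps = config.cohort.speeds_per_subject
    for k in config.k_range:
        if not 1 <= k <= tps - 1:
            violations.append(
                f"k_train={k} out of range [1, {tps - 1}] for "
                f"{tps} speed trials per subject"
            )
    if config.n_runs < 1:
        violations.append("n_runs must be >= 1")
    if config.distance_space not in ("mds", "vector"):
        violations.append(
            f"distance_space must be 'mds' or 'vector', "
            f"got {config.distance_space!r}"
        )
    for cutoff in (config.lowpass_kinematic_hz, config.lowpass_kinetic_hz):
        if cutoff >= config.cohort.fs / 2:
            violations.append(
                f"low-pass cutoff {cutoff} Hz is not below the Nyquist "
                f"frequency {config.cohort.fs / 2} Hz"
            )
    return violations


def preprocess_trials(
    trials: list[tuple[TrialTimeSeries, GroundTruth]],
    config: RunConfig,
) -> tuple[list[np.ndarray], list, pd.DataFrame]:
    """Filter, event-detect and assemble features for every trial.

    Returns (feature matrices, gait events, per-trial spatiotemporal table).
    """
    feats, events, st_rows = [], [], []
    for trial, truth in trials:
        x, labels = assemble_feature_set(trial, trial.data_type)
        kin_cols = [j for j, lab in enumerate(labels) if "angle" in lab]
        kinetic_cols = [j for j, lab in enumerate(labels) if "angle" not in lab]
        if kin_cols:
            x[:, kin_cols] = lowpass_filter(
                x[:, kin_cols], config.lowpass_kinematic_hz, trial.fs
            )
        if kinetic_cols:
            x[:, kinetic_cols] = lowpass_filter(
                x[:, kinetic_cols], config.lowpass_kinetic_hz, trial.fs
            )
        ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left, trial.fs)
        st = compute_spatiotemporal(trial, ev, step_width=truth.true_step_width)
        row = {"trial_id": trial.trial_id, "subject_id": trial.subject_id,
               "speed": trial.speed}
        row.update(st.as_dict())
        feats.append(x)
        events.append(ev)
        st_rows.append(row)
    return feats, events, pd.DataFrame(st_rows)


@dataclass
class StudyResults:
    """In-memory bundle of every stage output of one pipeline run."""

    config: RunConfig
    metadata: pd.DataFrame
    spatiotemporal: pd.DataFrame
    model: object
    variance_curve: object
    n_pcs: int
    signatures: list
    signature_table: pd.DataFrame
    classification: list
    distances: np.ndarray
    mds_map: object
    distance_stats: object
    subject_fits: list
    lme_fits: list
    bootstrap: object | None
    shifts: list
    correlations: pd.DataFrame
    st_regressions: pd.DataFrame


def run_study(config: RunConfig, verbose: bool = False) -> StudyResults:
    """Execute the full analysis chain in memory."""

    def log(msg: str) -> None:
        if verbose:
            print(f"[gaitsig] {msg}", flush=True)

    t0 = time.time()
    log("simulating cohort")
    trials, meta = generate_cohort(config.cohort)
    log(f"preprocessing {len(trials)} trials")
    feats, events, st_table = preprocess_trials(trials, config)

    log("training dynamics model")
    model = train_dynamics_model(feats, config.rnn)
    log(f"trained for {len(model.history)} epochs, "
        f"final loss {model.history[-1]:.5f}")

    log("extracting latents / fitting PCA")
    latents = [
        extract_latent_states(model, x, trial_id=tid)
        for x, tid in zip(feats, meta["trial_id"])
    ]
    basis = fit_latent_pca(latents, fitted_on=f"{len(latents)} trials")
    curve = variance_explained_curve(model, basis, feats, latents=latents)
    n_pcs = select_n_pcs(curve, config.pca_threshold)
    if config.max_pcs is not None:
        n_pcs = min(n_pcs, config.max_pcs)
    log(f"retained {n_pcs} PCs "
        f"(curve at n_pcs = {curve.values[n_pcs - 1]:.3f})")

    meta2 = meta.assign(data_type=config.cohort.data_type)
    signatures = build_signatures(
        model, basis, feats, events, meta2, n_pcs, n_bins=config.n_bins
    )
    sig_table = signatures_to_frame(signatures)
    sig_table = sig_table.merge(
        meta[["trial_id", "is_ss", "ss_speed", "balance_score"]], on="trial_id"
    )

    log("identification experiment")
    required = config.required_trials or config.cohort.speeds_per_subject
    complete = filter_complete_subjects(sig_table, required_trials=required)
    classification = speed_generalization_experiment(
        complete, k_range=list(config.k_range), n_runs=config.n_runs,
        label=config.cohort.data_type,
    )

    log("gait map")
    vectors = np.stack([s.vector for s in signatures])
    distances = pairwise_signature_distances(vectors)
    mds = mds_embed(
        distances, dim=3, trial_ids=list(meta["trial_id"]),
        speeds=meta["speed"].to_numpy(),
    )
    if config.distance_space == "mds":
        stat_dist = pairwise_signature_distances(mds.coordinates)
    else:
        stat_dist = distances
    dstats = intra_inter_stats(stat_dist, meta["subject_id"].to_numpy())

    log("speed models")
    coords = mds.coordinates
    speeds = meta["speed"].to_numpy(dtype=float)
    subjects = meta["subject_id"].to_numpy()
    subject_fits = per_subject_linear_fits(coords, speeds, subjects)
    lme_fits = fit_lme_all_coords(coords, speeds, subjects)
    bootstrap = None
    if config.run_bootstrap:
        bootstrap = hierarchical_bootstrap(
            coords, speeds, subjects,
            trial_counts=list(config.bootstrap_trial_counts),
            n_selections=config.bootstrap_selections,
            coordinate_index=0,
            master_seed=config.master_seed,
        )

    log("correlates")
    shifts = compute_shifts(coords, meta)
    deltas = _spatiotemporal_deltas(st_table, meta)
    correlations = correlations_to_frame(
        run_correlate_suite(shifts, spatiotemporal_deltas=deltas)
    )
    st_reg = correlations_to_frame(
        spatiotemporal_speed_regressions(st_table)
    )
    log(f"done in {time.time() - t0:.1f} s")
    return StudyResults(
        config=config,
        metadata=meta,
        spatiotemporal=st_table,
        model=model,
        variance_curve=curve,
        n_pcs=n_pcs,
        signatures=signatures,
        signature_table=sig_table,
        classification=classification,
        distances=distances,
        mds_map=mds,
        distance_stats=dstats,
        subject_fits=subject_fits,
        lme_fits=lme_fits,
        bootstrap=bootstrap,
        shifts=shifts,
        correlations=correlations,
        st_regressions=st_reg,
    )


def _spatiotemporal_deltas(st_table: pd.DataFrame,
                           meta: pd.DataFrame) -> pd.DataFrame:
    """Per-subject condition deltas value(extreme) - value(SS)."""
    merged = st_table.merge(meta[["trial_id", "is_ss"]], on="trial_id")
    rows = []
    for subj, grp in merged.groupby("subject_id", sort=True):
        ss = grp[grp["is_ss"]]
        if ss.empty:
            continue
        ss_row = ss.iloc[0]
        slow_row = grp.loc[grp["speed"].idxmin()]
        fast_row = grp.loc[grp["speed"].idxmax()]
        for pair, other in (("ss_to_slow", slow_row), ("ss_to_fast", fast_row)):
            row = {"subject_id": subj, "pair": pair}
            for var in SPATIOTEMPORAL_VARS:
                for side in ("r", "l"):
                    col = f"{var}_{side}"
                    row[col] = float(other[col]) - float(ss_row[col])
            rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def run_pipeline(config: RunConfig, output_dir: str | Path,
                 write_trials: bool = False, verbose: bool = False) -> dict:
    """Run the study and persist every stage output plus a manifest.

    Returns the manifest (also written as ``manifest.json``); every listed
    file carries its SHA-256 so reruns can be checked for byte-identity.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = run_study(config, verbose=verbose)

    files: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = _sha256(path)

    save_df(results.metadata, "cohort_metadata.csv")
    save_df(results.spatiotemporal, "spatiotemporal.csv")
    if write_trials:
        trials, _ = generate_cohort(config.cohort)
        tdir = out / "trials"
        tdir.mkdir(exist_ok=True)
        for trial, _truth in trials:
            name = f"trials/{trial.trial_id}.csv"
            write_trial_csv(trial, out / name)
            files[name] = _sha256(out / name)
    save_df(
        pd.DataFrame(
            {
                "n_pcs": np.arange(1, len(results.variance_curve.values) + 1),
                "cumulative_r2": results.variance_curve.values,
            }
        ),
        "variance_curve.csv",
    )
    save_df(results.signature_table, "signatures.csv")
    acc_rows = [
        {"label": r.label, "k_train": r.k_train, "run": seed, "accuracy": a}
        for r in results.classification
        for seed, a in zip(r.run_seeds, r.accuracies)
    ]
    save_df(pd.DataFrame(acc_rows), "classification.csv")
    mds_df = pd.DataFrame(
        results.mds_map.coordinates, columns=["X", "Y", "Z"]
    )
    mds_df.insert(0, "trial_id", results.mds_map.trial_ids)
    mds_df.insert(1, "subject_id", results.metadata["subject_id"].to_numpy())
    mds_df.insert(2, "speed", results.metadata["speed"].to_numpy())
    save_df(mds_df, "gait_map.csv")
    save_df(
        pd.DataFrame(
            [
                {
                    "subject_id": f.subject_id, "coordinate": f.coordinate,
                    "slope": f.slope, "intercept": f.intercept,
                    "r2": f.r2, "p": f.p,
                }
                for f in results.subject_fits
            ]
        ),
        "subject_linear_fits.csv",
    )
    save_df(
        pd.DataFrame(
            [
                {
                    "coordinate": f.coordinate, "beta0": f.beta0,
                    "beta1": f.beta1,
                    "random_intercept_sd": f.random_intercept_sd,
                    "residual_sd": f.residual_sd, "p_beta1": f.p_beta1,
                    "r2": f.r2, "singular": f.singular,
                }
                for f in results.lme_fits
            ]
        ),
        "lme_fits.csv",
    )
    if results.bootstrap is not None:
        save_df(results.bootstrap.grid, "bootstrap_grid.csv")
    save_df(results.correlations, "correlations.csv")
    save_df(results.st_regressions, "spatiotemporal_regressions.csv")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.master_seed,
        "config": _config_dict(config),
        "n_trials": int(len(results.metadata)),
        "n_pcs_retained": int(results.n_pcs),
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
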