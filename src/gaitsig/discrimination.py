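"""Subject identification across speeds with linear SVMs.

The speed-generalization experiment trains, for each training-set size k, a
multiclass linear SVM on k randomly chosen speed trials per subject and
tests on the remaining trials, repeated over seeded runs (the run number is
the split seed).  Accuracy is pooled over test trials.  Discrete-variable
tables run through the identical protocol as baselines.  Accuracy
distributions are compared with two-sided Mann-Whitney U tests and the
rank-biserial-style effect size r = Z / sqrt(n_a + n_b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class ClassificationResult:
    """Per-k outcome of the identification experiment."""

    label: str  # data type or feature-set name
    k_train: int  # speed trials per subject in training
    run_seeds: list[int]
    accuracies: np.ndarray  # per-run pooled test accuracy, fractions
    confusions: list[np.ndarray] = field(default_factory=list)
    class_labels: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.accuracies, [2.5, 97.5])
        return float(lo), float(hi)


def filter_complete_subjects(
    table: pd.DataFrame, required_trials: int = 9
) -> pd.DataFrame:
    """Retain only subjects with exactly ``required_trials`` trials."""
    counts = table.groupby("subject_id").size()
    keep = counts[counts == required_trials].index
    out = table[table["subject_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"no subject has exactly {required_trials} trials "
            f"(counts: {counts.to_dict()})"
        )
    return out


def split_trials(
    table: pd.DataFrame, k_train: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject uniform split: k_train trials to train, rest to test.

    Returns positional row indices into ``table``; deterministic in seed.
    """
    counts = table.groupby("subject_id").size()
    max_k = int(counts.min()) - 1
    if not 1 <= k_train <= max_k:
        raise ValueError(
            f"k_train must be in [1, {max_k}] "
            f"(trials_per_subject - 1), got {k_train}"
        )
    rng = np.random.default_rng(seed)
    subjects = table["subject_id"].to_numpy()
    pos = np.arange(len(table))
    train_idx, test_idx = [], []
    for s in sorted(np.unique(subjects)):
        rows = pos[subjects == s]
        chosen = rng.choice(len(rows), size=k_train, replace=False)
        mask = np.zeros(len(rows), dtype=bool)
        mask[chosen] = True
        train_idx.extend(rows[mask])
        test_idx.extend(rows[~mask])
    return np.asarray(sorted(train_idx)), np.asarray(sorted(test_idx))


def train_identify_svm(features: np.ndarray, labels: np.ndarray,
                       C: float = 1.0) -> tuple[StandardScaler, SVC]:
    """Linear-kernel one-vs-one SVM on z-scored features.

    The scaler is fit on training data only and must be applied unchanged to
    test features (leakage guard).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 subjects to train a classifier")
    scaler = StandardScaler().fit(features)
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    clf.fit(scaler.transform(features), labels)
    return scaler, clf


def _feature_columns(table: pd.DataFrame) -> list[str]:
    meta = {"trial_id", "subject_id", "speed", "speed_index", "data_type",
            "is_ss", "ss_speed", "balance_score", "body_mass"}
    return [c for c in table.columns if c not in meta]


def _run_once(table: pd.DataFrame, feats: np.ndarray, k_train: int,
              seed: int) -> tuple[float, np.ndarray, list[str]]:
    train_idx, test_idx = split_trials(table, k_train, seed)
    y = table["subject_id"].to_numpy()
    scaler, clf = train_identify_svm(feats[train_idx], y[train_idx])
    pred = clf.predict(scaler.transform(feats[test_idx]))
    truth = y[test_idx]
    classes = sorted(np.unique(y))
    lut = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for a, b in zip(truth, pred):
        confusion[lut[a], lut[b]] += 1
    acc = float(np.mean(pred == truth))
    return acc, confusion, classes


def speed_generalization_experiment(
    table: pd.DataFrame,
    k_range: range | list[int] = range(1, 9),
    n_runs: int = 140,
    label: str = "signatures",
    keep_confusions: bool = False,
) -> list[ClassificationResult]:
    """Progressive-trial identification: for each k, n_runs seeded splits.

    The split seed of run j is the run number j + 1.  Accuracy is pooled
    over all test trials of a run; mean and 2.5/97.5 percentile CI are
    derived from the per-run accuracies.
    """
    feats = table[_feature_columns(table)].to_numpy(dtype=float)
    results = []
    for k in k_range:
        seeds = [run + 1 for run in range(n_runs)]
        accs = np.empty(n_runs)
        confusions = []
        classes: list[str] = []
        for j, seed in enumerate(seeds):
            acc, confusion, classes = _run_once(table, feats, k, seed)
            accs[j] = acc
            if keep_confusions:
                confusions.append(confusion)
        results.append(
            ClassificationResult(
                label=label, k_train=k, run_seeds=seeds, accuracies=accs,
                confusions=confusions, class_labels=classes,
            )
        )
    return results


def baseline_discrete_experiment(
    tables: dict[str, pd.DataFrame],
    k_range: range | list[int] = range(1, 9),
    n_runs: int = 140,
) -> dict[str, list[ClassificationResult]]:
    """Identical protocol applied to discrete-variable feature tables."""
    return {
        name: speed_generalization_experiment(
            tbl, k_range=k_range, n_runs=n_runs, label=name
        )
        for name, tbl in tables.items()
    }


def compare_accuracy_distributions(
    acc_a: np.ndarray, acc_b: np.ndarray
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with effect size r = Z / sqrt(n_a + n_b).

    U is the statistic of the first sample (number of (a, b) pairs with
    a > b, plus half the ties); r is signed by the direction of a vs b, so
    r > 0 means sample a tends larger.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if sigma2 <= 0 else (u - mu) / np.sqrt(sigma2)
    r = z / np.sqrt(n)
    return u, float(res.pvalue), float(r)


def permuted_label_accuracy(
    table: pd.DataFrame, k_train: int, n_runs: int, seed: int = 0
) -> np.ndarray:
    """Chance-level control: accuracies after permuting subject labels.

    Labels are shuffled across trials once per run before the standard
    split/train/test cycle, collapsing the expected accuracy to
    1 / n_subjects.
    """
    rng = np.random.default_rng(seed)
    feats = table[_feature_columns(table)].to_numpy(dtype=float)
    accs = np.empty(n_runs)
    for j in range(n_runs):
        shuffled = table.copy()
        shuffled["subject_id"] = rng.permutation(
            shuffled["subject_id"].to_numpy()
        )
        # keep per-subject trial counts balanced for the split
        acc, _, _ = _run_once(shuffled, feats, k_train, seed=j + 1)
        accs[j] = acc
    return accs
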