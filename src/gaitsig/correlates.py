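"""Correlates of speed-induced signature shifts.

A signature shift is the Euclidean distance between a subject's trials at
two speed conditions (self-selected vs extreme slow, self-selected vs
extreme fast), computed by default in the 3D gait-map coordinates.  Shifts
are related to balance ability, self-selected speed, and per-subject changes
in spatiotemporal variables with Pearson correlations; the ten
spatiotemporal tests per condition pair are Bonferroni-corrected to
alpha = 0.005.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SPATIOTEMPORAL_VARS = (
    "cadence", "stance_duration", "swing_duration", "step_width", "step_length"
)


@dataclass
class ShiftRecord:
    subject_id: str
    condition_pair: str  # "ss_to_slow" or "ss_to_fast"
    shift: float  # Euclidean distance, map units
    ss_speed: float
    balance_score: float


@dataclass
class CorrelationResult:
    pair: str
    r: float
    p: float
    n: int
    alpha: float
    significant: bool


def signature_shift(
    coords: np.ndarray,
    trial_index_a: int,
    trial_index_b: int,
) -> float:
    """Euclidean distance between two trials' coordinates (any dimension)."""
    coords = np.asarray(coords, dtype=float)
    return float(
        np.linalg.norm(coords[trial_index_a] - coords[trial_index_b])
    )


def compute_shifts(
    coords: np.ndarray,
    meta: pd.DataFrame,
) -> list[ShiftRecord]:
    """Per-subject shifts SS->extreme-slow and SS->extreme-fast.

    ``meta`` aligns row-wise with ``coords`` and must carry subject_id,
    speed, is_ss, ss_speed, balance_score.  Extreme slow/fast are the
    subject's minimum/maximum speed trials.  Subjects missing a condition
    trial are skipped with a warning.
    """
    meta = meta.reset_index(drop=True)
    records = []
    for subj, grp in meta.groupby("subject_id", sort=True):
        ss_rows = grp.index[grp["is_ss"]]
        if len(ss_rows) == 0:
            warnings.warn(f"subject {subj} has no SS trial; skipped",
                          stacklevel=2)
            continue
        i_ss = int(ss_rows[0])
        i_slow = int(grp["speed"].idxmin())
        i_fast = int(grp["speed"].idxmax())
        for pair, other in (("ss_to_slow", i_slow), ("ss_to_fast", i_fast)):
            records.append(
                ShiftRecord(
                    subject_id=str(subj),
                    condition_pair=pair,
                    shift=signature_shift(coords, i_ss, other),
                    ss_speed=float(grp["ss_speed"].iloc[0]),
                    balance_score=float(grp["balance_score"].iloc[0]),
                )
            )
    return records


def pearson_correlation(
    x: np.ndarray, y: np.ndarray, pair: str = "", alpha: float = 0.05
) -> CorrelationResult:
    """Pearson r with a two-sided p-value via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        pair=pair, r=float(r), p=float(p), n=len(x), alpha=alpha,
        significant=bool(p < alpha),
    )


def bonferroni_alpha(alpha: float = 0.05, m: int = 10) -> float:
    """Bonferroni-adjusted per-test significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def run_correlate_suite(
    shifts: list[ShiftRecord],
    spatiotemporal_deltas: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """The full correlate battery; every test reported regardless of outcome.

    Balance-block tests at alpha = 0.05: balance vs SS speed, balance vs
    each shift condition, and SS speed vs the SS->slow shift.  When
    spatiotemporal deltas are provided (one row per subject x condition
    pair, columns ``<variable>_<side>``), ten Pearson tests per condition
    pair run at the Bonferroni-corrected alpha = 0.005.
    """
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "pair": s.condition_pair,
                "shift": s.shift,
                "ss_speed": s.ss_speed,
                "balance_score": s.balance_score,
            }
            for s in shifts
        ]
    )
    results = []
    per_subject = df.drop_duplicates("subject_id")
    results.append(
        pearson_correlation(
            per_subject["ss_speed"], per_subject["balance_score"],
            pair="balance~ss_speed", alpha=alpha,
        )
    )
    for cond in ("ss_to_slow", "ss_to_fast"):
        sub = df[df["pair"] == cond]
        results.append(
            pearson_correlation(
                sub["balance_score"], sub["shift"],
                pair=f"balance~shift_{cond}", alpha=alpha,
            )
        )
    slow = df[df["pair"] == "ss_to_slow"]
    results.append(
        pearson_correlation(
            slow["ss_speed"], slow["shift"],
            pair="ss_speed~shift_ss_to_slow", alpha=alpha,
        )
    )

    if spatiotemporal_deltas is not None:
        m = len(SPATIOTEMPORAL_VARS) * 2
        alpha_b = bonferroni_alpha(alpha, m)
        for cond in ("ss_to_slow", "ss_to_fast"):
            sub = df[df["pair"] == cond].set_index("subject_id")
            deltas = spatiotemporal_deltas[
                spatiotemporal_deltas["pair"] == cond
            ].set_index("subject_id")
            common = sub.index.intersection(deltas.index)
            for var in SPATIOTEMPORAL_VARS:
                for side in ("r", "l"):
                    col = f"{var}_{side}"
                    x = sub.loc[common, "shift"].to_numpy(dtype=float)
                    y = deltas.loc[common, col].to_numpy(dtype=float)
                    name = f"shift_{cond}~delta_{col}"
                    if np.std(x) == 0 or np.std(y) == 0:
                        # a constant delta (e.g. step width) carries no signal
                        results.append(
                            CorrelationResult(
                                pair=name, r=0.0, p=1.0, n=len(x),
                                alpha=alpha_b, significant=False,
                            )
                        )
                    else:
                        results.append(
                            pearson_correlation(x, y, pair=name, alpha=alpha_b)
                        )
    return results


def spatiotemporal_speed_regressions(
    records: pd.DataFrame,
    alpha: float = 0.05,
    m: int = 10,
) -> list[CorrelationResult]:
    """Per-variable linear fits against speed (Bonferroni alpha default 0.005).

    ``records`` holds one row per trial with a ``speed`` column and bilateral
    spatiotemporal columns ``<variable>_<side>``.
    """
    alpha_b = bonferroni_alpha(alpha, m)
    results = []
    speeds = records["speed"].to_numpy(dtype=float)
    for var in SPATIOTEMPORAL_VARS:
        for side in ("r", "l"):
            col = f"{var}_{side}"
            y = records[col].to_numpy(dtype=float)
            if np.std(y) == 0:
                results.append(
                    CorrelationResult(
                        pair=f"{col}~speed", r=0.0, p=1.0,
                        n=len(y), alpha=alpha_b, significant=False,
                    )
                )
                continue
            results.append(
                pearson_correlation(speeds, y, pair=f"{col}~speed",
                                    alpha=alpha_b)
            )
    return results


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": c.pair, "r": c.r, "p": c.p, "n": c.n,
                "alpha": c.alpha, "significant": c.significant,
            }
            for c in results
        ]
    )
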