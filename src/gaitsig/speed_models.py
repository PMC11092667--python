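"""Speed models for gait-map coordinates.

Per-subject ordinary least squares quantifies how each MDS coordinate moves
with belt speed within an individual.  Cohort-level structure is modelled
with a linear mixed-effects model per coordinate::

    coord ~ beta0 + beta1 * speed + (1 | subject) + eps

fit by maximum likelihood (statsmodels MixedLM).  A hierarchical bootstrap
(leave-one-subject-out x trials-per-subject x random trial selections)
probes the sensitivity of the fixed effects, and residual diagnostics check
normality and homoscedasticity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

COORD_NAMES = ("X", "Y", "Z")


@dataclass
class SubjectLinearFit:
    subject_id: str
    coordinate: str
    slope: float  # map-units per m/s
    intercept: float
    r2: float
    p: float


@dataclass
class LMEFit:
    coordinate: str
    beta0: float  # fixed intercept, map-units
    beta1: float  # fixed speed slope, map-units per m/s
    random_intercept_sd: float
    residual_sd: float
    p_beta1: float
    r2: float  # squared corr(fitted incl. random effects, observed)
    converged: bool = True
    singular: bool = False
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class BootstrapSummary:
    """Mean +/- SD of the LME fixed effects over the bootstrap grid."""

    coordinate: str
    grid: pd.DataFrame  # one row per (left-out subject, k, selection)
    beta0_mean: float
    beta0_sd: float
    beta1_mean: float
    beta1_sd: float
    random_sd_range: tuple[float, float]


def per_subject_linear_fits(
    coords: np.ndarray,
    speeds: np.ndarray,
    subject_ids: np.ndarray,
) -> list[SubjectLinearFit]:
    """OLS of each coordinate on speed, separately per subject."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] != len(speeds):
        coords = coords.T
    speeds = np.asarray(speeds, dtype=float)
    subject_ids = np.asarray(subject_ids)
    fits = []
    for subj in sorted(np.unique(subject_ids)):
        mask = subject_ids == subj
        if mask.sum() < 3:
            warnings.warn(
                f"subject {subj} has fewer than 3 trials; skipped",
                stacklevel=2,
            )
            continue
        for k in range(coords.shape[1]):
            y = coords[mask, k]
            if np.std(y) == 0:
                slope, intercept, r2, p = 0.0, float(y[0]), 0.0, 1.0
            else:
                res = stats.linregress(speeds[mask], y)
                slope, intercept = float(res.slope), float(res.intercept)
                r2, p = float(res.rvalue**2), float(res.pvalue)
            fits.append(
                SubjectLinearFit(
                    subject_id=str(subj),
                    coordinate=COORD_NAMES[k] if k < 3 else f"C{k}",
                    slope=slope,
                    intercept=intercept,
                    r2=r2,
                    p=p,
                )
            )
    return fits


def fit_lme(
    coord: np.ndarray,
    speeds: np.ndarray,
    subject_ids: np.ndarray,
    coordinate: str = "X",
) -> LMEFit:
    """Random-intercept LME of one coordinate on speed, ML estimation.

    A singular fit (random-intercept variance collapsing to zero) is
    reported via the ``singular`` flag, not hidden.
    """
    y = np.asarray(coord, dtype=float)
    s = np.asarray(speeds, dtype=float)
    groups = np.asarray(subject_ids)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or np.all(counts < 2):
        raise ValueError("need >= 2 subjects with >= 2 trials for an LME")
    exog = sm.add_constant(s)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, exog, groups=groups)
            res = model.fit(reml=False, method="lbfgs")
        beta0, beta1 = float(res.fe_params[0]), float(res.fe_params[1])
        re_var = float(np.asarray(res.cov_re)[0, 0])
        resid_sd = float(np.sqrt(res.scale))
        singular = re_var < 1e-10
        if singular:
            offsets = np.zeros(len(y))
        else:
            re = res.random_effects
            offsets = np.array([float(re[g].iloc[0]) for g in groups])
        fitted = exog @ res.fe_params + offsets
        residuals = y - fitted
        p_beta1 = float(res.pvalues[1])
        converged = bool(res.converged)
    except (np.linalg.LinAlgError, ValueError):
        # random-intercept variance at the boundary can make the ML Hessian
        # singular; the model then degenerates to pooled OLS with zero
        # random-effect variance, which is reported as a singular fit
        ols = sm.OLS(y, exog).fit()
        beta0, beta1 = float(ols.params[0]), float(ols.params[1])
        re_var = 0.0
        fitted = np.asarray(ols.fittedvalues)
        residuals = y - fitted
        resid_sd = float(np.sqrt(np.mean(residuals**2)))
        singular = True
        p_beta1 = float(ols.pvalues[1])
        converged = True
    if np.std(fitted) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2 = 0.0
    return LMEFit(
        coordinate=coordinate,
        beta0=beta0,
        beta1=beta1,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=resid_sd,
        p_beta1=p_beta1,
        r2=r2,
        converged=converged,
        singular=singular,
        fitted=fitted,
        residuals=residuals,
    )


def fit_lme_all_coords(
    coords: np.ndarray, speeds: np.ndarray, subject_ids: np.ndarray
) -> list[LMEFit]:
    coords = np.asarray(coords, dtype=float)
    return [
        fit_lme(coords[:, k], speeds, subject_ids, coordinate=COORD_NAMES[k])
        for k in range(coords.shape[1])
    ]


def hierarchical_bootstrap(
    coords: np.ndarray,
    speeds: np.ndarray,
    subject_ids: np.ndarray,
    trial_counts: range | list[int] = range(4, 9),
    n_selections: int = 5,
    coordinate_index: int = 0,
    master_seed: int = 0,
) -> BootstrapSummary:
    """Leave-one-subject-out LME bootstrap over trial-count subsets.

    For each left-out subject, each trial count k, and each seeded random
    selection of k trials per remaining subject, the LME is refit.  The grid
    has n_subjects x len(trial_counts) x n_selections cells per coordinate.
    Selection seeds derive from (master_seed, subject index, k, replicate).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] != len(speeds):
        coords = coords.T
    y_all = coords[:, coordinate_index]
    speeds = np.asarray(speeds, dtype=float)
    subject_ids = np.asarray(subject_ids)
    subjects = sorted(np.unique(subject_ids))
    rows = []
    for si, left_out in enumerate(subjects):
        keep = subject_ids != left_out
        for k in trial_counts:
            for rep in range(n_selections):
                rng = np.random.default_rng([master_seed, si, k, rep])
                sel = np.zeros(len(subject_ids), dtype=bool)
                for subj in subjects:
                    if subj == left_out:
                        continue
                    rows_s = np.nonzero(subject_ids == subj)[0]
                    take = rng.choice(rows_s, size=min(k, len(rows_s)),
                                      replace=False)
                    sel[take] = True
                fit = fit_lme(
                    y_all[sel & keep], speeds[sel & keep],
                    subject_ids[sel & keep],
                    coordinate=COORD_NAMES[coordinate_index],
                )
                rows.append(
                    {
                        "left_out": str(left_out),
                        "k": int(k),
                        "replicate": rep,
                        "beta0": fit.beta0,
                        "beta1": fit.beta1,
                        "random_sd": fit.random_intercept_sd,
                        "residual_sd": fit.residual_sd,
                    }
                )
    grid = pd.DataFrame(rows)
    return BootstrapSummary(
        coordinate=COORD_NAMES[coordinate_index],
        grid=grid,
        beta0_mean=float(grid["beta0"].mean()),
        beta0_sd=float(grid["beta0"].std(ddof=1)),
        beta1_mean=float(grid["beta1"].mean()),
        beta1_sd=float(grid["beta1"].std(ddof=1)),
        random_sd_range=(
            float(grid["random_sd"].min()), float(grid["random_sd"].max())
        ),
    )


def residual_diagnostics(fit: LMEFit) -> dict[str, float]:
    """Normality (Shapiro-Wilk) and homoscedasticity checks of LME residuals.

    Homoscedasticity is summarized as the Pearson correlation of the
    absolute residuals with the fitted values (0 under constant variance).
    """
    resid, fitted = fit.residuals, fit.fitted
    if resid.size == 0:
        raise ValueError("fit carries no residuals")
    sh_stat, sh_p = stats.shapiro(resid)
    if np.std(np.abs(resid)) > 0 and np.std(fitted) > 0:
        het_r, het_p = stats.pearsonr(np.abs(resid), fitted)
    else:
        het_r, het_p = 0.0, 1.0
    return {
        "residual_mean": float(np.mean(resid)),
        "shapiro_stat": float(sh_stat),
        "shapiro_p": float(sh_p),
        "heteroscedasticity_r": float(het_r),
        "heteroscedasticity_p": float(het_p),
    }
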