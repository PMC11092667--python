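"""Gait maps: low-dimensional embeddings of signature distances.

All trials' signature vectors are compared by Euclidean distance and
embedded into 3D with classical (Torgerson) multidimensional scaling, giving
a single deterministic gait map.  Intra- vs inter-individual distance
structure is quantified with pooled z-scores and a Mann-Whitney U test; by
default the distance statistics are computed on the 3D map coordinates, with
a switch to use the full signature vectors instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform


@dataclass
class MDSMap:
    """3D embedding of all trials' signatures."""

    trial_ids: list[str]
    coordinates: np.ndarray  # (N, dim)
    eigenvalues: np.ndarray
    stress: float  # Kruskal stress-1 of the embedded vs input distances
    distance_correlation: float  # Pearson r(input distances, embedded)
    method: str = "classical"


@dataclass
class DistanceStats:
    """Intra/inter-individual distance samples and their pooled z-scores."""

    intra: np.ndarray
    inter: np.ndarray
    intra_z: np.ndarray
    inter_z: np.ndarray
    prop_intra_above_2: float  # proportion of intra z-scores > +2
    prop_intra_below_2: float
    prop_inter_above_2: float
    prop_inter_below_2: float
    mwu_statistic: float
    mwu_p: float


def pairwise_signature_distances(vectors: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between signature vectors."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2D (N, D) array")
    return squareform(pdist(X, metric="euclidean"))


def mds_embed(
    distances: np.ndarray,
    dim: int = 3,
    trial_ids: list[str] | None = None,
    speeds: np.ndarray | None = None,
) -> MDSMap:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers the squared distances, takes the top eigenvectors scaled
    by the square root of their eigenvalues.  Deterministic up to axis sign;
    signs are canonicalized so that axis 1 correlates non-negatively with
    speed (when speeds are given) and every axis has its largest-magnitude
    coordinate positive otherwise.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval[:dim] > max(eigval[0], 0.0) * 1e-12
    if positive.sum() < dim:
        warnings.warn(
            f"only {int(positive.sum())} of {dim} requested axes carry "
            "positive eigenvalues; remaining axes are zero", stacklevel=2,
        )
    coords = np.zeros((n, dim))
    for k in range(dim):
        if positive[k]:
            coords[:, k] = eigvec[:, k] * np.sqrt(eigval[k])
    # axis sign canonicalization
    for k in range(dim):
        col = coords[:, k]
        if speeds is not None and k == 0:
            c = np.corrcoef(col, np.asarray(speeds, dtype=float))[0, 1]
            sign = -1.0 if np.isfinite(c) and c < 0 else 1.0
        else:
            j = int(np.argmax(np.abs(col))) if np.any(col) else 0
            sign = -1.0 if col[j] < 0 else 1.0
        coords[:, k] = col * sign

    emb = squareform(pdist(coords))
    iu = np.triu_indices(n, k=1)
    d_in, d_emb = D[iu], emb[iu]
    denom = float(np.sum(d_in**2))
    stress = float(np.sqrt(np.sum((d_in - d_emb) ** 2) / denom)) if denom > 0 else 0.0
    if np.std(d_in) > 0 and np.std(d_emb) > 0:
        corr = float(np.corrcoef(d_in, d_emb)[0, 1])
    else:
        corr = 1.0
    return MDSMap(
        trial_ids=list(trial_ids) if trial_ids is not None else
        [str(i) for i in range(n)],
        coordinates=coords,
        eigenvalues=eigval[:dim],
        stress=stress,
        distance_correlation=corr,
    )


def intra_inter_stats(distances: np.ndarray,
                      subject_ids: np.ndarray) -> DistanceStats:
    """Split upper-triangle distances into intra/inter-individual groups.

    Z-scores use the pooled mean/SD of all pairwise distances; proportions
    with z > +2 and z < -2 are reported per group together with a two-sided
    Mann-Whitney U test between the groups.
    """
    D = np.asarray(distances, dtype=float)
    labels = np.asarray(subject_ids)
    n = D.shape[0]
    if len(labels) != n:
        raise ValueError("subject_ids must match the distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(counts < 2):
        warnings.warn(
            "subjects with a single trial contribute no intra-individual "
            "distances", stacklevel=2,
        )
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = D[iu]
    intra, inter = vals[same], vals[~same]
    pooled_mean = float(vals.mean())
    pooled_sd = float(vals.std())
    if pooled_sd < 1e-15:
        warnings.warn("all pairwise distances identical; z-scores set to 0",
                      stacklevel=2)
        intra_z = np.zeros_like(intra)
        inter_z = np.zeros_like(inter)
    else:
        intra_z = (intra - pooled_mean) / pooled_sd
        inter_z = (inter - pooled_mean) / pooled_sd
    if len(intra) and len(inter) and (np.std(vals) > 0):
        mwu = stats.mannwhitneyu(intra, inter, alternative="two-sided")
        u, p = float(mwu.statistic), float(mwu.pvalue)
    else:
        u, p = np.nan, 1.0
    return DistanceStats(
        intra=intra,
        inter=inter,
        intra_z=intra_z,
        inter_z=inter_z,
        prop_intra_above_2=float(np.mean(intra_z > 2)) if len(intra) else np.nan,
        prop_intra_below_2=float(np.mean(intra_z < -2)) if len(intra) else np.nan,
        prop_inter_above_2=float(np.mean(inter_z > 2)),
        prop_inter_below_2=float(np.mean(inter_z < -2)),
        mwu_statistic=u,
        mwu_p=p,
    )
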