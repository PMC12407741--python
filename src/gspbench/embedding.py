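"""Two-dimensional spectral embedding of parameter-combination similarity.

For one feature type, the pairwise similarity between the feature vectors of
all parameter combinations is summarized with an adaptive Gaussian kernel on
cosine distances, ``S(i,j) = exp(-d_ij^2 / sigma_i^2)`` with ``sigma_i`` the
mean distance from vector i to all others (row-adaptive, hence generally
asymmetric) and a zero diagonal.  Per-scan affinities are averaged first
across scans, then across subjects.  Spectral clustering-style
eigendecomposition of the (symmetrized) affinity yields the second and third
eigenvectors (u2, u3) as the two summary coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .features import FeatureTable, ParameterCombination
from .operators import _fix_signs

__all__ = ["AffinityMatrix", "Embedding2D", "build_affinity",
           "spectral_embed", "embedding_frame"]


@dataclass
class AffinityMatrix:
    S_mat: np.ndarray
    combo_index: list[ParameterCombination]


@dataclass
class Embedding2D:
    coords: np.ndarray          # np x 2: (u2, u3)
    eigenvalues: np.ndarray     # the eigenvalues of the used eigenvectors
    combo_index: list[ParameterCombination]


def adaptive_kernel(D: np.ndarray) -> np.ndarray:
    """Row-adaptive Gaussian kernel on a distance matrix, zero diagonal.

    NaN distances (undefined pairs) yield affinity 0 and are excluded from
    the sigma estimate.  A row of all-zero distances (identical vectors)
    gets affinity 1 to every twin.
    """
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sigma = np.array([np.nanmean(D[i, off[i]]) for i in range(n)])
    degenerate = ~(sigma > 0)  # all-zero or all-NaN row
    sigma[degenerate] = 1.0
    with np.errstate(invalid="ignore"):
        S = np.exp(-(D**2) / sigma[:, None] ** 2)
    S[np.isnan(D)] = 0.0
    np.fill_diagonal(S, 0.0)
    return S


def build_affinity(table: FeatureTable, feature_type: str) -> AffinityMatrix:
    """Average adaptive-kernel affinity over scans, then over subjects.

    Zero-norm feature vectors (undefined cosine distance) are dropped from
    the sigma estimate and their affinity row/column set to 0, with a
    warning.
    """
    combos = table.combos(feature_type)
    n = len(combos)
    stack = np.stack([table.get(feature_type, c) for c in combos], axis=1)
    # stack: n_scans x n_combos x R
    subjects = sorted(table.scans["subject"].unique())
    per_subject = []
    warned = False
    for subj in subjects:
        idx = table.scans.index[table.scans["subject"] == subj]
        per_scan = []
        for i in idx:
            F = stack[i]
            norms = np.linalg.norm(F, axis=1)
            dead = norms == 0
            if np.any(dead) and not warned:
                warnings.warn("zero-norm feature vector(s): affinity "
                              "row/column set to 0", UserWarning)
                warned = True
            D = np.full((n, n), np.nan)
            ok = ~dead
            if ok.sum() >= 2:
                D_ok = squareform(pdist(F[ok], metric="cosine"))
                D[np.ix_(ok, ok)] = D_ok
            S = adaptive_kernel(D)
            S[dead, :] = 0.0
            S[:, dead] = 0.0
            per_scan.append(S)
        per_subject.append(np.mean(per_scan, axis=0))
    S_mat = np.mean(per_subject, axis=0)
    return AffinityMatrix(S_mat=S_mat, combo_index=combos)


def spectral_embed(affinity: AffinityMatrix,
                   symmetrize: bool = True) -> Embedding2D:
    """Eigendecompose the affinity and return (u2, u3) coordinates.

    The row-adaptive kernel is asymmetric; by default it is symmetrized as
    ``(S + S.T) / 2`` so the spectrum is real.  ``symmetrize=False``
    eigendecomposes the raw matrix and takes real parts.  Eigenvectors are
    ordered by descending eigenvalue with the deterministic sign convention
    of the operator module.
    """
    S = affinity.S_mat
    if not np.all(np.isfinite(S)):
        raise ValueError("affinity has non-finite entries")
    if symmetrize:
        W = (S + S.T) / 2.0
        lam, U = np.linalg.eigh(W)
        order = np.argsort(-lam, kind="stable")
    else:
        lam, U = np.linalg.eig(S)
        order = np.argsort(-lam.real, kind="stable")
        lam, U = lam.real, U.real
    lam = lam[order]
    U = _fix_signs(U[:, order])
    return Embedding2D(coords=U[:, 1:3], eigenvalues=lam[1:3],
                       combo_index=affinity.combo_index)


def embedding_frame(emb: Embedding2D) -> pd.DataFrame:
    """One row per combination: all factor levels plus (u2, u3)."""
    rows = []
    for c, (u2, u3) in zip(emb.combo_index, emb.coords):
        rows.append({"property": c.property, "individuality": c.individuality,
                     "operator": c.operator, "zscore": c.zscore,
                     "normalize": c.normalize, "extra": c.extra,
                     "u2": u2, "u3": u3})
    return pd.DataFrame(rows)
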