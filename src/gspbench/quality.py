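"""Quality criteria and consensus ranking for the pipeline comparison.

Six criteria are computed per feature type x parameter combination:

1. ``pct_incongruent`` — percentage of subjects whose feature vectors are
   more similar across days than within a day (robustness to acquisition
   settings; lower is better).  The companion penalty
   ``Omega = sum_s max(0, -dR(s))`` with ``dR = Rbar_same - Rbar_diff``
   quantifies how strongly incongruent subjects are.
2. ``pfd_selected`` — mean percentage of feature-coefficient variance
   explained by per-scan mean framewise displacement, within the selected
   coefficient subset (head-motion sensitivity; lower is better).
3. ``icc_selected`` — mean ICC(A,1) (two-way random effects, absolute
   agreement, single measurement) over the selected coefficients (higher is
   better).
4. ``accuracy_max`` — maximal Hungarian fingerprinting accuracy over an
   ICC-ranked feature-subset sweep, selected on SES1 (LR) scans and
   evaluated on the held-out SES2 (RL) day pair (higher is better).
5. ``pct_coeffs_used`` — smallest percentage of coefficients attaining that
   maximum (parsimony; lower is better).
6. ``generalization_change`` — mean absolute change in full-set accuracy
   when switching parcellation variants (lower is better).

The consensus ranking min-max-normalizes each criterion to [0, 100] over
all compared cases (orientation flipped where lower is better) and averages
the six normalized columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cohort import DAYS, PHASES
from .features import FeatureTable, ParameterCombination

__all__ = [
    "SessionSimilarity",
    "session_similarity_stats",
    "movement_variance",
    "icc_a1",
    "icc_a1_batch",
    "fingerprint_accuracy",
    "fingerprint_accuracy_pairs",
    "select_features_by_icc",
    "generalization_delta",
    "CRITERIA",
    "CRITERIA_HIGHER_BETTER",
    "rank_pipelines",
]

SAME_DAY_PAIRS = [((1, "LR"), (1, "RL")), ((2, "LR"), (2, "RL"))]
DIFF_DAY_PAIRS = [((1, "LR"), (2, "LR")), ((1, "RL"), (2, "RL"))]
SES1_SCANS = [(1, "LR"), (2, "LR")]  # LR = first scan of each day
SES2_PAIR = ((1, "RL"), (2, "RL"))

# criterion name -> True if larger values are better
CRITERIA_HIGHER_BETTER = {
    "pct_incongruent": False,
    "pfd_selected": False,
    "icc_selected": True,
    "accuracy_max": True,
    "pct_coeffs_used": False,
    "generalization_change": False,
}
CRITERIA = tuple(CRITERIA_HIGHER_BETTER)


def _pearson_rows(A: np.ndarray, B: np.ndarray,
                  warn_constant: bool = True) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B.

    Constant rows get correlation 0 (with a warning): they carry no pattern
    to correlate.
    """
    def standardize(M):
        Z = M - M.mean(axis=1, keepdims=True)
        n = np.linalg.norm(Z, axis=1, keepdims=True)
        const = n[:, 0] == 0
        n[const] = 1.0
        return Z / n, const

    Az, ca = standardize(np.asarray(A, dtype=float))
    Bz, cb = standardize(np.asarray(B, dtype=float))
    if warn_constant and (np.any(ca) or np.any(cb)):
        warnings.warn("constant feature vector(s): correlation set to 0",
                      UserWarning)
    C = Az @ Bz.T
    C[ca, :] = 0.0
    C[:, cb] = 0.0
    return np.clip(C, -1.0, 1.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(_pearson_rows(x[None, :], y[None, :], warn_constant=False)[0, 0])


@dataclass
class SessionSimilarity:
    """Same-day vs different-day cross-scan similarity per subject."""

    subjects: list[str]
    R_same: np.ndarray      # S x 2 (one column per same-day pair)
    R_diff: np.ndarray      # S x 2 (one column per different-day pair)
    valid: np.ndarray       # S bool, False where a correlation was undefined

    @property
    def Rbar_same(self) -> np.ndarray:
        return self.R_same.mean(axis=1)

    @property
    def Rbar_diff(self) -> np.ndarray:
        return self.R_diff.mean(axis=1)

    @property
    def deltaR(self) -> np.ndarray:
        """Rbar_same - Rbar_diff over subjects with all pairs defined."""
        return (self.Rbar_same - self.Rbar_diff)[self.valid]


def omega_penalty(deltaR: np.ndarray, variant: str = "magnitude") -> float:
    """Acquisition-settings penalty over the per-subject similarity gaps.

    ``magnitude`` (default) sums ``max(0, -dR)``, so the penalty grows both
    with the number of incongruent subjects and with how strongly negative
    their gaps are; ``count`` is the plain Heaviside count.
    """
    d = np.asarray(deltaR, dtype=float)
    if variant == "magnitude":
        return float(np.maximum(0.0, -d).sum())
    if variant == "count":
        return float((d < 0).sum())
    raise ValueError(f"unknown omega variant {variant!r}")


def session_similarity_stats(table: FeatureTable, feature_type: str,
                             combo: ParameterCombination,
                             omega_variant: str = "magnitude"):
    """Per-subject same-/different-day similarity, penalty and incongruency.

    Same-day pairs are (day LR, day RL) for each day; different-day pairs
    are the same-phase scans across days.  Returns
    ``(SessionSimilarity, omega, pct_incongruent)``.
    """
    mats = {dp: table.scan_matrix(feature_type, combo, *dp)
            for dp in [(d, p) for d in DAYS for p in PHASES]}
    subjects = mats[(1, "LR")][0]
    S = len(subjects)

    def pair_corrs(pairs):
        out = np.empty((S, len(pairs)))
        for j, (a, b) in enumerate(pairs):
            A, B = mats[a][1], mats[b][1]
            for s in range(S):
                out[s, j] = _pearson(A[s], B[s])
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        R_same = pair_corrs(SAME_DAY_PAIRS)
        R_diff = pair_corrs(DIFF_DAY_PAIRS)
    const = np.zeros(S, dtype=bool)
    for a in mats:
        M = mats[a][1]
        const |= M.std(axis=1) == 0
    if np.any(const):
        warnings.warn(f"{const.sum()} subject(s) with constant feature "
                      "vectors excluded from deltaR", UserWarning)
    sim = SessionSimilarity(subjects, R_same, R_diff, valid=~const)
    d = sim.deltaR
    omega = omega_penalty(d, omega_variant)
    pct = 100.0 * float((d < 0).sum()) / len(d) if len(d) else float("nan")
    return sim, omega, pct


def movement_variance(table: FeatureTable, feature_type: str,
                      combo: ParameterCombination,
                      coefficient_subset: np.ndarray | None = None) -> float:
    """Mean percentage of coefficient variance explained by mean FD.

    For each of the four scan conditions, each coefficient is correlated
    with per-scan mean FD across subjects; ``100 * r^2`` is averaged over
    the (optionally restricted) coefficients, then over the four scans.
    Coefficients with zero variance across subjects are excluded.
    """
    if coefficient_subset is not None and len(coefficient_subset) == 0:
        raise ValueError("coefficient subset must be nonempty")
    scan_means = []
    for day in DAYS:
        for phase in PHASES:
            subjects, F = table.scan_matrix(feature_type, combo, day, phase)
            mask = (table.scans["day"] == day) & (table.scans["phase"] == phase)
            sub = table.scans.loc[mask].sort_values("subject")
            fd = sub["mean_fd"].to_numpy()
            if coefficient_subset is not None:
                F = F[:, coefficient_subset]
            var_ok = F.std(axis=0) > 0
            if not np.all(var_ok):
                warnings.warn(f"{(~var_ok).sum()} zero-variance coefficient(s)"
                              " excluded from FD variance", UserWarning)
            if not np.any(var_ok):
                continue
            r = _pearson_rows(F[:, var_ok].T, fd[None, :],
                              warn_constant=False)[:, 0]
            scan_means.append(float(np.mean(100.0 * r**2)))
    return float(np.mean(scan_means)) if scan_means else float("nan")


def icc_a1(values: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``values`` is an ``n x k`` table (rows = subjects, columns = repeated
    measurements).  From the two-way ANOVA mean squares,

        ICC(A,1) = (MS_R - MS_E) /
                   (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)).

    Returns NaN (with a warning) when the total variance is zero.
    """
    return float(icc_a1_batch(np.asarray(values, dtype=float)[:, :, None])[0])


def icc_a1_batch(values: np.ndarray) -> np.ndarray:
    """Vectorized ICC(A,1) over an ``n x k x p`` stack of tables."""
    V = np.asarray(values, dtype=float)
    if V.ndim != 3:
        raise ValueError("expected an n x k x p array")
    n, k, p = V.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 measurements")
    gm = V.mean(axis=(0, 1))
    row_means = V.mean(axis=1)
    col_means = V.mean(axis=0)
    ss_total = ((V - gm) ** 2).sum(axis=(0, 1))
    ss_rows = k * ((row_means - gm) ** 2).sum(axis=0)
    ss_cols = n * ((col_means - gm) ** 2).sum(axis=0)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    zero = ss_total == 0
    if np.any(zero):
        warnings.warn(f"{zero.sum()} ICC table(s) with zero total variance",
                      UserWarning)
    out = np.full(p, np.nan)
    ok = ~zero & (denom != 0)
    out[ok] = (msr[ok] - mse[ok]) / denom[ok]
    return out


def fingerprint_accuracy(features_A: np.ndarray,
                         features_B: np.ndarray) -> float:
    """Hungarian one-to-one identification accuracy between two sessions.

    Rows of both matrices are subjects in the same order.  The S x S Pearson
    similarity matrix is matched with the Hungarian algorithm (maximizing
    total similarity); accuracy is the percentage of subjects assigned to
    themselves.  Pearson is undefined for single-coefficient vectors, so for
    p = 1 the similarity is the negative absolute coefficient difference
    (nearest-value matching).
    """
    A = np.asarray(features_A, dtype=float)
    B = np.asarray(features_B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("feature matrices must share shape")
    if A.shape[1] == 1:
        sim = -np.abs(A - B.T)
    else:
        sim = _pearson_rows(A, B)
    row, col = linear_sum_assignment(-sim)
    return 100.0 * float(np.mean(col[np.argsort(row)] == np.arange(A.shape[0])))


def fingerprint_accuracy_pairs(table: FeatureTable, feature_type: str,
                               combo: ParameterCombination) -> float:
    """Full-feature accuracy averaged over both same-phase day pairs."""
    accs = []
    for (a, b) in DIFF_DAY_PAIRS:
        _, A = table.scan_matrix(feature_type, combo, *a)
        _, B = table.scan_matrix(feature_type, combo, *b)
        accs.append(fingerprint_accuracy(A, B))
    return float(np.mean(accs))


def select_features_by_icc(table: FeatureTable, feature_type: str,
                           combo: ParameterCombination, stride: int = 1):
    """ICC-ranked feature-subset sweep with a held-out session pair.

    Per-coefficient ICC(A,1) (k=2) is computed on the two SES1 (LR) scans
    only; coefficients are ranked by descending ICC (undefined ICC last,
    ties by index) and the top-m sets for m = 1..R (by ``stride``, with R
    always included) are evaluated by Hungarian accuracy on the SES2 (RL)
    day pair, avoiding double dipping.  Returns ``(accuracy_max,
    pct_coeffs_used, selected_set, sweep)`` where ``sweep`` is the
    (m, accuracy) curve and ``pct_coeffs_used`` corresponds to the smallest
    m attaining the maximum.
    """
    R = table.n_regions
    ses1 = [table.scan_matrix(feature_type, combo, *dp)[1] for dp in SES1_SCANS]
    stack = np.stack(ses1, axis=1)  # S x 2 x R
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        icc = icc_a1_batch(stack)
    rank_key = np.where(np.isnan(icc), -np.inf, icc)
    order = np.argsort(-rank_key, kind="stable")
    _, A_full = table.scan_matrix(feature_type, combo, *SES2_PAIR[0])
    _, B_full = table.scan_matrix(feature_type, combo, *SES2_PAIR[1])
    ms = sorted(set(range(1, R + 1, stride)) | {R})
    sweep = []
    for m in ms:
        sel = order[:m]
        sweep.append((m, fingerprint_accuracy(A_full[:, sel], B_full[:, sel])))
    accs = np.array([a for _, a in sweep])
    best = float(accs.max())
    m_best = sweep[int(np.argmax(accs))][0]  # argmax -> smallest m on ties
    return best, 100.0 * m_best / R, order[:m_best], sweep


def generalization_delta(acc_S3: float, acc_S3minus: float, acc_S1: float,
                         signed: bool = False) -> float:
    """Mean accuracy change from the reference atlas to its two variants.

    Absolute differences by default; ``signed=True`` averages the raw
    (signed) changes instead.
    """
    d1 = acc_S3minus - acc_S3
    d2 = acc_S1 - acc_S3
    if signed:
        return float((d1 + d2) / 2.0)
    return float((abs(d1) + abs(d2)) / 2.0)


def rank_pipelines(report: pd.DataFrame, top_n: int = 20):
    """Min-max normalize the six criteria to [0, 100] and average them.

    Criteria are concatenated over all cases (rows of ``report``);
    orientation is flipped where lower is better, so 100 is always best.
    A criterion that is constant across cases normalizes to 50 everywhere
    (with a warning).  Returns ``(ranked, top)``: the input frame with
    ``norm_*`` columns and a ``consensus`` column, and the top-``top_n``
    cases by raw fingerprinting accuracy per feature type (spider-plot
    export).
    """
    if len(report) < 2:
        raise ValueError("need at least 2 cases to rank")
    out = report.copy()
    for crit, higher_better in CRITERIA_HIGHER_BETTER.items():
        x = out[crit].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            warnings.warn(f"criterion {crit!r} constant across cases: "
                          "normalized to 50", UserWarning)
            norm = np.full_like(x, 50.0)
        else:
            norm = 100.0 * (x - lo) / (hi - lo)
            if not higher_better:
                norm = 100.0 - norm
        out[f"norm_{crit}"] = norm
    out["consensus"] = out[[f"norm_{c}" for c in CRITERIA]].mean(axis=1)
    if "feature_type" in out.columns:
        top = (out.sort_values("accuracy_max", ascending=False)
                  .groupby("feature_type", sort=False).head(top_n))
    else:
        top = out.sort_values("accuracy_max", ascending=False).head(top_n)
    return out, top
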