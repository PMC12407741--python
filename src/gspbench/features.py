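"""GSP feature extraction across the full factor-of-variation grid.

Regional BOLD time courses ``X`` (R x T) are optionally z-scored per region,
projected onto connectome harmonics with the graph Fourier transform
``xhat_t = U^T x_t``, optionally normalized per time point in the spectral
domain, and reduced to one of five feature vectors:

* ``PSD``         — per-harmonic power ``xhat^2`` (spectral domain),
* ``energy``      — per-harmonic ``lam_k * xhat`` (spectral domain),
* ``alignment``   — low-pass graph-filtered signal (regional domain),
* ``liberality``  — high-pass graph-filtered signal (regional domain),
* ``SDI``         — structural decoupling index, the per-region ratio of
  liberal to aligned temporal norms, with the low/high split set by one of
  four cutoff-frequency schemes (f1..f4).

All R x T representations are collapsed into a length-R feature vector by
the L2-norm over time.  The factor grid crosses edge property (4), structural
individuality (2), operator (4), temporal z-scoring (2) and spectral
normalization (2), extended by the retained-harmonics grid (10) for
alignment/liberality and the cutoff scheme (4) for SDI — 128, 1280 and 512
parameter combinations respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .cohort import DAYS, PHASES, Cohort
from .operators import (OPERATOR_KINDS, PROPERTIES, GraphSpectrum,
                        build_shift_operator, eigendecompose)

__all__ = [
    "FEATURE_TYPES",
    "CUTOFF_SCHEMES",
    "DegenerateSignalWarning",
    "ParameterCombination",
    "FeatureTable",
    "preprocess_timecourses",
    "gft",
    "igft",
    "spectral_normalize",
    "spectral_feature",
    "filter_coefficients",
    "graph_filter_feature",
    "coefficients_grid",
    "cutoff_frequency",
    "sdi",
    "enumerate_combinations",
    "compute_feature_table",
    "compute_single_combo",
]

FEATURE_TYPES = ("PSD", "energy", "alignment", "liberality", "SDI")
CUTOFF_SCHEMES = ("f1", "f2", "f3", "f4")
INDIVIDUALITY = ("group", "individual")


class DegenerateSignalWarning(UserWarning):
    """Raised for documented degenerate inputs (constant rows, zero columns)."""


@dataclass(frozen=True)
class ParameterCombination:
    """One cell of the factor grid.

    ``extra`` is the retained-harmonics count ``nH`` for alignment and
    liberality, the cutoff scheme (``f1``..``f4``) for SDI, and ``None`` for
    the spectral-domain features.
    """

    property: str
    individuality: str
    operator: str
    zscore: bool
    normalize: bool
    extra: int | str | None = None

    def label(self) -> str:
        parts = [self.property, self.individuality, self.operator,
                 f"z={int(self.zscore)}", f"norm={int(self.normalize)}"]
        if self.extra is not None:
            parts.append(str(self.extra))
        return "/".join(parts)


def preprocess_timecourses(X: np.ndarray, zscore: bool,
                           population_sd: bool = True) -> np.ndarray:
    """Optionally z-score each regional time course to mean 0, sd 1.

    Population-sd convention (divide by T) by default; set
    ``population_sd=False`` for the sample-sd (T-1) convention.  Constant
    rows are set to zero with a :class:`DegenerateSignalWarning`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an R x T matrix with T >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("time courses must be finite")
    if not zscore:
        return X
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0 if population_sd else 1, keepdims=True)
    const = sd[:, 0] == 0
    if np.any(const):
        warnings.warn(f"{const.sum()} constant region(s) zeroed during "
                      "z-scoring", DegenerateSignalWarning)
        sd[const] = 1.0
    Z = (X - mu) / sd
    Z[const] = 0.0
    return Z


def gft(spectrum: GraphSpectrum, X: np.ndarray, strict: bool = False) -> np.ndarray:
    """Graph Fourier transform: project signals onto the harmonics.

    For orthonormal bases this is ``U^T X``.  For the degree-weighted
    random-walk basis the adjoint ``U^T diag(w) X`` is used so that
    ``gft(igft(Y)) == Y``; ``strict=True`` forces plain ``U^T X`` for all
    kinds.
    """
    if X.shape[0] != spectrum.U.shape[0]:
        raise ValueError("basis/signal dimension mismatch")
    if spectrum.inner_product_weight is not None and not strict:
        return spectrum.U.T @ (spectrum.inner_product_weight[:, None] * X)
    return spectrum.U.T @ X


def igft(spectrum: GraphSpectrum, Xhat: np.ndarray) -> np.ndarray:
    """Inverse graph Fourier transform ``U Xhat``."""
    if Xhat.shape[0] != spectrum.U.shape[1]:
        raise ValueError("basis/coefficient dimension mismatch")
    return spectrum.U @ Xhat


def spectral_normalize(Xhat: np.ndarray) -> np.ndarray:
    """Normalize each time point to unit spectral energy (unit column L2-norm).

    Zero columns are left untouched with a warning.
    """
    norms = np.linalg.norm(Xhat, axis=0, keepdims=True)
    zero = norms[0] == 0
    if np.any(zero):
        warnings.warn(f"{zero.sum()} zero-energy time point(s) left "
                      "unnormalized", DegenerateSignalWarning)
        norms[:, zero] = 1.0
    return Xhat / norms


def spectral_feature(Xhat: np.ndarray, lam: np.ndarray, mode: str,
                     energy_squared: bool = False) -> np.ndarray:
    """Per-harmonic PSD or energy, reduced by the L2-norm over time.

    PSD is ``xhat_{t,k}^2``; energy is ``lam_k * xhat_{t,k}`` by default
    (set ``energy_squared=True`` for the variance-like ``lam_k * xhat^2``).
    """
    lam = np.asarray(lam, dtype=float)
    if Xhat.shape[0] != lam.shape[0]:
        raise ValueError("coefficients/eigenvalues mismatch")
    if mode == "PSD":
        Q = Xhat**2
    elif mode == "energy":
        Q = lam[:, None] * (Xhat**2 if energy_squared else Xhat)
    else:
        raise ValueError(f"unknown spectral feature mode {mode!r}")
    return np.linalg.norm(Q, axis=1)


def filter_coefficients(spectrum: GraphSpectrum, Xhat: np.ndarray,
                        side: str, nH: int) -> np.ndarray:
    """Reconstruct the low-pass (alignment) or high-pass (liberality) signal.

    ``H`` keeps the ``nH`` lowest-index harmonics for alignment and the
    ``nH`` highest-index harmonics for liberality: ``X_F = U H Xhat``.
    """
    R = spectrum.U.shape[1]
    if not 1 <= nH <= R:
        raise ValueError(f"nH must be in [1, {R}]")
    if side == "alignment":
        idx = slice(0, nH)
    elif side == "liberality":
        idx = slice(R - nH, R)
    else:
        raise ValueError(f"unknown filter side {side!r}")
    return spectrum.U[:, idx] @ Xhat[idx]


def graph_filter_feature(spectrum: GraphSpectrum, X: np.ndarray, side: str,
                         nH: int, Xhat: np.ndarray | None = None) -> np.ndarray:
    """Alignment/liberality feature: filtered signal L2-norm over time per region."""
    if Xhat is None:
        Xhat = gft(spectrum, X)
    XF = filter_coefficients(spectrum, Xhat, side, nH)
    return np.linalg.norm(XF, axis=1)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def coefficients_grid(R: int) -> list[int]:
    """Retained-harmonics grid: 5% to 20% of R in 10 uniform steps.

    Percentages are converted to counts by nearest-integer rounding (half
    away from zero); duplicates are kept so the grid size stays 10.
    """
    pcts = np.linspace(0.05, 0.20, 10)
    nH = _round_half_away(pcts * R).astype(int)
    if nH[0] < 1:
        raise ValueError(f"R={R} too small: 5% of R rounds below 1 harmonic")
    return [int(v) for v in nH]


def cutoff_frequency(psd: np.ndarray | None, R: int, scheme: str):
    """Cutoff between the low- (aligned) and high- (liberal) frequency sets.

    ``f1 = floor(R/2)`` uses only R.  The other schemes equate energy on the
    cumulative PSD (normalized so the last entry is 1 per time point):
    ``f2`` is the largest index with cumulative PSD <= 0.5, per time point
    (clamped to [1, R-1]); ``f3`` is the mode of the ``f2`` values (smallest
    on tie); ``f4`` applies the ``f2`` rule to the time-averaged cumulative
    PSD.  An all-zero-PSD time point falls back to ``f1`` with a warning.
    """
    if scheme not in CUTOFF_SCHEMES:
        raise ValueError(f"unknown cutoff scheme {scheme!r}")
    f1 = R // 2
    if scheme == "f1":
        return f1
    if psd is None or psd.size == 0:
        raise ValueError("schemes f2-f4 require a PSD matrix")
    if psd.shape[0] != R:
        raise ValueError("PSD row count must equal R")
    colsum = psd.sum(axis=0, keepdims=True)
    zero = colsum[0] == 0
    if np.any(zero):
        warnings.warn(f"{zero.sum()} all-zero-PSD time point(s): cutoff "
                      "falls back to f1", DegenerateSignalWarning)
        colsum[:, zero] = 1.0
    cum = np.cumsum(psd / colsum, axis=0)
    if scheme == "f4":
        cbar = cum.mean(axis=1)
        f4 = int(np.searchsorted(cbar, 0.5, side="right"))
        return int(np.clip(f4, 1, R - 1))
    f2 = (cum <= 0.5).sum(axis=0)
    f2 = np.clip(f2, 1, R - 1)
    f2[zero] = f1
    if scheme == "f2":
        return f2.astype(int)
    counts = np.bincount(f2.astype(int))
    return int(np.argmax(counts))  # smallest index on ties


def sdi(spectrum: GraphSpectrum, X: np.ndarray, cutoff,
        Xhat: np.ndarray | None = None) -> np.ndarray:
    """Structural decoupling index per region: ``||X_L|| / ||X_A||``.

    ``cutoff`` is the highest (1-based) harmonic index assigned to the
    low-frequency (aligned) set; a length-T vector applies one cutoff per
    time point (scheme f2).  A region with zero aligned norm yields ``+inf``
    if its liberal norm is nonzero, and 0 for 0/0, each with a warning.
    """
    if Xhat is None:
        Xhat = gft(spectrum, X)
    R, T = Xhat.shape
    cut = np.asarray(cutoff)
    if cut.ndim == 0:
        c = int(cut)
        if not 1 <= c <= R - 1:
            raise ValueError(f"cutoff must be in [1, {R - 1}]")
        low = filter_coefficients(spectrum, Xhat, "alignment", c)
        high = filter_coefficients(spectrum, Xhat, "liberality", R - c)
        low_sq = (low**2).sum(axis=1)
        high_sq = (high**2).sum(axis=1)
    else:
        if cut.shape != (T,):
            raise ValueError("per-timepoint cutoffs must have length T")
        if np.any((cut < 1) | (cut > R - 1)):
            raise ValueError(f"cutoffs must be in [1, {R - 1}]")
        low_sq = np.zeros(R)
        high_sq = np.zeros(R)
        for c in np.unique(cut):
            cols = cut == c
            low = spectrum.U[:, :c] @ Xhat[:c][:, cols]
            high = spectrum.U[:, c:] @ Xhat[c:][:, cols]
            low_sq += (low**2).sum(axis=1)
            high_sq += (high**2).sum(axis=1)
    aligned = np.sqrt(low_sq)
    liberal = np.sqrt(high_sq)
    out = np.empty(R)
    both_zero = (aligned == 0) & (liberal == 0)
    inf_mask = (aligned == 0) & ~both_zero
    if np.any(both_zero):
        warnings.warn(f"{both_zero.sum()} region(s) with 0/0 SDI set to 0",
                      DegenerateSignalWarning)
    if np.any(inf_mask):
        warnings.warn(f"{inf_mask.sum()} region(s) with zero aligned norm: "
                      "SDI is +inf", DegenerateSignalWarning)
    ok = ~(both_zero | inf_mask)
    out[ok] = liberal[ok] / aligned[ok]
    out[both_zero] = 0.0
    out[inf_mask] = np.inf
    return out


def enumerate_combinations(feature_type: str, R: int) -> list[ParameterCombination]:
    """Full parameter grid for one feature type.

    128 combinations for PSD/energy, 1280 for alignment/liberality (x10
    retained-harmonics values), 512 for SDI (x4 cutoff schemes).
    """
    if feature_type not in FEATURE_TYPES:
        raise ValueError(f"unknown feature type {feature_type!r}")
    base = product(PROPERTIES, INDIVIDUALITY, OPERATOR_KINDS,
                   (False, True), (False, True))
    if feature_type in ("PSD", "energy"):
        extras: list = [None]
    elif feature_type == "SDI":
        extras = list(CUTOFF_SCHEMES)
    else:
        extras = coefficients_grid(R)
    return [ParameterCombination(p, ind, op, z, n, e)
            for (p, ind, op, z, n) in base for e in extras]


class FeatureTable:
    """Feature vectors indexed by scan x feature type x parameter combination.

    ``scans`` is a DataFrame (subject, day, phase, mean_fd) whose row order
    matches the first axis of every stored ``(n_scans, R)`` array.
    """

    def __init__(self, scans: pd.DataFrame, n_regions: int):
        self.scans = scans.reset_index(drop=True)
        self.n_regions = n_regions
        self.data: dict[tuple[str, ParameterCombination], np.ndarray] = {}

    def set(self, feature_type: str, combo: ParameterCombination,
            values: np.ndarray) -> None:
        self.data[(feature_type, combo)] = values

    def get(self, feature_type: str, combo: ParameterCombination) -> np.ndarray:
        return self.data[(feature_type, combo)]

    def combos(self, feature_type: str) -> list[ParameterCombination]:
        return [c for (ft, c) in self.data if ft == feature_type]

    def feature_types(self) -> list[str]:
        return sorted({ft for (ft, _) in self.data},
                      key=FEATURE_TYPES.index)

    def scan_matrix(self, feature_type: str, combo: ParameterCombination,
                    day: int, phase: str) -> tuple[list[str], np.ndarray]:
        """(subjects, S x R feature matrix) for one (day, phase) condition."""
        mask = (self.scans["day"] == day) & (self.scans["phase"] == phase)
        sub = self.scans.loc[mask].sort_values("subject")
        return list(sub["subject"]), self.data[(feature_type, combo)][sub.index.values]

    def index_frame(self) -> pd.DataFrame:
        """Long-format index: one row per (scan, feature type, combination)."""
        rows = []
        for (ft, c), _ in self.data.items():
            for _, scan in self.scans.iterrows():
                rows.append({"subject": scan["subject"], "day": scan["day"],
                             "phase": scan["phase"], "feature_type": ft,
                             "property": c.property,
                             "individuality": c.individuality,
                             "operator": c.operator, "zscore": c.zscore,
                             "normalize": c.normalize, "extra": c.extra})
        return pd.DataFrame(rows)


def compute_feature_table(cohort: Cohort,
                          feature_types: tuple[str, ...] = FEATURE_TYPES,
                          variant: str = "S3") -> FeatureTable:
    """Run the full pipeline over the requested grid for every scan.

    Eigendecompositions are cached per (scope, property, operator) and
    spectral coefficients per (scan, SC, operator, z-scoring), so the
    512-1280-combination sweeps stay at desk scale.
    """
    cv = cohort.get_variant(variant)
    R = cv.config.n_regions
    scans = cv.scan_table
    table = FeatureTable(scans, R)
    for ft in feature_types:
        for combo in enumerate_combinations(ft, R):
            table.set(ft, combo, np.empty((len(scans), R)))

    spectra: dict[tuple[str, str, str], GraphSpectrum] = {}

    def get_spectrum(scope: str, prop: str, op: str) -> GraphSpectrum:
        key = (scope, prop, op)
        if key not in spectra:
            sc = (cv.group_sc[prop] if scope == "group"
                  else cv.subject_scs[scope][prop])
            spectra[key] = eigendecompose(build_shift_operator(sc, op))
        return spectra[key]

    nH_grid = coefficients_grid(R) if ("alignment" in feature_types or
                                       "liberality" in feature_types) else []
    for scan_i, (meta, X) in enumerate(cv.timeseries):
        Xz = {z: preprocess_timecourses(X, z) for z in (False, True)}
        for prop in PROPERTIES:
            for indiv in INDIVIDUALITY:
                scope = "group" if indiv == "group" else meta.subject
                for op in OPERATOR_KINDS:
                    spec = get_spectrum(scope, prop, op)
                    for z in (False, True):
                        Xhat0 = gft(spec, Xz[z])
                        for norm in (False, True):
                            Y = spectral_normalize(Xhat0) if norm else Xhat0
                            _fill_features(table, feature_types, scan_i, spec,
                                           prop, indiv, op, z, norm, Y, nH_grid)
    return table


def compute_single_combo(cohort: Cohort, feature_type: str,
                         combo: ParameterCombination,
                         variant: str = "S3") -> FeatureTable:
    """Feature table restricted to one parameter combination (fast path)."""
    cv = cohort.get_variant(variant)
    R = cv.config.n_regions
    scans = cv.scan_table
    table = FeatureTable(scans, R)
    values = np.empty((len(scans), R))
    spectra: dict[str, GraphSpectrum] = {}
    for scan_i, (meta, X) in enumerate(cv.timeseries):
        scope = "group" if combo.individuality == "group" else meta.subject
        if scope not in spectra:
            sc = (cv.group_sc[combo.property] if scope == "group"
                  else cv.subject_scs[scope][combo.property])
            spectra[scope] = eigendecompose(
                build_shift_operator(sc, combo.operator))
        spec = spectra[scope]
        Xp = preprocess_timecourses(X, combo.zscore)
        Y = gft(spec, Xp)
        if combo.normalize:
            Y = spectral_normalize(Y)
        if feature_type in ("PSD", "energy"):
            values[scan_i] = spectral_feature(Y, spec.lam, feature_type)
        elif feature_type in ("alignment", "liberality"):
            values[scan_i] = graph_filter_feature(spec, None, feature_type,
                                                  int(combo.extra), Xhat=Y)
        elif feature_type == "SDI":
            cut = cutoff_frequency(Y**2, R, str(combo.extra))
            values[scan_i] = sdi(spec, None, cut, Xhat=Y)
        else:
            raise ValueError(f"unknown feature type {feature_type!r}")
    table.set(feature_type, combo, values)
    return table


def _fill_features(table, feature_types, scan_i, spec, prop, indiv, op, z,
                   norm, Y, nH_grid) -> None:
    R = Y.shape[0]

    def key(extra):
        return ParameterCombination(prop, indiv, op, z, norm, extra)

    if "PSD" in feature_types:
        table.get("PSD", key(None))[scan_i] = spectral_feature(Y, spec.lam, "PSD")
    if "energy" in feature_types:
        table.get("energy", key(None))[scan_i] = spectral_feature(Y, spec.lam,
                                                                  "energy")
    for side in ("alignment", "liberality"):
        if side in feature_types:
            for nH in nH_grid:
                table.get(side, key(nH))[scan_i] = graph_filter_feature(
                    spec, None, side, nH, Xhat=Y)
    if "SDI" in feature_types:
        psd = Y**2
        for scheme in CUTOFF_SCHEMES:
            cut = cutoff_frequency(psd, R, scheme)
            table.get("SDI", key(scheme))[scan_i] = sdi(spec, None, cut, Xhat=Y)
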