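"""GSP feature extraction: transforms, filters, cutoffs, grids."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gspbench import (CohortConfig, ParameterCombination, build_shift_operator,
                      coefficients_grid, compute_feature_table,
                      cutoff_frequency, eigendecompose,
                      enumerate_combinations, generate_cohort, gft,
                      graph_filter_feature, igft, preprocess_timecourses,
                      sdi, spectral_feature, spectral_normalize)
from gspbench.features import DegenerateSignalWarning, filter_coefficients
from gspbench.operators import GraphSpectrum
from conftest import random_connected_sc


def spectrum_of(rng, R=8):
    return eigendecompose(build_shift_operator(random_connected_sc(rng, R=R),
                                               "L_U"))


# ---------------------------------------------------------------- preprocessing

def test_zscore_row_population_sd():
    X = np.array([[1.0, 2.0, 3.0]])
    Z = preprocess_timecourses(X, zscore=True)
    np.testing.assert_allclose(Z[0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)
    assert Z[0].mean() == pytest.approx(0.0, abs=1e-12)
    assert Z[0].std() == pytest.approx(1.0, abs=1e-12)


def test_zscore_passthrough_and_constant_row():
    X = np.array([[1.0, 2.0], [5.0, 5.0]])
    np.testing.assert_array_equal(preprocess_timecourses(X, zscore=False), X)
    with pytest.warns(DegenerateSignalWarning):
        Z = preprocess_timecourses(X, zscore=True)
    np.testing.assert_array_equal(Z[1], 0.0)


# ------------------------------------------------------------------------- GFT

def test_gft_identity_basis():
    R = 4
    spec = GraphSpectrum(U=np.eye(R), lam=np.arange(R, dtype=float),
                         kind="L_U", orthonormal=True)
    X = np.arange(12.0).reshape(R, 3)
    np.testing.assert_array_equal(gft(spec, X), X)


def test_gft_projects_harmonic_to_unit_vector(rng):
    spec = spectrum_of(rng)
    k = 3
    Xhat = gft(spec, spec.U[:, [k]])
    expected = np.zeros((spec.n_regions, 1))
    expected[k] = 1.0
    np.testing.assert_allclose(Xhat, expected, atol=1e-10)


def test_gft_constant_signal_loads_only_null_mode(rng):
    spec = spectrum_of(rng)
    X = np.ones((spec.n_regions, 5))
    Xhat = gft(spec, X)
    assert np.max(np.abs(Xhat[1:])) < 1e-8


def test_parseval(rng):
    spec = spectrum_of(rng)
    X = rng.normal(size=(spec.n_regions, 7))
    Xhat = gft(spec, X)
    np.testing.assert_allclose((Xhat**2).sum(axis=0), (X**2).sum(axis=0),
                               atol=1e-8)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), T=st.integers(2, 12))
def test_parseval_property(seed, T):
    rng = np.random.default_rng(seed)
    spec = spectrum_of(rng, R=int(rng.integers(5, 15)))
    X = rng.normal(size=(spec.n_regions, T))
    Xhat = gft(spec, X)
    np.testing.assert_allclose((Xhat**2).sum(axis=0), (X**2).sum(axis=0),
                               atol=1e-8)


def test_gft_igft_round_trip_degree_weighted(rng):
    sc = random_connected_sc(rng)
    spec = eigendecompose(build_shift_operator(sc, "L_RW"))
    Y = rng.normal(size=(sc.n_regions, 4))
    np.testing.assert_allclose(gft(spec, igft(spec, Y)), Y, atol=1e-10)
    # strict mode is the plain transpose
    X = rng.normal(size=(sc.n_regions, 4))
    np.testing.assert_array_equal(gft(spec, X, strict=True), spec.U.T @ X)


# ---------------------------------------------------------------- normalization

def test_spectral_normalize_column():
    Xhat = np.array([[3.0], [4.0]])
    np.testing.assert_allclose(spectral_normalize(Xhat), [[0.6], [0.8]])


def test_spectral_normalize_idempotent_and_zero_column(rng):
    Xhat = rng.normal(size=(5, 3))
    once = spectral_normalize(Xhat)
    np.testing.assert_allclose(spectral_normalize(once), once, atol=1e-12)
    with pytest.warns(DegenerateSignalWarning):
        out = spectral_normalize(np.zeros((4, 1)))
    np.testing.assert_array_equal(out, 0.0)


def test_normalized_psd_columns_sum_to_one(rng):
    Xhat = spectral_normalize(rng.normal(size=(6, 9)))
    np.testing.assert_allclose((Xhat**2).sum(axis=0), 1.0, atol=1e-10)


# -------------------------------------------------------------- spectral feats

def test_psd_squares_coefficients():
    Xhat = np.array([[2.0], [-3.0]])
    np.testing.assert_allclose(spectral_feature(Xhat, [1.0, 1.0], "PSD"),
                               [4.0, 9.0])


def test_energy_weights_coefficient_by_eigenvalue():
    Xhat = np.array([[5.0], [1.0]])
    lam = np.array([0.0, 2.0])
    np.testing.assert_allclose(spectral_feature(Xhat, lam, "energy"),
                               [0.0, 2.0])
    np.testing.assert_allclose(
        spectral_feature(Xhat, lam, "energy", energy_squared=True),
        [0.0, 2.0])  # same here since coefficient is 1
    np.testing.assert_allclose(
        spectral_feature(np.array([[5.0], [3.0]]), lam, "energy",
                         energy_squared=True), [0.0, 18.0])


def test_feature_nonnegativity(rng):
    spec = spectrum_of(rng)
    Xhat = gft(spec, rng.normal(size=(spec.n_regions, 6)))
    assert np.all(spectral_feature(Xhat, spec.lam, "PSD") >= 0)
    assert np.all(spectral_feature(Xhat, spec.lam, "energy") >= 0)


# -------------------------------------------------------------- graph filtering

def test_alignment_of_constant_signal_recovers_it(rng):
    spec = spectrum_of(rng)
    X = np.full((spec.n_regions, 5), 2.0)
    align = graph_filter_feature(spec, X, "alignment", nH=1)
    np.testing.assert_allclose(align, np.linalg.norm(X, axis=1), atol=1e-8)
    lib = graph_filter_feature(spec, X, "liberality", nH=1)
    np.testing.assert_allclose(lib, 0.0, atol=1e-8)


def test_all_pass_filter_returns_row_norms(rng):
    spec = spectrum_of(rng)
    X = rng.normal(size=(spec.n_regions, 6))
    for side in ("alignment", "liberality"):
        out = graph_filter_feature(spec, X, side, nH=spec.n_regions)
        np.testing.assert_allclose(out, np.linalg.norm(X, axis=1), atol=1e-8)


def test_filter_against_brute_force_projector(rng):
    """Oracle: explicitly build H and compute U H U^T X, R <= 8."""
    for _ in range(5):
        spec = spectrum_of(rng, R=int(rng.integers(4, 9)))
        R = spec.n_regions
        X = rng.normal(size=(R, 5))
        Xhat = gft(spec, X)
        for nH in range(1, R + 1):
            for side in ("alignment", "liberality"):
                H = np.zeros((R, R))
                keep = range(nH) if side == "alignment" else range(R - nH, R)
                for k in keep:
                    H[k, k] = 1.0
                oracle = np.linalg.norm(spec.U @ H @ spec.U.T @ X, axis=1)
                mine = graph_filter_feature(spec, X, side, nH)
                np.testing.assert_allclose(mine, oracle, atol=1e-10)


def test_filter_complementarity(rng):
    spec = spectrum_of(rng)
    R = spec.n_regions
    X = rng.normal(size=(R, 6))
    Xhat = gft(spec, X)
    for a in range(1, R):
        low = filter_coefficients(spec, Xhat, "alignment", a)
        high = filter_coefficients(spec, Xhat, "liberality", R - a)
        np.testing.assert_allclose(low + high, X, atol=1e-8)


def test_filter_nh_out_of_range(rng):
    spec = spectrum_of(rng)
    with pytest.raises(ValueError):
        graph_filter_feature(spec, np.zeros((spec.n_regions, 2)),
                             "alignment", 0)


# -------------------------------------------------------------------- nH grid

def test_coefficients_grid_frozen_values():
    assert coefficients_grid(274) == [14, 18, 23, 27, 32, 37, 41, 46, 50, 55]
    g100 = coefficients_grid(100)
    assert g100[0] == 5 and g100[-1] == 20 and len(g100) == 10
    assert coefficients_grid(20)[0] == 1
    with pytest.raises(ValueError):
        coefficients_grid(8)


# -------------------------------------------------------------------- cutoffs

def test_cutoff_f1_is_half_split():
    assert cutoff_frequency(None, 274, "f1") == 137


def test_cutoff_f2_per_timepoint():
    psd = np.array([[0.4], [0.2], [0.2], [0.2]])
    np.testing.assert_array_equal(cutoff_frequency(psd, 4, "f2"), [1])


def test_cutoff_f3_is_mode_of_f2():
    # four time points with per-timepoint crossings at 1, 2, 2, 3
    psd = np.array([
        [0.5, 0.2, 0.2, 0.1],
        [0.1, 0.3, 0.3, 0.2],
        [0.1, 0.2, 0.2, 0.2],
        [0.3, 0.3, 0.3, 0.5],
    ])
    np.testing.assert_array_equal(cutoff_frequency(psd, 4, "f2"),
                                  [1, 2, 2, 3])
    assert cutoff_frequency(psd, 4, "f3") == 2


def test_flat_psd_all_schemes_agree(rng):
    for R in (10, 11, 24):
        psd = np.ones((R, 7))
        f1 = cutoff_frequency(None, R, "f1")
        assert f1 == R // 2
        np.testing.assert_array_equal(cutoff_frequency(psd, R, "f2"), f1)
        assert cutoff_frequency(psd, R, "f3") == f1
        assert cutoff_frequency(psd, R, "f4") == f1


def test_cutoff_zero_psd_timepoint_falls_back():
    psd = np.ones((6, 3))
    psd[:, 1] = 0.0
    with pytest.warns(DegenerateSignalWarning):
        f2 = cutoff_frequency(psd, 6, "f2")
    assert f2[1] == 3


# ------------------------------------------------------------------------ SDI

def test_sdi_zero_for_constant_signal(rng):
    spec = spectrum_of(rng)
    X = np.ones((spec.n_regions, 5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateSignalWarning)
        out = sdi(spec, X, cutoff=3)
    np.testing.assert_allclose(out, 0.0, atol=1e-8)


def test_sdi_is_ratio_of_component_norms(rng):
    spec = spectrum_of(rng)
    R = spec.n_regions
    cutoff = R // 2
    # one low and one high harmonic on separate time points: the temporal
    # norms reduce to |u_low| and |u_high| per region, so SDI is their ratio
    Xhat = np.zeros((R, 2))
    Xhat[0, 0] = 1.0
    Xhat[R - 1, 1] = 1.0
    X = igft(spec, Xhat)
    low = spec.U[:, [0]]  # contributes only to column 0
    high = spec.U[:, [R - 1]]
    expected = np.abs(high[:, 0]) / np.abs(low[:, 0])
    out = sdi(spec, X, cutoff)
    np.testing.assert_allclose(out, expected, atol=1e-8)


def test_sdi_per_timepoint_cutoffs_match_column_filtering(rng):
    spec = spectrum_of(rng)
    R = spec.n_regions
    T = 6
    X = rng.normal(size=(R, T))
    cuts = rng.integers(1, R - 1, size=T)
    out = sdi(spec, X, cuts)
    Xhat = gft(spec, X)
    low = np.column_stack([spec.U[:, :c] @ Xhat[:c, [t]]
                           for t, c in enumerate(cuts)])
    high = np.column_stack([spec.U[:, c:] @ Xhat[c:, [t]]
                            for t, c in enumerate(cuts)])
    oracle = np.linalg.norm(high, axis=1) / np.linalg.norm(low, axis=1)
    np.testing.assert_allclose(out, oracle, atol=1e-10)


def test_sdi_cutoff_validation(rng):
    spec = spectrum_of(rng)
    X = rng.normal(size=(spec.n_regions, 3))
    with pytest.raises(ValueError):
        sdi(spec, X, cutoff=0)
    with pytest.raises(ValueError):
        sdi(spec, X, cutoff=spec.n_regions)


# ------------------------------------------------------------------- the grid

@pytest.mark.parametrize("ft,count", [("PSD", 128), ("energy", 128),
                                      ("alignment", 1280),
                                      ("liberality", 1280), ("SDI", 512)])
def test_grid_cardinalities(ft, count):
    combos = enumerate_combinations(ft, 274)
    assert len(combos) == count
    assert len(set(combos)) == count


def test_feature_table_complete_and_deterministic(tiny_cohort):
    t1 = compute_feature_table(tiny_cohort, ("PSD",))
    assert len(t1.combos("PSD")) == 128
    n_scans = len(tiny_cohort.timeseries)
    for c in t1.combos("PSD"):
        v = t1.get("PSD", c)
        assert v.shape == (n_scans, tiny_cohort.config.n_regions)
        assert np.all(np.isfinite(v))
        assert np.all(v >= 0)
    t2 = compute_feature_table(tiny_cohort, ("PSD",))
    for c in t1.combos("PSD"):
        np.testing.assert_array_equal(t1.get("PSD", c), t2.get("PSD", c))


def test_group_equals_individual_without_jitter():
    cfg = CohortConfig(n_subjects=3, n_regions=20, n_timepoints=30,
                       n_communities=2, subject_sc_jitter=0.0, seed=9)
    cohort = generate_cohort(cfg)
    table = compute_feature_table(cohort, ("PSD",))
    for combo in table.combos("PSD"):
        if combo.individuality != "group":
            continue
        twin = dataclasses.replace(combo, individuality="individual")
        np.testing.assert_allclose(table.get("PSD", combo),
                                   table.get("PSD", twin), atol=1e-8)
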