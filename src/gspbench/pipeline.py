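"""End-to-end orchestration: cohort -> feature tables -> quality report -> ranking.

`evaluate_quality` computes the six quality criteria for every parameter
combination of the requested feature types, using the reference parcellation
(S3) for all criteria except the generalization change, which compares
full-set fingerprinting accuracy across the three parcellation variants.
Combinations are matched across variants by their position in the grid
enumeration, because the retained-harmonics values are R-dependent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import Cohort
from .features import (FEATURE_TYPES, FeatureTable, compute_feature_table,
                       enumerate_combinations)
from .quality import (fingerprint_accuracy_pairs, generalization_delta,
                      icc_a1_batch, movement_variance, rank_pipelines,
                      select_features_by_icc, session_similarity_stats)

__all__ = ["evaluate_quality", "run_ranking"]


def _allscan_icc(table: FeatureTable, feature_type: str, combo) -> np.ndarray:
    """Per-coefficient ICC(A,1) over all four scans (k=4)."""
    order = table.scans.sort_values(["subject", "day", "phase"])
    F = table.get(feature_type, combo)[order.index.values]
    S = order["subject"].nunique()
    stack = F.reshape(S, 4, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return icc_a1_batch(stack)


def evaluate_quality(cohort: Cohort,
                     feature_types: tuple[str, ...] = FEATURE_TYPES,
                     selection_stride: int = 1,
                     omega_variant: str = "magnitude",
                     variants: tuple[str, ...] = ("S3", "S3-", "S1"),
                     tables: dict[str, FeatureTable] | None = None
                     ) -> pd.DataFrame:
    """Six quality criteria per feature type x parameter combination.

    Returns one row per case with the raw criteria plus the intermediates
    (Rbar_same, Rbar_diff means, omega, accuracy_full).  Precomputed feature
    tables can be passed via ``tables`` (keyed by variant name).
    """
    if tables is None:
        tables = {v: compute_feature_table(cohort, feature_types, variant=v)
                  for v in variants}
    ref = tables["S3"]
    rows = []
    for ft in feature_types:
        # map each stored combination to its first position in the grid
        # enumeration, so variants with different R (hence different nH
        # values, possibly duplicated) can be matched position-wise
        enum = {v: enumerate_combinations(ft, tables[v].n_regions)
                for v in tables}
        first_pos: dict = {}
        for i, c in enumerate(enum["S3"]):
            first_pos.setdefault(c, i)
        for combo in tables["S3"].combos(ft):
            ci = first_pos[combo]
            sim, omega, pct_incong = session_similarity_stats(
                ref, ft, combo, omega_variant=omega_variant)
            acc_max, pct_used, selected, _ = select_features_by_icc(
                ref, ft, combo, stride=selection_stride)
            pfd_all = movement_variance(ref, ft, combo)
            pfd_sel = movement_variance(ref, ft, combo,
                                        coefficient_subset=selected)
            icc_all = _allscan_icc(ref, ft, combo)
            icc_sel = float(np.nanmean(icc_all[selected]))
            acc_full = {v: fingerprint_accuracy_pairs(tables[v], ft,
                                                      enum[v][ci])
                        for v in tables}
            gen = (generalization_delta(acc_full["S3"], acc_full["S3-"],
                                        acc_full["S1"])
                   if {"S3-", "S1"} <= set(tables) else np.nan)
            rows.append({
                "feature_type": ft,
                "property": combo.property,
                "individuality": combo.individuality,
                "operator": combo.operator,
                "zscore": combo.zscore,
                "normalize": combo.normalize,
                "extra": combo.extra,
                "Rbar_same": float(np.mean(sim.Rbar_same[sim.valid])),
                "Rbar_diff": float(np.mean(sim.Rbar_diff[sim.valid])),
                "omega": omega,
                "pct_incongruent": pct_incong,
                "pfd_all": pfd_all,
                "pfd_selected": pfd_sel,
                "icc_selected": icc_sel,
                "accuracy_full": acc_full["S3"],
                "accuracy_max": acc_max,
                "pct_coeffs_used": pct_used,
                "generalization_change": gen,
            })
    return pd.DataFrame(rows)


def run_ranking(report: pd.DataFrame, top_n: int = 20):
    """Consensus ranking over a quality report (see `rank_pipelines`)."""
    return rank_pipelines(report, top_n=top_n)
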