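"""HDF5 / CSV persistence for cohorts and feature tables.

Cohort layout: ``/group_sc/<property>``, ``/subject_sc/<subject>/<property>``,
``/timeseries/<subject>/<day>/<phase>``, ``/meta`` (scan table), and
``/variants``.  Feature tables are stored as one dataset per feature type
with a CSV-compatible long-format index.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, ScanMeta
from .features import FeatureTable, ParameterCombination
from .operators import StructuralConnectome

__all__ = ["save_cohort", "load_cohort", "save_feature_table",
           "load_feature_table"]


def save_cohort(cohort: Cohort, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(cohort.config))
        for prop, sc in cohort.group_sc.items():
            f.create_dataset(f"group_sc/{prop}", data=sc.weights)
        for subj, d in cohort.subject_scs.items():
            for prop, sc in d.items():
                f.create_dataset(f"subject_sc/{subj}/{prop}", data=sc.weights)
        for meta, X in cohort.timeseries:
            f.create_dataset(
                f"timeseries/{meta.subject}/{meta.day}/{meta.phase}", data=X)
        tbl = cohort.scan_table
        grp = f.create_group("meta")
        grp.create_dataset("subject", data=tbl["subject"].astype("S"))
        grp.create_dataset("day", data=tbl["day"].to_numpy())
        grp.create_dataset("phase", data=tbl["phase"].astype("S"))
        grp.create_dataset("mean_fd", data=tbl["mean_fd"].to_numpy())
        f.create_dataset("communities", data=cohort.communities)
        var = f.create_group("variants")
        var.create_dataset("S3", data=np.asarray(cohort.variant_maps["S3"]))
        var.create_dataset("S3-", data=np.asarray(cohort.variant_maps["S3-"]))
        var.attrs["S1"] = json.dumps(cohort.variant_maps["S1"])


def load_cohort(path: str) -> Cohort:
    with h5py.File(path, "r") as f:
        config = CohortConfig(**json.loads(f.attrs["config"]))
        group_sc = {p: StructuralConnectome(f[f"group_sc/{p}"][()], p, "group")
                    for p in f["group_sc"]}
        subject_scs = {
            s: {p: StructuralConnectome(f[f"subject_sc/{s}/{p}"][()], p, s)
                for p in f[f"subject_sc/{s}"]}
            for s in f["subject_sc"]
        }
        meta = f["meta"]
        subjects = [s.decode() for s in meta["subject"][()]]
        days = meta["day"][()]
        phases = [p.decode() for p in meta["phase"][()]]
        fds = meta["mean_fd"][()]
        timeseries = []
        for s, d, p, fd in zip(subjects, days, phases, fds):
            X = f[f"timeseries/{s}/{d}/{p}"][()]
            timeseries.append((ScanMeta(s, int(d), p, float(fd)), X))
        communities = f["communities"][()]
        variant_maps = {
            "S3": f["variants/S3"][()],
            "S3-": f["variants/S3-"][()],
            "S1": json.loads(f["variants"].attrs["S1"]),
        }
    return Cohort(config=config, group_sc=group_sc, subject_scs=subject_scs,
                  timeseries=timeseries, communities=communities,
                  variant_maps=variant_maps)


def _combo_key(combo: ParameterCombination) -> str:
    return json.dumps([combo.property, combo.individuality, combo.operator,
                       combo.zscore, combo.normalize, combo.extra])


def save_feature_table(table: FeatureTable, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_regions"] = table.n_regions
        grp = f.create_group("scans")
        grp.create_dataset("subject", data=table.scans["subject"].astype("S"))
        grp.create_dataset("day", data=table.scans["day"].to_numpy())
        grp.create_dataset("phase", data=table.scans["phase"].astype("S"))
        grp.create_dataset("mean_fd", data=table.scans["mean_fd"].to_numpy())
        for (ft, combo), values in table.data.items():
            ds = f.create_dataset(f"features/{ft}/{_combo_key(combo)}",
                                  data=values)


def load_feature_table(path: str) -> FeatureTable:
    with h5py.File(path, "r") as f:
        scans = pd.DataFrame({
            "subject": [s.decode() for s in f["scans/subject"][()]],
            "day": f["scans/day"][()],
            "phase": [p.decode() for p in f["scans/phase"][()]],
            "mean_fd": f["scans/mean_fd"][()],
        })
        table = FeatureTable(scans, int(f.attrs["n_regions"]))
        for ft in f["features"]:
            for key in f[f"features/{ft}"]:
                p, ind, op, z, n, extra = json.loads(key)
                combo = ParameterCombination(p, ind, op, bool(z), bool(n),
                                             extra)
                table.set(ft, combo, f[f"features/{ft}/{key}"][()])
    return table
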