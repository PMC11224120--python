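"""File formats for cohort archives and analysis artifacts.

Cohort archives are HDF5 with one group per subject x condition holding the
time series, confounds and (for task conditions) the event table; the
generating config and seed travel as root attributes. Partitions and
matrices are exchanged as delimited text so they stay diffable.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd
import yaml

from .modularity import Partition
from .synthetic import CohortConfig, SubjectConditionSeries

_EVENT_COLS = ["trial", "onset", "duration", "phase", "event_type"]


def save_cohort(path, series_list, phenotypes: pd.DataFrame,
                ground_truth: dict | None = None, config: CohortConfig | None = None):
    """Write a cohort archive (HDF5) plus the embedded phenotype table."""
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        if config is not None:
            f.attrs["config"] = yaml.safe_dump(_config_dict(config))
            f.attrs["seed"] = config.seed
        for s in series_list:
            g = f.require_group(f"subjects/{s.subject_id}/{s.condition}")
            g.create_dataset("timeseries", data=s.data, compression="gzip")
            g.create_dataset("confounds", data=s.confounds, compression="gzip")
            g.attrs["repetition_time"] = s.repetition_time
            if s.events is not None:
                ev = g.require_group("events")
                ev.create_dataset("trial", data=s.events["trial"].to_numpy(np.int64))
                ev.create_dataset("onset", data=s.events["onset"].to_numpy(float))
                ev.create_dataset("duration", data=s.events["duration"].to_numpy(float))
                ev.create_dataset("phase", data=[str(x) for x in s.events["phase"]], dtype=str_dt)
                ev.create_dataset("event_type", data=[str(x) for x in s.events["event_type"]], dtype=str_dt)
        ph = f.require_group("phenotypes")
        ph.create_dataset("subject", data=[str(x) for x in phenotypes.index], dtype=str_dt)
        ph.attrs["columns"] = list(map(str, phenotypes.columns))
        for col in phenotypes.columns:
            ph.create_dataset(col, data=phenotypes[col].to_numpy(float))
        if ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(ground_truth)


def load_cohort(path):
    """Read a cohort archive; returns (series list, phenotypes, ground_truth)."""
    series = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            for cond in f[f"subjects/{sid}"]:
                g = f[f"subjects/{sid}/{cond}"]
                events = None
                if "events" in g:
                    ev = g["events"]
                    events = pd.DataFrame({
                        "trial": ev["trial"][()],
                        "onset": ev["onset"][()],
                        "duration": ev["duration"][()],
                        "phase": [x.decode() for x in ev["phase"][()]],
                        "event_type": [x.decode() for x in ev["event_type"][()]],
                    })[_EVENT_COLS]
                series.append(SubjectConditionSeries(
                    sid, cond, g["timeseries"][()], g["confounds"][()],
                    float(g.attrs["repetition_time"]), events))
        ph = f["phenotypes"]
        idx = [x.decode() for x in ph["subject"][()]]
        cols = list(ph.attrs.get("columns",
                                 [c for c in ph if c != "subject"]))
        phen = pd.DataFrame({c: ph[c][()] for c in cols},
                            index=pd.Index(idx, name="subject"))
        gt = json.loads(f.attrs["ground_truth"]) if "ground_truth" in f.attrs else None
    return series, phen, gt


def save_connectivity(path, matrices: dict):
    """Write (subject, condition) -> ConnectivityMatrix mapping to HDF5."""
    with h5py.File(path, "w") as f:
        for (sid, cond), cm in matrices.items():
            g = f.require_group(f"{sid}/{cond}")
            g.create_dataset("z", data=cm.values, compression="gzip")
            g.attrs["flagged_nodes"] = list(cm.flagged_nodes)


def load_connectivity(path):
    from .connectivity import ConnectivityMatrix
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            for cond in f[sid]:
                g = f[f"{sid}/{cond}"]
                out[(sid, cond)] = ConnectivityMatrix(
                    sid, cond, g["z"][()], tuple(g.attrs.get("flagged_nodes", ())))
    return out


def save_partition_table(path, records):
    """Long-format partition table: rows of dicts with a ``labels`` array."""
    rows = []
    for rec in records:
        labels = rec.pop("labels")
        for node, module in enumerate(np.asarray(labels)):
            rows.append({**rec, "node": node, "module": int(module)})
        rec["labels"] = labels
    pd.DataFrame(rows).to_csv(path, index=False)


def load_partition_table(path):
    """Inverse of :func:`save_partition_table`; yields (key dict, Partition)."""
    df = pd.read_csv(path)
    keys = [c for c in df.columns if c not in ("node", "module")]
    for key_vals, grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("node")
        key = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        yield key, Partition(grp["module"].to_numpy())


def save_square_matrix(path, values: np.ndarray, labels=None):
    n = values.shape[0]
    labels = labels if labels is not None else [f"n{i}" for i in range(n)]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def load_square_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(float)


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["planted_partitions"] = {c: p.labels.tolist()
                               for c, p in config.planted_partitions.items()}
    d["conditions"] = list(config.conditions)
    d["phenotype_effects"] = {k: list(v) for k, v in config.phenotype_effects.items()}
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if d.get("planted_partitions"):
        d["planted_partitions"] = {c: Partition(np.asarray(v))
                                   for c, v in d["planted_partitions"].items()}
    if d.get("phenotype_effects"):
        d["phenotype_effects"] = {k: tuple(v) for k, v in d["phenotype_effects"].items()}
    if d.get("conditions"):
        d["conditions"] = tuple(d["conditions"])
    return CohortConfig(**d)
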