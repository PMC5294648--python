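"""Readers and writers: tab-separated tables/matrices with a YAML sidecar
for metadata and YAML records for results.  Floating-point cells are written
with 17 significant digits so every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_network import (
    BipartiteDistanceMatrix,
    SubjectData,
    SymmetricDistanceMatrix,
    TrialPowerTable,
)
from .stats import BehavioralRecord

__all__ = [
    "write_power_table", "read_power_table",
    "write_matrix", "read_matrix",
    "write_bipartite_matrix", "read_bipartite_matrix",
    "write_behavior", "read_behavior",
    "write_yaml", "read_yaml",
    "write_cohort", "read_cohort",
    "power_table_filename",
]

_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def write_power_table(table: TrialPowerTable, path) -> Path:
    """TSV (header = ROI labels, one row per trial) plus a key-value sidecar
    carrying subject/condition/band-epoch provenance."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(table.roi_labels) + "\n")
        np.savetxt(fh, table.values, fmt=_FMT, delimiter="\t")
    meta = {
        "subject_id": table.subject_id,
        "condition": table.condition,
        "band_epoch": table.band_epoch,
        "n_trials": int(table.n_trials),
    }
    with open(_sidecar(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_power_table(path) -> TrialPowerTable:
    path = Path(path)
    with open(_sidecar(path), "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    df = pd.read_csv(path, sep="\t", header=0, dtype=float,
                     float_precision="round_trip")
    return TrialPowerTable(
        subject_id=str(meta["subject_id"]),
        condition=str(meta["condition"]),
        band_epoch=str(meta["band_epoch"]),
        roi_labels=tuple(df.columns),
        values=df.to_numpy(),
    )


def write_matrix(values: np.ndarray, row_labels, col_labels, path) -> Path:
    path = Path(path)
    values = np.asarray(values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(col_labels) + "\n")
        for lab, row in zip(row_labels, values):
            fh.write(lab + "\t" + "\t".join(_FMT % v for v in row) + "\n")
    return path


def read_matrix(path):
    """Returns (values, row_labels, col_labels)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0,
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(str(x) for x in df.index), tuple(df.columns)


def write_bipartite_matrix(D: BipartiteDistanceMatrix, path) -> Path:
    return write_matrix(D.values, D.row_labels, D.col_labels, path)


def read_bipartite_matrix(path, n_trials_used: int = 0) -> BipartiteDistanceMatrix:
    values, rows, cols = read_matrix(path)
    return BipartiteDistanceMatrix(row_labels=rows, col_labels=cols,
                                   values=values, n_trials_used=n_trials_used)


_BEHAVIOR_COLS = ["subject_id", "r_hits", "r_trials", "nr_hits", "nr_trials",
                  "false_alarms", "new_trials"]


def write_behavior(records, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_BEHAVIOR_COLS) + "\n")
        for r in records:
            fh.write("\t".join(str(getattr(r, c)) for c in _BEHAVIOR_COLS) + "\n")
    return path


def read_behavior(path) -> list:
    df = pd.read_csv(path, sep="\t", header=0)
    return [
        BehavioralRecord(
            subject_id=str(row["subject_id"]),
            r_hits=int(row["r_hits"]), r_trials=int(row["r_trials"]),
            nr_hits=int(row["nr_hits"]), nr_trials=int(row["nr_trials"]),
            false_alarms=int(row["false_alarms"]), new_trials=int(row["new_trials"]),
        )
        for _, row in df.iterrows()
    ]


def write_yaml(obj, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def read_yaml(path):
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def power_table_filename(subject_id: str, condition: str, band_epoch: str) -> str:
    return f"{subject_id}_cond-{condition}_epoch-{band_epoch}.tsv"


def write_cohort(subjects, behavior, directory, manifest=None) -> Path:
    """Write every subject table, the behavioral table and (optionally) the
    ground-truth manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for subj in subjects:
        for (cond, epoch), table in subj.tables.items():
            write_power_table(table, directory / power_table_filename(subj.subject_id, cond, epoch))
    write_behavior(behavior, directory / "behavior.tsv")
    if manifest is not None:
        write_yaml(manifest, directory / "manifest.yaml")
    return directory


def read_cohort(directory):
    """Load a cohort directory.  Returns (subjects, behavior records).

    Raises a labeled error naming the subject when a band-epoch table is
    missing.
    """
    directory = Path(directory)
    tables: dict[str, dict] = {}
    for path in sorted(directory.glob("*.tsv")):
        if path.name == "behavior.tsv":
            continue
        table = read_power_table(path)
        tables.setdefault(table.subject_id, {})[(table.condition, table.band_epoch)] = table
    subjects = []
    for sid in sorted(tables):
        try:
            subjects.append(SubjectData(subject_id=sid, tables=tables[sid]))
        except ValueError as exc:
            raise ValueError(f"cohort at {directory}: {exc}") from exc
    behavior_path = directory / "behavior.tsv"
    behavior = read_behavior(behavior_path) if behavior_path.exists() else []
    return subjects, behavior
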