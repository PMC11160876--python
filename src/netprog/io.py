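"""Readers and writers for the pipeline's plain-text artifact formats.

Everything is delimited text, JSON or YAML: regional profile tables (TSV,
rows = subjects, columns = region labels), pattern weight files (TSV),
score tables (CSV), adjacency matrices (TSV with label header row/column),
connection-change tables (CSV), anatomy edge lists (TSV), DAT count tables
(CSV) and configuration (YAML).  All writer/reader pairs round-trip finite
values losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, PlantedEdge
from .connectivity import AdjacencyMatrix, ConnectionChange
from .exceptions import DomainError
from .expression import NetworkPattern, RegionalProfileSet, ScoreSet
from .phenoconversion import PredictorConfig

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_pattern",
    "write_pattern",
    "write_scores",
    "read_adjacency",
    "write_adjacency",
    "write_changes",
    "read_anatomy",
    "write_anatomy",
    "read_cohort_config",
    "write_cohort_config",
    "read_predictor_config",
    "write_predictor_config",
    "write_json",
]

_FLOAT_FMT = "%.17g"


def write_profiles(profiles: RegionalProfileSet, path) -> None:
    df = profiles.values.copy()
    df.index.name = "subject"
    df.to_csv(path, sep="\t", float_format=None)


def read_profiles(path, group: str = "", timepoint: float = 0.0) -> RegionalProfileSet:
    """Read a subjects x regions TSV; validates positivity and label uniqueness."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise DomainError(f"{path}: duplicate region labels: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.empty:
        raise DomainError(f"{path}: no subject rows")
    bad = df.columns[df.isna().any(axis=0)]
    if len(bad):
        row = int(np.nonzero(df[bad[0]].isna().to_numpy())[0][0])
        raise DomainError(f"{path}: missing value at line {row + 2}, region {bad[0]!r}")
    try:
        return RegionalProfileSet(values=df, group=group, timepoint=timepoint)
    except DomainError as err:
        raise DomainError(f"{path}: {err}") from err


def write_pattern(pattern: NetworkPattern, path, region_labels=None) -> None:
    """Write all parcellation regions with weight and flag columns."""
    labels = list(region_labels) if region_labels is not None else list(pattern.weights.index)
    rows = []
    for lab in labels:
        member = lab in pattern.weights.index
        rows.append(
            {
                "region_label": lab,
                "weight": float(pattern.weights.get(lab, 0.0)),
                "membership_flag": int(member),
                "core_flag": int(lab in pattern.core),
                "active_flag": int(lab in pattern.active) if pattern.active is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pattern(path, name: str | None = None) -> NetworkPattern:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    mem = df[df["membership_flag"] == 1]
    active_col = df["active_flag"] if "active_flag" in df else None
    has_active = active_col is not None and active_col.notna().all() and len(df)
    return NetworkPattern(
        name=name or path.stem.upper(),
        weights=pd.Series(mem["weight"].to_numpy(), index=mem["region_label"].tolist()),
        core=frozenset(df.loc[df["core_flag"] == 1, "region_label"]),
        active=frozenset(df.loc[df["active_flag"] == 1, "region_label"]) if has_active else None,
    )


def write_scores(score_sets: list[ScoreSet], path) -> None:
    pd.concat([s.to_frame() for s in score_sets], ignore_index=True).to_csv(path, index=False)


def write_adjacency(adj: AdjacencyMatrix, path) -> None:
    df = adj.r.copy()
    df.index.name = "region"
    df.to_csv(path, sep="\t")


def read_adjacency(path, group: str = "", timepoint: float = 0.0) -> AdjacencyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return AdjacencyMatrix(r=df, group=group, timepoint=timepoint)


def write_changes(changes: list[ConnectionChange], path) -> None:
    cols = [f.name for f in dataclasses.fields(ConnectionChange)]
    rows = [dataclasses.asdict(ch) for ch in changes]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_anatomy(edges, path) -> None:
    pd.DataFrame(sorted(edges), columns=["region_a", "region_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_anatomy(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df[["region_a", "region_b"]].itertuples(index=False)]


def write_cohort_config(config: CohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["planted_gains"] = [dataclasses.asdict(e) for e in config.planted_gains]
    d["planted_losses"] = [dataclasses.asdict(e) for e in config.planted_losses]
    for key in ("timepoints", "case_n_by_timepoint", "dat_n_by_timepoint"):
        if d[key] is not None:
            d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_cohort_config(path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("planted_gains", "planted_losses"):
        edges = []
        for e in d.get(key) or []:
            if e.get("timepoints") is not None:
                e["timepoints"] = tuple(e["timepoints"])
            edges.append(PlantedEdge(**e))
        d[key] = tuple(edges)
    return CohortConfig(**d)


def write_predictor_config(config: PredictorConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


def read_predictor_config(path) -> PredictorConfig:
    return PredictorConfig(**yaml.safe_load(Path(path).read_text()))


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
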