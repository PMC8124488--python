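"""Tidy-CSV readers/writers, run configuration, and provenance.

Interchange conventions: UTF-8 comma-separated CSV with a mandatory
header row and "." decimals; area identifiers are strings everywhere
(internal 0-based indices never appear in files); every output file
carries ``# key: value`` provenance comment lines (input hashes, seeds,
package version) so that re-running with unchanged inputs reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graphs import AreaGraph
from .synth import STRATA

__all__ = [
    "read_count_panel",
    "read_population_panel",
    "read_covariates",
    "read_road_records",
    "read_neighbor_csv",
    "write_neighbor_csv",
    "write_csv_with_provenance",
    "file_sha256",
    "RunConfig",
    "load_run_config",
    "aggregate_window",
]

FLOAT_FORMAT = "%.17g"


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_csv_with_provenance(
    df: pd.DataFrame, path, provenance: dict | None = None, index: bool = False
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=index, float_format=FLOAT_FORMAT)


def _read_tidy(path, value_col: str, dtype) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"area_id": str, "stratum": str})
    required = {"area_id", "year", "stratum", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["stratum"]) - set(STRATA)
    if bad:
        raise ValueError(f"{path}: unknown strata {sorted(bad)} (allowed: {STRATA})")
    df["year"] = df["year"].astype(int)
    df[value_col] = df[value_col].astype(dtype)
    return df


def read_count_panel(path) -> pd.DataFrame:
    """Hospitalization counts: columns area_id, year, stratum, count (>= 0)."""
    df = _read_tidy(path, "count", int)
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_population_panel(path) -> pd.DataFrame:
    """Population panel: columns area_id, year, stratum, population (> 0)."""
    df = _read_tidy(path, "population", float)
    if (df["population"] <= 0).any():
        raise ValueError(f"{path}: nonpositive population")
    return df


def read_covariates(path) -> pd.DataFrame:
    """Per-area covariate table with at least the six design columns."""
    from .model import DESIGN_COLUMNS

    df = pd.read_csv(path, comment="#", dtype={"area_id": str})
    missing = ({"area_id"} | set(DESIGN_COLUMNS)) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_road_records(path):
    """Road monitoring CSV (road_id, area_id, monitor_id, density) ->
    list of RoadRecord (rows with empty density mark roads without data)."""
    from .preprocess import RoadRecord

    df = pd.read_csv(path, comment="#", dtype={"road_id": str, "area_id": str})
    records = []
    for (road_id, area_id), grp in df.groupby(["road_id", "area_id"], sort=True):
        vals = [float(v) for v in grp["density"] if pd.notna(v)]
        records.append(RoadRecord(road_id, area_id, vals))
    return records


def read_neighbor_csv(path) -> AreaGraph:
    """Neighbor-list CSV (area_id, neighbor_id, weight) -> AreaGraph."""
    df = pd.read_csv(
        path, comment="#", dtype={"area_id": str, "neighbor_id": str}
    )
    area_ids = list(dict.fromkeys(df["area_id"]))
    idx = {a: i for i, a in enumerate(area_ids)}
    neighbors: list[list[int]] = [[] for _ in area_ids]
    weights: list[list[float]] = [[] for _ in area_ids]
    for _, row in df.iterrows():
        a, b = row["area_id"], row["neighbor_id"]
        if b not in idx:
            raise ValueError(f"{path}: neighbor {b!r} never appears as area_id")
        neighbors[idx[a]].append(idx[b])
        weights[idx[a]].append(float(row.get("weight", 1.0)))
    return AreaGraph(area_ids, neighbors, weights)


def write_neighbor_csv(graph: AreaGraph, path, provenance: dict | None = None) -> None:
    rows = []
    for i, (nbs, ws) in enumerate(zip(graph.neighbors, graph.weights)):
        for j, w in zip(nbs, ws):
            rows.append((graph.area_ids[i], graph.area_ids[j], w))
    df = pd.DataFrame(rows, columns=["area_id", "neighbor_id", "weight"])
    write_csv_with_provenance(df, path, provenance)


def aggregate_window(
    counts: pd.DataFrame,
    population: pd.DataFrame,
    graph: AreaGraph,
    years,
    stratum: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool the study window into the model inputs (y, log tot).

    y[i] is the window count sum (rounded half-to-even if corrections left
    it non-integer); tot[i] the person-period population summed over the
    window years, entering as a log offset.
    Areas follow the graph ordering.
    """
    c = counts[(counts["stratum"] == stratum) & counts["year"].isin(years)]
    p = population[
        (population["stratum"] == stratum) & population["year"].isin(years)
    ]
    y = c.groupby("area_id")["count"].sum()
    tot = p.groupby("area_id")["population"].sum()
    missing = [a for a in graph.area_ids if a not in y.index or a not in tot.index]
    if missing:
        raise ValueError(f"areas missing from panels in window: {missing}")
    y = np.rint(y.loc[graph.area_ids].to_numpy(dtype=float)).astype(int)
    tot = tot.loc[graph.area_ids].to_numpy(dtype=float)
    if np.any(tot <= 0):
        raise ValueError("nonpositive window population")
    return y, np.log(tot)


@dataclass
class RunConfig:
    """Run configuration for the CLI pipeline (YAML-serializable)."""

    counts: str
    population: str
    covariates: str
    adjacency: str
    output_dir: str
    stratum: str = "total"
    years: tuple[int, int] = (2013, 2017)
    per: float = 1000.0
    base_seed: int = 0
    model: dict = dc_field(default_factory=dict)
    mcmc: dict = dc_field(default_factory=dict)
    closure: dict | None = None

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")

    @property
    def year_range(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def input_paths(self) -> dict[str, str]:
        return {
            "counts": self.counts,
            "population": self.population,
            "covariates": self.covariates,
            "adjacency": self.adjacency,
        }

    def provenance(self) -> dict:
        prov = {f"sha256_{k}": file_sha256(v) for k, v in self.input_paths().items()}
        prov["base_seed"] = self.base_seed
        prov["stratum"] = self.stratum
        prov["years"] = f"{self.years[0]}-{self.years[1]}"
        return prov


def load_run_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    inputs = raw.pop("inputs", {})
    base = Path(path).parent
    kwargs = dict(raw)
    for key in ("counts", "population", "covariates", "adjacency"):
        if key not in inputs:
            raise ValueError(f"{path}: missing inputs.{key}")
        kwargs[key] = str((base / inputs[key]).resolve())
    kwargs["output_dir"] = str((base / raw.get("output_dir", "out")).resolve())
    if "years" in kwargs:
        kwargs["years"] = tuple(kwargs["years"])
    cfg = RunConfig(**kwargs)
    for p in cfg.input_paths().values():
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")
    return cfg


def write_run_report(path, config: RunConfig, extra: dict | None = None) -> None:
    """JSON run report: config echo, input hashes, package version."""
    from . import __version__

    report = {
        "package": "carioca",
        "version": __version__,
        "config": {
            **{k: str(v) for k, v in config.input_paths().items()},
            "output_dir": config.output_dir,
            "stratum": config.stratum,
            "years": list(config.years),
            "per": config.per,
            "base_seed": config.base_seed,
            "model": config.model,
            "mcmc": config.mcmc,
        },
        "input_hashes": {
            k: file_sha256(v) for k, v in config.input_paths().items()
        },
    }
    if extra:
        report.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
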