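"""End-to-end orchestration of the affinity and isonymy pipelines."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from isonymica import affinity as aff
from isonymica import communities as comm
from isonymica import isonymy as iso
from isonymica import registry as reg
from isonymica import skeleton as skel
from isonymica import synthetic_city as synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "prepare_records", "run_affinity_pipeline", "run_isonymy_pipeline"]


@dataclass
class RunConfig:
    """Parameters for a full run; defaults follow the reference analysis."""

    input_path: str | None = None
    city: synth.CityConfig | None = None
    # affinity stage
    k: float = 100.0
    k_core_min: int = 3
    affinity_runs: int = 10
    # isonymy stage
    nx: int = 64
    ny: int = 64
    min_count: int = 50
    metric: str = "euclid"
    n_iter: int = 250
    aggregate: int = 20
    isonymy_runs: int = 10
    grid_extent: tuple[float, float, float, float] | None = None
    # global
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if "city" in data and data["city"] is not None:
            data["city"] = synth.CityConfig(**data["city"])
        if data.get("grid_extent") is not None:
            data["grid_extent"] = tuple(data["grid_extent"])
        return cls(**data)


def _stage(name: str):
    """Decorator: re-raise stage failures with the stage name attached."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def _seed_for(master: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the master seed."""
    ss = np.random.SeedSequence([master, abs(hash(stage)) % (2**31)])
    return int(ss.generate_state(1)[0])


def prepare_records(config: RunConfig) -> pd.DataFrame:
    """Load or synthesize records and attach person-level SES."""
    if config.input_path is not None:
        records = reg.read_records(config.input_path)
    elif config.city is not None:
        records = synth.generate_city(config.city)
    else:
        raise ValueError("RunConfig needs an input_path or a city config")
    if "ses" not in records.columns:
        if "block_income" not in records.columns:
            raise ValueError("records lack both 'ses' and 'block_income'")
        block_income = records.groupby("block_id")["block_income"].first()
        ses = reg.normalize_ses(block_income)
        records = reg.assign_person_ses(records, ses)
    return records


def run_affinity_pipeline(config: RunConfig, records: pd.DataFrame | None = None) -> dict:
    """records -> pair counts -> affinity filter -> core -> consensus communities."""
    if records is None:
        records = _stage("read")(prepare_records)(config)

    graph = _stage("count_pairs")(aff.count_pairs)(records)
    filtered = _stage("affinity_filter")(aff.affinity_filter)(graph, k=config.k)
    core = _stage("k_core")(aff.k_core)(filtered, k_core_min=config.k_core_min)
    if core.number_of_nodes() == 0:
        raise RuntimeError("stage 'k_core' failed: core is empty; lower k or k_core_min")
    partition = _stage("detect_consensus")(comm.detect_consensus)(
        core, n_runs=config.affinity_runs, seed=_seed_for(config.seed, "affinity-louvain")
    )
    ses_by_surname = _stage("surname_ses")(aff.surname_ses)(records)
    report = {
        "n_persons": int(len(records)),
        "stages": {
            "raw": {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()},
            "filtered": {"nodes": filtered.number_of_nodes(), "edges": filtered.number_of_edges()},
            "core": {"nodes": core.number_of_nodes(), "edges": core.number_of_edges()},
        },
        "n_communities": partition.n_communities,
        "modularity": partition.modularity,
        "modularity_range": partition.modularity_range,
        "cluster_ses": comm.cluster_ses(partition, ses_by_surname),
        "top_degree_surnames": comm.top_degree_surnames(partition, core),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aff.write_edgelist(core, out / "affinity_core_edges.csv")
        aff.write_graphml(core, out / "affinity_core.graphml")
        partition.write(out / "affinity_partition.csv", out / "affinity_partition.json")
        (out / "affinity_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report, partition, core


def run_isonymy_pipeline(config: RunConfig, records: pd.DataFrame | None = None) -> dict:
    """records -> grid -> distances -> MMST skeleton -> consensus communities."""
    if records is None:
        records = _stage("read")(prepare_records)(config)

    extent = config.grid_extent
    if extent is None and config.city is not None:
        extent = config.city.grid_extent
    if extent is None:
        extent = (
            float(records["x"].min()), float(records["x"].max()),
            float(records["y"].min()), float(records["y"].max()),
        )

    cells = _stage("grid_bin")(iso.grid_bin)(
        records, extent, nx=config.nx, ny=config.ny, min_count=config.min_count
    )
    if len(cells.cells) < 2:
        raise RuntimeError("stage 'grid_bin' failed: fewer than 2 retained cells")

    matrices = {
        m: _stage("distance_matrix")(iso.distance_matrix)(cells, metric=m)
        for m in iso.METRICS
    }
    separability = {}
    for m, dmat in matrices.items():
        try:
            separability[m] = iso.separability_report(
                dmat, seed=_seed_for(config.seed, f"gmm-{m}")
            )
        except ValueError as exc:
            separability[m] = {"error": str(exc)}

    dm = matrices[config.metric]
    run = _stage("mmst")(skel.mmst)(dm, n_iter=config.n_iter)
    depth = min(config.aggregate, len(run.trees))
    skeleton_graph = run.aggregate(depth)
    stats = skel.network_stats(skeleton_graph)
    partition = _stage("detect_consensus")(comm.detect_consensus)(
        skeleton_graph, n_runs=config.isonymy_runs,
        seed=_seed_for(config.seed, "isonymy-louvain"), weight=None,
    )

    alphas = cells.alphas()
    alpha_by_comm = {
        c: float(np.mean([alphas[cell] for cell in members]))
        for c, members in partition.communities().items()
    }
    report = {
        "n_persons": int(len(records)),
        "n_candidate_cells": cells.n_candidate_cells,
        "n_retained_cells": len(cells.cells),
        "separability": separability,
        "n_trees": len(run.trees),
        "aggregate_depth": depth,
        "skeleton": stats,
        "n_communities": partition.n_communities,
        "modularity": partition.modularity,
        "modularity_range": partition.modularity_range,
        "alpha_by_community": alpha_by_comm,
        "alpha_ses_correlation": iso.alpha_ses_correlation(cells)
        if cells.mean_ses and len(cells.mean_ses) >= 3 else None,
        "salient_surnames": comm.salient_surnames(cells, partition),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells.write(out / "cell_frequencies.csv", out / "cell_summary.csv")
        for m, dmat in matrices.items():
            dmat.write(out / f"distance_{m}.csv", out / f"distance_{m}.json")
        skel.write_skeleton(skeleton_graph, out / "skeleton_edges.csv", out / "skeleton.graphml")
        skel.write_d_series(run, out / "d_values.csv")
        partition.write(out / "isonymy_partition.csv", out / "isonymy_partition.json")
        (out / "isonymy_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report, partition, cells, run
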