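"""File formats, configuration I/O and the synthetic fixture generator.

Graph snapshots travel as two CSV tables (``nodes.csv``:
``id,x_um,y_um,birth_h,class,provenance``; ``edges.csv``:
``a,b,branch_type``) or one JSON document with the same fields; columns
carry their units in the header and parsers reject unit-less files.
Trajectories are directories holding the config, an events log, the
apex-position snapshots and the final graph.  All formats are plain
text and round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .branching import BranchEvent
from .graph import NetworkGraph
from .laws import exp2
from .params import GrowthConfig

__all__ = [
    "SchemaError",
    "read_graph",
    "write_graph",
    "read_trajectory",
    "write_trajectory",
    "read_config",
    "write_config",
    "read_events",
    "write_events",
    "SnapshotSeries",
    "FixtureSpec",
    "generate_fixture",
]

NODE_COLUMNS = ["id", "x_um", "y_um", "birth_h", "class", "provenance"]
EDGE_COLUMNS = ["a", "b", "branch_type"]
EVENT_COLUMNS = [
    "type", "time_h", "x_um", "y_um", "L_lat_um", "L_hypha_um", "side",
    "side_vs_curvature", "hypha_id", "arclength_um", "spacing_um",
]


class SchemaError(ValueError):
    """A table is missing required (unit-annotated) columns or has
    dangling references; the offending row is named when known."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s) {missing}; "
                          f"columns must carry units (e.g. x_um, birth_h)")


# ---------------------------------------------------------------------------
# graphs


def _graph_frames(graph: NetworkGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    cls = graph.vertex_class
    nodes = pd.DataFrame({
        "id": graph.node_ids,
        "x_um": graph.xy[:, 0],
        "y_um": graph.xy[:, 1],
        "birth_h": graph.birth_h,
        "class": cls if cls is not None and len(cls) == graph.n_nodes
        else [""] * graph.n_nodes,
        "provenance": graph.provenance,
    })
    edges = pd.DataFrame({
        "a": graph.edges[:, 0] if graph.n_edges else np.array([], dtype=np.int64),
        "b": graph.edges[:, 1] if graph.n_edges else np.array([], dtype=np.int64),
        "branch_type": graph.branch_type,
    })
    return nodes, edges


def write_graph(graph: NetworkGraph, path: str | Path) -> None:
    """Write a graph snapshot to ``path``.

    A ``.json`` suffix produces a single JSON document; anything else is
    treated as a directory receiving ``nodes.csv`` and ``edges.csv``.
    """
    path = Path(path)
    nodes, edges = _graph_frames(graph)
    if path.suffix == ".json":
        doc = {
            "snapshot_time_h": graph.snapshot_time,
            "nodes": nodes.to_dict(orient="records"),
            "edges": edges.to_dict(orient="records"),
        }
        path.write_text(json.dumps(doc))
    else:
        path.mkdir(parents=True, exist_ok=True)
        nodes.to_csv(path / "nodes.csv", index=False)
        edges.to_csv(path / "edges.csv", index=False)
        (path / "meta.json").write_text(
            json.dumps({"snapshot_time_h": graph.snapshot_time}))


def _graph_from_frames(nodes: pd.DataFrame, edges: pd.DataFrame,
                       snapshot_time: float) -> NetworkGraph:
    _check_columns(nodes, NODE_COLUMNS[:4], "nodes")
    _check_columns(edges, EDGE_COLUMNS[:2], "edges")
    ids = set(int(i) for i in nodes["id"])
    for row, (a, b) in enumerate(zip(edges["a"], edges["b"])):
        if int(a) not in ids or int(b) not in ids:
            raise SchemaError(f"edges row {row}: edge ({a}, {b}) references "
                              "a node that is not in the nodes table")
    prov = (nodes["provenance"].fillna("unknown").astype(str).to_numpy(dtype=object)
            if "provenance" in nodes else
            np.array(["unknown"] * len(nodes), dtype=object))
    cls = (nodes["class"].fillna("").astype(str).to_numpy(dtype=object)
           if "class" in nodes else None)
    bt = (edges["branch_type"].fillna("unknown").astype(str).to_numpy(dtype=object)
          if "branch_type" in edges else
          np.array(["unknown"] * len(edges), dtype=object))
    return NetworkGraph(
        node_ids=nodes["id"].to_numpy(dtype=np.int64),
        xy=nodes[["x_um", "y_um"]].to_numpy(dtype=float),
        birth_h=nodes["birth_h"].to_numpy(dtype=float),
        provenance=prov,
        edges=(np.column_stack([edges["a"].to_numpy(dtype=np.int64),
                                edges["b"].to_numpy(dtype=np.int64)])
               if len(edges) else np.empty((0, 2), dtype=np.int64)),
        branch_type=bt,
        snapshot_time=snapshot_time,
        vertex_class=cls,
    )


def read_graph(path: str | Path) -> NetworkGraph:
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        nodes = pd.DataFrame(doc["nodes"], columns=NODE_COLUMNS)
        edges = pd.DataFrame(doc["edges"], columns=EDGE_COLUMNS)
        t = float(doc.get("snapshot_time_h", 0.0))
    else:
        nodes = pd.read_csv(path / "nodes.csv")
        edges = pd.read_csv(path / "edges.csv")
        meta = path / "meta.json"
        t = (json.loads(meta.read_text()).get("snapshot_time_h", 0.0)
             if meta.exists() else 0.0)
    graph = _graph_from_frames(nodes, edges, t)
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# events and trajectories


def write_events(events: list[BranchEvent], path: str | Path) -> None:
    rows = [dataclasses.asdict(ev) for ev in events]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list[BranchEvent]:
    df = pd.read_csv(path)
    _check_columns(df, EVENT_COLUMNS[:8], "events")
    out = []
    for rec in df.to_dict(orient="records"):
        rec = {k: rec.get(k) for k in EVENT_COLUMNS}
        rec["hypha_id"] = int(rec.get("hypha_id", -1))
        for k in ("arclength_um", "spacing_um"):
            v = rec.get(k)
            rec[k] = float("nan") if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        out.append(BranchEvent(**rec))
    return out


@dataclass
class SnapshotSeries:
    """Trajectory read back from disk: enough to re-run every measurement."""

    config: GrowthConfig | None
    times: np.ndarray
    apex_xy: list[np.ndarray]
    events: list[BranchEvent]
    graph_dir: Path | None = None

    @property
    def n1(self) -> np.ndarray:
        return np.array([len(p) for p in self.apex_xy], dtype=np.int64)

    def snapshots(self) -> Iterator[tuple[float, np.ndarray]]:
        yield from zip(self.times, self.apex_xy)

    @property
    def final_graph(self) -> NetworkGraph:
        if self.graph_dir is None:
            raise FileNotFoundError("no final graph stored with this trajectory")
        return read_graph(self.graph_dir)


def write_trajectory(traj, out_dir: str | Path) -> None:
    """Write a trajectory directory: config.yaml, events.csv,
    snapshots.csv (t_h, apex_id, x_um, y_um) and the final graph."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if traj.config is not None:
        write_config(traj.config, out / "config.yaml")
    write_events(traj.events, out / "events.csv")
    rows = []
    for t, pts in traj.snapshots():
        for k, (x, y) in enumerate(np.asarray(pts).reshape(-1, 2)):
            rows.append((t, k, x, y))
    pd.DataFrame(rows, columns=["t_h", "apex_id", "x_um", "y_um"]).to_csv(
        out / "snapshots.csv", index=False)
    graph = getattr(traj, "final_graph", None)
    if graph is not None:
        write_graph(graph, out / "graph")


def read_trajectory(in_dir: str | Path) -> SnapshotSeries:
    src = Path(in_dir)
    snaps = pd.read_csv(src / "snapshots.csv")
    _check_columns(snaps, ["t_h", "x_um", "y_um"], "snapshots")
    times = []
    apex_xy = []
    for t, grp in snaps.groupby("t_h", sort=True):
        times.append(float(t))
        apex_xy.append(grp[["x_um", "y_um"]].to_numpy(dtype=float))
    cfg_path = src / "config.yaml"
    cfg = read_config(cfg_path) if cfg_path.exists() else None
    ev_path = src / "events.csv"
    events = read_events(ev_path) if ev_path.exists() else []
    gdir = src / "graph"
    return SnapshotSeries(config=cfg, times=np.array(times), apex_xy=apex_xy,
                          events=events,
                          graph_dir=gdir if gdir.exists() else None)


# ---------------------------------------------------------------------------
# config


def write_config(config: GrowthConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path: str | Path) -> GrowthConfig:
    d = yaml.safe_load(Path(path).read_text())
    return GrowthConfig.from_dict(d)


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class FixtureSpec:
    """Recipe for a deterministic synthetic dataset.

    ``kind`` selects the generator; ``params`` are its keyword
    arguments; a fixed ``seed`` makes the output byte-identical.
    """

    kind: str
    params: dict
    seed: int = 0

    KINDS = ("point_cloud", "toy_graph", "count_series",
             "branching_samples", "mixture_samples")


def generate_fixture(spec: FixtureSpec, out: str | Path | None = None):
    """Generate a synthetic dataset from a :class:`FixtureSpec`.

    Returns the in-memory object; when ``out`` is given the dataset is
    also written as CSV (graphs as a snapshot directory).
    """
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    if spec.kind == "point_cloud":
        data = _point_cloud(rng, **p)
        frame = pd.DataFrame(data, columns=["x_um", "y_um"])
    elif spec.kind == "count_series":
        data = _count_series(rng, **p)
        frame = pd.DataFrame({"t_h": data[0], "count": data[1]})
    elif spec.kind == "branching_samples":
        data = _branching_samples(rng, **p)
        frame = pd.DataFrame({"L_um": data})
    elif spec.kind == "mixture_samples":
        data = _mixture_samples(rng, **p)
        frame = pd.DataFrame({"dL_um": data})
    elif spec.kind == "toy_graph":
        data = _toy_graph(**p)
        if out is not None:
            write_graph(data, out)
        return data
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    if out is not None:
        frame.to_csv(out, index=False)
    return data


def _point_cloud(rng, lambda1: float = 2.0, lambda2: float = 0.5,
                 n: int = 1000, angle_rad: float = 0.0,
                 center=(0.0, 0.0)) -> np.ndarray:
    """Gaussian cloud whose population inertia eigenvalues are λ1, λ2."""
    pts = rng.normal(size=(n, 2)) * np.sqrt([lambda1, lambda2])
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T + np.asarray(center, dtype=float)


def _count_series(rng, C: float = 4.0, omega: float = 0.48,
                  t_end_h: float = 15.0, cadence_h: float = 0.3,
                  poisson: bool = True):
    t = np.arange(cadence_h, t_end_h + 1e-9, cadence_h)
    mean = C * 2.0 ** (omega * t)
    y = rng.poisson(mean).astype(float) if poisson else mean
    return t, np.maximum(y, 1.0)


def _branching_samples(rng, L0: float = 180.0, alpha: float = 10.4e-3,
                       n: int = 10_000) -> np.ndarray:
    return L0 + exp2(rng, alpha, size=n)


def _mixture_samples(rng, gamma1: float = 2.3e-3, uniform_fraction: float = 0.22,
                     spatial_range_um: float = 5000.0, n: int = 10_000) -> np.ndarray:
    dl = exp2(rng, gamma1, size=n)
    isolated = rng.random(n) < uniform_fraction
    dl[isolated] = rng.uniform(0.0, spatial_range_um, size=int(isolated.sum()))
    return dl


def _toy_graph(shape: str = "Y") -> NetworkGraph:
    if shape == "Y":
        nodes = [(0, 0.0, 0.0, 0.0, "", "germination"),
                 (1, 0.0, 100.0, 1.0, "", "apical"),
                 (2, -60.0, 180.0, 2.0, "", "operating"),
                 (3, 60.0, 180.0, 2.0, "", "exploratory")]
        edges = [(0, 1, "germination"), (1, 2, "operating"),
                 (1, 3, "exploratory")]
    elif shape == "X":
        nodes = [(0, -1.0, -1.0, 0.0, "", "germination"),
                 (1, 1.0, 1.0, 0.0, "", "germination"),
                 (2, -1.0, 1.0, 0.0, "", "germination"),
                 (3, 1.0, -1.0, 0.0, "", "germination")]
        edges = [(0, 1, "germination"), (2, 3, "germination")]
    elif shape == "filament":
        nodes = [(0, 0.0, 0.0, 0.0, "", "germination"),
                 (1, 100.0, 0.0, 1.0, "", "germination")]
        edges = [(0, 1, "germination")]
    else:
        raise ValueError(f"unknown toy graph shape {shape!r}")
    return NetworkGraph.from_records(nodes, edges, snapshot_time=2.0)


# ensure a fixed seed reproduces files byte-for-byte
def fixture_bytes(spec: FixtureSpec) -> bytes:
    import io as _io

    buf = _io.StringIO()
    data = generate_fixture(spec)
    if spec.kind == "toy_graph":
        nodes, edges = _graph_frames(data)
        nodes.to_csv(buf, index=False)
        edges.to_csv(buf, index=False)
    elif spec.kind == "count_series":
        pd.DataFrame({"t_h": data[0], "count": data[1]}).to_csv(buf, index=False)
    elif spec.kind == "point_cloud":
        pd.DataFrame(data, columns=["x_um", "y_um"]).to_csv(buf, index=False)
    else:
        pd.DataFrame({"value": np.asarray(data)}).to_csv(buf, index=False)
    return buf.getvalue().encode()
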