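"""File formats: the grid dialects and analysis exports.

Two self-describing on-disk dialects carry a completed grid:

grid-csv::

    # scale: 1 7
    left_pole,right_pole,H1,...,Hn,ideal
    Sick,Healthy,6,7,6,6,6,7
    ...

Row *j*, column ``Hi`` holds the rating of construct *j* under scenario
*i*; the diagonal cell is the Self-Now rating.  grid-json stores the same
fields as a JSON object.  Both round-trip integer grids bit-exactly.

Analysis outputs are plain CSV (weight matrices with construct labels as
header row/column, degree/PB/IF tables, long-format trajectories) plus
GraphML and DOT for the construct graph.  Floats are written with 12
significant digits.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .grid import Construct, RatingScale, RawWimpGrid
from .dynamics import Trajectory

__all__ = [
    "read_grid",
    "write_grid",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_graphml",
    "write_dot",
    "write_trajectory_csv",
    "load_config",
    "GridParseError",
]

FLOAT_FMT = "%.12g"


class GridParseError(ValueError):
    """Malformed grid file; the message carries the line number where known."""


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("grid-csv", "grid-json"):
            raise ValueError(f"unknown grid format {fmt!r}")
        return fmt
    return "grid-json" if path.suffix.lower() == ".json" else "grid-csv"


def read_grid(path, fmt: str | None = None) -> RawWimpGrid:
    """Parse a grid file (format inferred from the extension unless given)."""
    path = Path(path)
    if _detect_format(path, fmt) == "grid-json":
        return _read_grid_json(path)
    return _read_grid_csv(path)


def write_grid(g: RawWimpGrid, path, fmt: str | None = None) -> None:
    path = Path(path)
    if _detect_format(path, fmt) == "grid-json":
        _write_grid_json(g, path)
    else:
        _write_grid_csv(g, path)


def _read_grid_csv(path: Path) -> RawWimpGrid:
    with open(path, encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.startswith("# scale:"):
            raise GridParseError(f"{path}:1: expected '# scale: r_min r_max' header line")
        parts = first[len("# scale:"):].split()
        if len(parts) != 2:
            raise GridParseError(f"{path}:1: malformed scale header {first.strip()!r}")
        try:
            scale = RatingScale(int(parts[0]), int(parts[1]))
        except ValueError as e:
            raise GridParseError(f"{path}:1: {e}") from e
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GridParseError(f"{path}:2: missing column header") from None
        rows = [r for r in reader if r]
    n = len(header) - 3
    expected = ["left_pole", "right_pole"] + [f"H{i+1}" for i in range(n)] + ["ideal"]
    if n < 1 or header != expected:
        raise GridParseError(f"{path}:2: bad column header (want left_pole,right_pole,H1..Hn,ideal)")
    if len(rows) != n:
        raise GridParseError(f"{path}: expected {n} construct rows, found {len(rows)}")
    constructs, hyp, ideal = [], [], []
    for lineno, row in enumerate(rows, start=3):
        if len(row) != n + 3:
            raise GridParseError(f"{path}:{lineno}: expected {n + 3} fields, found {len(row)}")
        constructs.append(Construct(row[0], row[1]))
        try:
            hyp.append([int(v) for v in row[2:-1]])
            ideal.append(int(row[-1]))
        except ValueError as e:
            raise GridParseError(f"{path}:{lineno}: non-integer rating") from e
    return RawWimpGrid(
        scale=scale, constructs=tuple(constructs), hyp=np.array(hyp), ideal=np.array(ideal)
    )


def _write_grid_csv(g: RawWimpGrid, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# scale: {g.scale.r_min} {g.scale.r_max}\n")
        w = csv.writer(fh)
        w.writerow(["left_pole", "right_pole"] + [f"H{i+1}" for i in range(g.n)] + ["ideal"])
        for j, c in enumerate(g.constructs):
            w.writerow(
                [c.left_pole, c.right_pole]
                + [int(v) for v in g.hyp[j]]
                + [int(g.ideal[j])]
            )


def _read_grid_json(path: Path) -> RawWimpGrid:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise GridParseError(f"{path}:{e.lineno}: {e.msg}") from e
    try:
        scale = RatingScale(int(doc["scale"]["r_min"]), int(doc["scale"]["r_max"]))
        constructs = tuple(
            Construct(c["left_pole"], c["right_pole"]) for c in doc["constructs"]
        )
        hyp = np.array(doc["hyp"], dtype=int)
        ideal = np.array(doc["ideal"], dtype=int)
    except (KeyError, TypeError, ValueError) as e:
        raise GridParseError(f"{path}: malformed grid document ({e})") from e
    return RawWimpGrid(scale=scale, constructs=constructs, hyp=hyp, ideal=ideal)


def _write_grid_json(g: RawWimpGrid, path: Path) -> None:
    doc = {
        "format": "wimpgrid",
        "scale": {"r_min": g.scale.r_min, "r_max": g.scale.r_max},
        "constructs": [
            {"left_pole": c.left_pole, "right_pole": c.right_pole} for c in g.constructs
        ],
        "hyp": [[int(v) for v in row] for row in g.hyp],
        "ideal": [int(v) for v in g.ideal],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, ensure_ascii=False)
        fh.write("\n")


def write_matrix_csv(W: np.ndarray, labels: list[str], path) -> None:
    """Square matrix as CSV with construct labels as header row and column."""
    pd.DataFrame(W, index=labels, columns=labels).to_csv(path, float_format=FLOAT_FMT)


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_graphml(G: nx.DiGraph, path) -> None:
    nx.write_graphml(G, path)


def write_dot(G: nx.DiGraph, path) -> None:
    """Minimal DOT serialization of the construct graph with its node and
    edge attributes (quoted and escaped; no styling)."""

    def q(v) -> str:
        s = f"{v:.12g}" if isinstance(v, float) else str(v)
        return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("digraph wimpgrid {\n")
        for node, attrs in G.nodes(data=True):
            alist = ", ".join(f"{k}={q(v)}" for k, v in attrs.items())
            fh.write(f"  {node} [{alist}];\n")
        for u, v, attrs in G.edges(data=True):
            alist = ", ".join(f"{k}={q(val)}" for k, val in attrs.items())
            fh.write(f"  {u} -> {v} [{alist}];\n")
        fh.write("}\n")


def write_trajectory_csv(traj: Trajectory, path, wide: bool = False) -> None:
    """Long-format (step, construct, state, delta, activation) CSV; with
    ``wide=True`` one state column per construct instead."""
    df = traj.to_frame()
    if wide:
        df = df.pivot(index="step", columns="construct", values="state")
        df.to_csv(path, float_format=FLOAT_FMT)
    else:
        df.to_csv(path, index=False, float_format=FLOAT_FMT)


#: Config keys understood by the CLI, with defaults.
CONFIG_DEFAULTS = {
    "pb_factor": float(1.0 / np.sqrt(2.0)),
    "degree_mode": "absolute",
    "edge_threshold": 0.0,
    "lambda": 0.1,
    "tol": 1e-6,
    "max_steps": 50,
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Key-value config (YAML) mirroring the CLI flags; unknown keys rejected."""
    cfg = dict(CONFIG_DEFAULTS)
    if path is None:
        return cfg
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    unknown = set(user) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg.update(user)
    return cfg
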