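"""Plain-text readers and writers for the package's data formats.

Formats (all delimited text, loss-free round trips):

* edge list — one ``i j`` pair per line, 1-based node indices, ``#`` comments;
* series — tab-separated, header ``ch1..chP``, one time point per row, with
  the sampling rate recorded on a leading ``# sampling_rate_hz=...`` line;
* distance matrix — square tab-separated numeric matrix with channel header;
* persistence diagram — three columns ``dim birth death`` with an ``inf``
  token for essential classes.

A compact binary container (`.npz`) is offered for large simulation runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .graphs import DependenceGraph
from .mixing import MultivariateSeries
from .persistence import PersistenceDiagram

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_series",
    "read_series",
    "write_series_npz",
    "read_series_npz",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_diagram",
    "read_diagram",
]


def write_edge_list(g: DependenceGraph, path: str | Path) -> None:
    lines = [f"# nodes={g.n_nodes}"]
    lines += [f"{i + 1} {j + 1}" for i, j in g.edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> DependenceGraph:
    n_nodes = None
    edges = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("nodes="):
                n_nodes = int(body.split("=", 1)[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed edge line: {raw!r}")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        edges.append((i, j))
    if not edges:
        raise ValueError(f"no edges found in {path}")
    if n_nodes is None:
        n_nodes = max(max(e) for e in edges) + 1
    return DependenceGraph(n_nodes=n_nodes, edges=tuple(edges))


def write_series(y: MultivariateSeries, path: str | Path) -> None:
    header = "\t".join(f"ch{p + 1}" for p in range(y.n_channels))
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={y.sampling_rate_hz!r}\n")
        fh.write(header + "\n")
        np.savetxt(fh, y.y, fmt="%.10g", delimiter="\t")


def read_series(path: str | Path) -> MultivariateSeries:
    sr = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "sampling_rate_hz=" in first:
            sr = float(first.split("=", 1)[1])
            header = fh.readline()
        else:
            header = first
        if not header.strip().startswith("ch"):
            raise ValueError(f"missing channel header in {path}")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.size == 0:
        raise ValueError(f"no data rows in {path}")
    if sr is None:
        raise ValueError(f"missing '# sampling_rate_hz=' line in {path}")
    return MultivariateSeries(y=data, sampling_rate_hz=sr)


def write_series_npz(y: MultivariateSeries, path: str | Path) -> None:
    np.savez_compressed(path, y=y.y, sampling_rate_hz=y.sampling_rate_hz)


def read_series_npz(path: str | Path) -> MultivariateSeries:
    with np.load(path) as z:
        return MultivariateSeries(y=z["y"], sampling_rate_hz=float(z["sampling_rate_hz"]))


def write_distance_matrix(D: np.ndarray, path: str | Path) -> None:
    D = np.asarray(D, dtype=float)
    header = "\t".join(f"ch{p + 1}" for p in range(D.shape[1]))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, D, fmt="%.12g", delimiter="\t")


def read_distance_matrix(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline()
        if not header.strip().startswith("ch"):
            raise ValueError(f"missing channel header in {path}")
        d = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if d.size == 0 or d.shape[0] != d.shape[1]:
        raise ValueError(f"not a square matrix: {path}")
    return d


def write_diagram(pd: PersistenceDiagram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("dim\tbirth\tdeath\n")
        for d, b, dd in zip(pd.dims, pd.births, pd.deaths):
            death = "inf" if np.isinf(dd) else f"{dd:.12g}"
            fh.write(f"{int(d)}\t{b:.12g}\t{death}\n")


def read_diagram(path: str | Path) -> PersistenceDiagram:
    dims, births, deaths = [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("dim"):
            raise ValueError(f"missing diagram header in {path}")
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            d, b, dd = line.split("\t")
            dims.append(int(d))
            births.append(float(b))
            deaths.append(np.inf if dd == "inf" else float(dd))
    return PersistenceDiagram(
        dims=np.asarray(dims, dtype=int),
        births=np.asarray(births, dtype=float),
        deaths=np.asarray(deaths, dtype=float),
    )
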