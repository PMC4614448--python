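"""Delimited-text readers and writers.

All formats are plain UTF-8 text: multichannel series as CSV/TSV (rows
= time, columns = channels, optional header of channel labels), graphs
as tab-separated edge lists (0-based, ``i < j``, lexicographically
sorted), multiplexes as one edge list per layer plus a manifest or as a
combined ``layer<TAB>i<TAB>j`` file, and metric reports as key/value
tables.  Floats are serialized with 17 significant digits so that a
write/read round trip is exact.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .hvg import VisibilityGraph
from .multiplex import MultiplexVisibilityGraph
from .series import MultivariateSeries

__all__ = [
    "read_multivariate",
    "write_multivariate",
    "write_edge_list",
    "read_edge_list",
    "write_adjacency_matrix",
    "write_multiplex",
    "read_multiplex",
    "write_weighted_edge_list",
    "write_metrics",
]

_FLOAT_FMT = "%.17g"


def read_multivariate(path, delimiter=None) -> MultivariateSeries:
    """Read a rectangular numeric table; columns become channels.

    The delimiter is sniffed (comma/tab/semicolon/whitespace) unless
    given.  A header row of labels is detected automatically.  Ragged
    rows, non-numeric cells and NaNs are rejected with the offending
    row named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        sample = path.open().read(8192)
        try:
            delimiter = csv.Sniffer().sniff(sample, delimiters=",\t; ").delimiter
        except csv.Error:
            delimiter = ","

    def _read(header):
        return pd.read_csv(path, sep=delimiter, header=header,
                           float_precision="round_trip")

    try:
        frame = _read("infer")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    # a numeric "header" means the file had none: re-read with labels s0..s{M-1}
    try:
        [float(c) for c in frame.columns]
    except (TypeError, ValueError):
        pass
    else:
        frame = _read(None)
        frame.columns = [f"s{j}" for j in range(frame.shape[1])]
    body = frame.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & ~frame.isna()
    if bad.to_numpy().any():
        r = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(f"{path}: non-numeric cell at data row {r}")
    if body.isna().to_numpy().any():
        r = int(np.nonzero(body.isna().to_numpy())[0][0])
        raise ValueError(f"{path}: missing value at data row {r}")
    return MultivariateSeries.from_dataframe(body)


def write_multivariate(series: MultivariateSeries, path, delimiter=",") -> None:
    series.to_dataframe().to_csv(path, sep=delimiter, index=False,
                                 float_format=_FLOAT_FMT)


def write_edge_list(graph: VisibilityGraph, path) -> None:
    """One ``i<TAB>j`` pair per line, 0-based, i < j, sorted."""
    np.savetxt(path, graph.edges, fmt="%d", delimiter="\t")


def read_edge_list(path, n_nodes=None) -> VisibilityGraph:
    edges = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    if n_nodes is None:
        n_nodes = int(edges.max()) + 1 if edges.size else 0
    return VisibilityGraph(n_nodes=n_nodes, edges=edges)


def write_adjacency_matrix(graph: VisibilityGraph, path, delimiter="\t") -> None:
    """N x N symmetric 0/1 matrix with zero diagonal."""
    np.savetxt(path, graph.adjacency_matrix(), fmt="%d", delimiter=delimiter)


def write_multiplex(mux: MultiplexVisibilityGraph, directory, combined=True) -> None:
    """Per-layer edge lists plus a ``manifest.tsv`` (label -> file) and,
    optionally, a combined ``layer<TAB>i<TAB>j`` file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["layer", "label", "n_nodes", "file"])
        for a, (layer, label) in enumerate(zip(mux.layers, mux.labels)):
            fname = f"layer_{a}.edges"
            write_edge_list(layer, directory / fname)
            writer.writerow([a, label, layer.n_nodes, fname])
    if combined:
        with open(directory / "multiplex.edges", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for a, layer in enumerate(mux.layers):
                for i, j in layer.edges:
                    writer.writerow([a, int(i), int(j)])


def read_multiplex(directory) -> MultiplexVisibilityGraph:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    layers, labels = [], []
    for _, row in manifest.iterrows():
        layers.append(read_edge_list(directory / row["file"], n_nodes=int(row["n_nodes"])))
        labels.append(str(row["label"]))
    return MultiplexVisibilityGraph(layers=tuple(layers), labels=tuple(labels))


def write_weighted_edge_list(g, path, delimiter="\t") -> None:
    """``alpha<TAB>beta<TAB>weight`` rows of a weighted graph (e.g. the
    graph of layers, its backbone or MST)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for u, v, w in sorted(g.edges(data="weight")):
            writer.writerow([u, v, _FLOAT_FMT % w])


def write_metrics(metrics: dict, path, delimiter="\t") -> None:
    """Flat key/value report; floats at full precision."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for key, value in metrics.items():
            if isinstance(value, float):
                value = _FLOAT_FMT % value
            writer.writerow([key, value])
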