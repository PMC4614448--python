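"""Windowed (temporal multiplex) analysis.

A long multichannel record is split into non-overlapping, contiguous
windows; each window yields one multiplex visibility graph snapshot,
and per-window coherence metrics (omega, I, MST hub statistics) form
time profiles whose peaks mark epochs of increased cross-channel
synchronisation — the structure used to scan long records for regime
changes.  A regime-switching lattice generator provides ground-truthed
synthetic input for validating that machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cml import CMLParams, _initial_state, _simulate
from .layers import graph_of_layers, hub_fraction, maximum_spanning_tree
from .multiplex import (
    average_edge_overlap,
    build_multiplex,
    mean_interlayer_mutual_information,
)
from .series import MultivariateSeries

__all__ = [
    "TemporalMultiplex",
    "windowed_multiplex",
    "temporal_profiles",
    "running_average",
    "make_regime_series",
]


@dataclass(frozen=True)
class TemporalMultiplex:
    """Ordered multiplex snapshots from contiguous non-overlapping
    windows ``[start, stop)`` of a common multichannel record."""

    snapshots: tuple
    window_bounds: tuple

    @property
    def n_windows(self) -> int:
        return len(self.snapshots)


def windowed_multiplex(series, window_length: int) -> TemporalMultiplex:
    """Split into ``floor(N / window_length)`` full windows (trailing
    remainder dropped) and build one multiplex per window."""
    if not isinstance(series, MultivariateSeries):
        series = MultivariateSeries(np.asarray(series, dtype=float))
    if window_length < 2:
        raise ValueError("window_length must be at least 2")
    n_windows = series.n_points // window_length
    if n_windows == 0:
        raise ValueError("series shorter than one window")
    snaps, bounds = [], []
    for w in range(n_windows):
        start, stop = w * window_length, (w + 1) * window_length
        snaps.append(build_multiplex(series.window(start, stop)))
        bounds.append((start, stop))
    return TemporalMultiplex(snapshots=tuple(snaps), window_bounds=tuple(bounds))


def temporal_profiles(tm: TemporalMultiplex, base=None) -> pd.DataFrame:
    """One row per window: omega, mean interlayer MI, and the MST hub
    fraction and total weight of the graph of layers."""
    rows = []
    for w, (mux, (start, stop)) in enumerate(zip(tm.snapshots, tm.window_bounds)):
        gol = graph_of_layers(mux, base=base)
        mst = maximum_spanning_tree(gol)
        rows.append(
            {
                "window": w,
                "start": start,
                "stop": stop,
                "omega": average_edge_overlap(mux),
                "mi": mean_interlayer_mutual_information(mux, base=base),
                "hub_fraction": hub_fraction(mst),
                "mst_weight": float(
                    sum(wt for *_, wt in mst.edges(data="weight"))
                ),
            }
        )
    return pd.DataFrame(rows)


def running_average(profile, half_width: int = 2) -> np.ndarray:
    """Centred moving mean with the window truncated at the ends;
    ``half_width=0`` is the identity."""
    x = np.asarray(profile, dtype=float)
    if half_width < 0:
        raise ValueError("half_width must be nonnegative")
    out = np.empty_like(x)
    n = x.size
    for i in range(n):
        lo, hi = max(0, i - half_width), min(n, i + half_width + 1)
        out[i] = x[lo:hi].mean()
    return out


def make_regime_series(segments, seed=None):
    """Concatenate lattice runs with piecewise-constant parameters.

    ``segments`` is a list of ``(CMLParams, length)`` pairs sharing the
    same lattice size; the dynamical state is carried across segment
    boundaries (only the first segment's transient is discarded), so
    the output is one continuous trajectory with parameter switches.
    Zero-length segments are skipped.

    Returns ``(series, labels)`` where ``labels[t]`` is the index of
    the segment that produced row ``t`` — the ground truth for
    regime-recovery tests.
    """
    segments = [(p, int(n)) for p, n in segments if int(n) > 0]
    if not segments:
        raise ValueError("need at least one segment of positive length")
    m = segments[0][0].n_sites
    if any(p.n_sites != m for p, _ in segments):
        raise ValueError("all segments must share the same number of sites")
    rng = np.random.default_rng(seed if seed is not None else segments[0][0].seed)
    state = _initial_state(segments[0][0], rng)
    chunks, labels = [], []
    for idx, (params, length) in enumerate(segments):
        p = replace(params, n_steps=length, transient=params.transient if idx == 0 else 0)
        traj = _simulate(p, x0=state)
        state = traj[-1]
        chunks.append(traj)
        labels.append(np.full(length, idx))
    return (
        MultivariateSeries(np.vstack(chunks)),
        np.concatenate(labels),
    )
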