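"""Fixed-partition symbolization baseline.

The comparison method: each channel is coarse-grained onto ``p``
equal-width bins of a stated range, and cross-channel structure is the
plug-in mutual information between the aligned symbol sequences,
averaged over channel pairs (``I^SYMB``).  The partition choice (range,
``p``, bin convention) is an explicit parameter precisely because the
method's sensitivity to it is its known weakness; bins are half-open
with the last bin closed at the upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multiplex import _mi_from_pairs
from .series import MultivariateSeries, as_values

__all__ = [
    "SymbolicSeries",
    "symbolize",
    "symbolic_mutual_information",
    "mean_symbolic_mutual_information",
]


@dataclass(frozen=True)
class SymbolicSeries:
    """Symbol sequence over the alphabet ``{0, ..., p-1}`` together
    with the partition that produced it."""

    symbols: np.ndarray
    p: int
    bounds: tuple

    def __len__(self):
        return self.symbols.size


def symbolize(series, p: int = 2, data_range=(0.0, 1.0)) -> SymbolicSeries:
    """Partition ``[lo, hi]`` into ``p`` equal subintervals and map each
    datum to its bin index.

    Bins are ``[lo + m*D, lo + (m+1)*D)`` for ``m < p-1`` and the last
    bin is closed at ``hi`` (``D = (hi-lo)/p``).  Data outside the range
    raise ``ValueError``.
    """
    x = as_values(series, min_length=1)
    if p < 2:
        raise ValueError("need at least p = 2 symbols")
    lo, hi = float(data_range[0]), float(data_range[1])
    if not lo < hi:
        raise ValueError("range must satisfy lo < hi")
    if np.any(x < lo) or np.any(x > hi):
        idx = int(np.flatnonzero((x < lo) | (x > hi))[0])
        raise ValueError(f"datum at index {idx} ({x[idx]!r}) outside range [{lo}, {hi}]")
    sym = np.minimum((np.floor((x - lo) / (hi - lo) * p)).astype(np.int64), p - 1)
    return SymbolicSeries(symbols=sym, p=p, bounds=(lo, hi))


def symbolic_mutual_information(a: SymbolicSeries, b: SymbolicSeries, base=None) -> float:
    """Plug-in MI of two aligned symbol sequences (0 log 0 := 0);
    bounded by log p."""
    if len(a) != len(b):
        raise ValueError("symbol sequences must have equal length")
    return _mi_from_pairs(a.symbols, b.symbols, base=base)


def mean_symbolic_mutual_information(
    series, p: int = 2, data_range=(0.0, 1.0), base=None
) -> float:
    """``I^SYMB``: mean pairwise symbolic MI over the M(M-1)/2 channel
    pairs after per-channel symbolization.

    ``data_range=None`` uses each channel's own [min, max] (the choice
    for empirical data whose state space is unknown); the default
    [0, 1] matches logistic-lattice state space.
    """
    if not isinstance(series, MultivariateSeries):
        series = MultivariateSeries(np.asarray(series, dtype=float))
    m = series.n_channels
    if m < 2:
        raise ValueError("need M >= 2 channels")
    seqs = []
    for j in range(m):
        col = series.values[:, j]
        rng = (col.min(), col.max()) if data_range is None else data_range
        seqs.append(symbolize(col, p=p, data_range=rng))
    vals = [
        symbolic_mutual_information(seqs[a], seqs[b], base=base)
        for a in range(m)
        for b in range(a + 1, m)
    ]
    return float(np.mean(vals))
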