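"""Containers for ordered real-valued signals.

A :class:`TimeSeries` is a single gapless, finite, ordered sequence of
reals — the object a visibility graph is built from.  A
:class:`MultivariateSeries` stacks ``M`` equal-length channels, one per
state variable of the underlying dynamical system; channel ``alpha``
becomes layer ``alpha`` of the multiplex visibility graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "MultivariateSeries", "as_values"]


def as_values(series, min_length: int = 2) -> np.ndarray:
    """Coerce a series-like object to a validated 1-D float array.

    Accepts a :class:`TimeSeries`, a pandas Series, or any 1-D
    array-like.  Raises ``ValueError`` on short input or non-finite
    entries (the offending index is named: visibility is undefined
    across gaps, so missing values must be handled upstream).
    """
    if isinstance(series, TimeSeries):
        values = series.values
    else:
        values = np.asarray(series, dtype=float)
    if values.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {values.shape}")
    if values.size < min_length:
        raise ValueError(
            f"series too short: need at least {min_length} points, got {values.size}"
        )
    bad = ~np.isfinite(values)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite value at index {idx}: {values[idx]!r}")
    return values


@dataclass(frozen=True)
class TimeSeries:
    """An ordered sequence of finite reals with a channel label."""

    values: np.ndarray
    label: str = "x"

    def __post_init__(self):
        object.__setattr__(self, "values", as_values(np.asarray(self.values, dtype=float)))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class MultivariateSeries:
    """``M`` equal-length channels over a shared 0-based time index.

    ``values`` has shape ``(N, M)``: rows are time points, columns are
    channels, matching the on-disk delimited-text layout.
    """

    values: np.ndarray
    labels: list[str] = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D (N, M) array, got shape {values.shape}")
        bad = ~np.isfinite(values)
        if bad.any():
            r, c = (int(v[0]) for v in np.nonzero(bad))
            raise ValueError(f"non-finite value at row {r}, column {c}")
        labels = self.labels
        if labels is None:
            labels = [f"s{j}" for j in range(values.shape[1])]
        labels = [str(l) for l in labels]
        if len(labels) != values.shape[1]:
            raise ValueError(
                f"{len(labels)} labels for {values.shape[1]} channels"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel(self, key) -> TimeSeries:
        """Extract one channel by integer position or label."""
        if isinstance(key, str):
            key = self.labels.index(key)
        return TimeSeries(self.values[:, key], label=self.labels[key])

    def window(self, start: int, stop: int) -> "MultivariateSeries":
        """Rows ``start:stop`` as a new series (all channels)."""
        return MultivariateSeries(self.values[start:stop], labels=list(self.labels))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "MultivariateSeries":
        return cls(frame.to_numpy(dtype=float), labels=[str(c) for c in frame.columns])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)
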