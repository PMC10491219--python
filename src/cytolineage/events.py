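"""Core in-memory containers for mass-cytometry event data.

The central object is :class:`EventMatrix`, an events x channels matrix of
ion-count-derived intensities plus per-event metadata (sample, batch, tissue,
anchor flag, and optional simulation ground truth).  Every transformation in
the pipeline consumes and returns an ``EventMatrix`` and updates its ``scale``
tag so that stages can assert they are operating on the scale they expect
(``raw`` ion counts, ``arcsinh`` transformed, or percentile ``scaled``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Recognized values of :attr:`EventMatrix.scale`.
SCALES = ("raw", "arcsinh", "scaled")

#: Metadata columns every EventMatrix must carry.
REQUIRED_META = ("sample_id", "batch_id", "tissue")


class EventMatrixError(ValueError):
    """Raised when an EventMatrix violates its invariants."""


@dataclass
class EventMatrix:
    """Events x channels expression values with aligned per-event metadata.

    Parameters
    ----------
    values
        Float array of shape ``(n_events, n_channels)``.  Must be finite.
    channels
        Channel (marker) names, unique, one per column.
    meta
        DataFrame with one row per event.  Must contain ``sample_id``,
        ``batch_id`` and ``tissue``; may carry ``is_anchor`` and simulation
        truth columns (``latent_time``, ``branch``, ``population``).
    scale
        One of ``raw``, ``arcsinh``, ``scaled``.
    """

    values: np.ndarray
    channels: list[str]
    meta: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.channels = list(self.channels)
        if self.values.ndim != 2:
            raise EventMatrixError("values must be a 2-D events x channels array")
        if len(self.channels) != self.values.shape[1]:
            raise EventMatrixError(
                f"{len(self.channels)} channel names for {self.values.shape[1]} columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise EventMatrixError("channel names must be unique")
        if len(self.meta) != self.values.shape[0]:
            raise EventMatrixError(
                f"metadata has {len(self.meta)} rows for {self.values.shape[0]} events"
            )
        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise EventMatrixError(f"metadata missing required columns: {missing}")
        if self.scale not in SCALES:
            raise EventMatrixError(f"unknown scale tag {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise EventMatrixError("values contain NaN or Inf")
        # normalize the index so row positions and labels agree
        self.meta = self.meta.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None

    def channel_values(self, channel: str) -> np.ndarray:
        return self.values[:, self.channel_index(channel)]

    # -- derivation ----------------------------------------------------------

    def copy(self) -> "EventMatrix":
        return EventMatrix(
            self.values.copy(), list(self.channels), self.meta.copy(), self.scale
        )

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "EventMatrix":
        """Return a new EventMatrix sharing metadata but with new values."""
        return EventMatrix(values, list(self.channels), self.meta.copy(),
                           self.scale if scale is None else scale)

    def subset_rows(self, rows: np.ndarray | Sequence[int]) -> "EventMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return EventMatrix(
            self.values[rows], list(self.channels),
            self.meta.iloc[rows].reset_index(drop=True), self.scale,
        )

    def select_channels(self, channels: Iterable[str]) -> "EventMatrix":
        channels = list(channels)
        idx = [self.channel_index(c) for c in channels]
        return EventMatrix(self.values[:, idx], channels, self.meta.copy(), self.scale)

    def to_frame(self) -> pd.DataFrame:
        """Expression values joined with metadata, one row per event."""
        expr = pd.DataFrame(self.values, columns=self.channels)
        return pd.concat([expr, self.meta.reset_index(drop=True)], axis=1)


def concat_events(parts: Sequence[EventMatrix]) -> EventMatrix:
    """Concatenate EventMatrix objects sharing channel sets and scale.

    Channel order is harmonized to the first part's order.
    """
    if not parts:
        raise EventMatrixError("nothing to concatenate")
    ref = parts[0]
    for p in parts[1:]:
        if set(p.channels) != set(ref.channels):
            raise EventMatrixError("channel sets differ across parts")
        if p.scale != ref.scale:
            raise EventMatrixError("scale tags differ across parts")
    aligned = [p.select_channels(ref.channels) for p in parts]
    values = np.vstack([p.values for p in aligned])
    meta = pd.concat([p.meta for p in aligned], ignore_index=True)
    return EventMatrix(values, list(ref.channels), meta, ref.scale)


@dataclass
class PanelDef:
    """Panel definition: marker class and analysis-inclusion flags per channel.

    ``table`` columns: ``marker`` (unique), ``marker_class`` in
    {surface, regulator, utility}, ``use_clustering`` (bool), and one boolean
    ``traj_<lineage>`` column per named trajectory subset.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "marker_class", "use_clustering"}
        missing = required - set(self.table.columns)
        if missing:
            raise EventMatrixError(f"panel table missing columns: {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            raise EventMatrixError("panel marker names must be unique")
        bad = set(self.table["marker_class"]) - {"surface", "regulator", "utility"}
        if bad:
            raise EventMatrixError(f"unknown marker classes: {sorted(bad)}")
        if not self.table["use_clustering"].any():
            raise EventMatrixError("panel must flag at least one clustering channel")

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    def clustering_channels(self) -> list[str]:
        return list(self.table.loc[self.table["use_clustering"], "marker"])

    def trajectory_channels(self, lineage: str) -> list[str]:
        col = f"traj_{lineage}"
        if col not in self.table.columns:
            raise KeyError(f"panel has no trajectory subset {lineage!r}")
        return list(self.table.loc[self.table[col].astype(bool), "marker"])
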