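"""Preprocessing: arcsinh transform, percentile scaling, gating, downsampling.

These are the steps between raw ion counts and the clustering substrate:
the variance-stabilizing arcsinh transform with a CyTOF-standard cofactor
of 5, per-channel scaling to the 99.9th percentile of the pooled analysis
set, evaluation of a hierarchical manual-gate tree written on the arcsinh
scale, and balanced (per-group) downsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventMatrix

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


def arcsinh_transform(events: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """asinh(value / cofactor), channel-wise; raw -> arcsinh scale."""
    if cofactor <= 0:
        raise PreprocessError("cofactor must be positive")
    if events.scale != "raw":
        raise PreprocessError(f"expected raw-scale events, got {events.scale!r}")
    return events.with_values(np.arcsinh(events.values / cofactor), scale="arcsinh")


def inverse_arcsinh(values: np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    return cofactor * np.sinh(values)


def percentile_scale(events: EventMatrix, q: float = 99.9) -> EventMatrix:
    """Divide each channel by its q-th percentile over the pooled analysis set.

    Channels whose q-th percentile is zero are left unchanged (and logged):
    dividing them would produce NaN and they carry no usable signal anyway.
    """
    if not (0.0 < q < 100.0):
        raise PreprocessError("percentile must be in (0, 100)")
    if events.scale != "arcsinh":
        raise PreprocessError(f"expected arcsinh-scale events, got {events.scale!r}")
    denom = np.percentile(events.values, q, axis=0)
    degenerate = denom == 0
    if degenerate.any():
        skipped = [c for c, d in zip(events.channels, degenerate) if d]
        log.warning("percentile_scale: zero %sth percentile, leaving unchanged: %s",
                    q, skipped)
    denom = np.where(degenerate, 1.0, denom)
    return events.with_values(events.values / denom[None, :], scale="scaled")


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

@dataclass
class GateNode:
    """One node of a hierarchical gate tree.

    ``intervals`` is a conjunction of 1-D interval tests
    ``channel -> (lo, hi)`` (either bound may be ``None`` for open-ended);
    a 2-D rectangle is simply two intervals.  ``polarity`` selects events
    inside (``"inside"``) or outside (``"outside"``) the conjunction.
    Membership is hierarchical: an event belongs to a node only if it also
    satisfies every ancestor.
    """

    name: str
    intervals: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    polarity: str = "inside"
    children: list["GateNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.polarity not in ("inside", "outside"):
            raise PreprocessError(f"gate {self.name}: bad polarity {self.polarity!r}")

    def add(self, child: "GateNode") -> "GateNode":
        self.children.append(child)
        return child

    def walk(self, _depth: int = 0):
        yield self, _depth
        for child in self.children:
            yield from child.walk(_depth + 1)

    def node_names(self) -> list[str]:
        names = [n.name for n, _ in self.walk()]
        if len(set(names)) != len(names):
            raise PreprocessError("gate node names must be unique")
        return names

    def _local_mask(self, events: EventMatrix) -> np.ndarray:
        mask = np.ones(events.n_events, dtype=bool)
        for channel, (lo, hi) in self.intervals.items():
            x = events.channel_values(channel)  # KeyError on unknown channel
            if lo is not None:
                mask &= x >= lo
            if hi is not None:
                mask &= x <= hi
        return mask if self.polarity == "inside" else ~mask


def apply_gate_tree(events: EventMatrix, root: GateNode) -> pd.DataFrame:
    """Evaluate a gate tree -> per-event boolean membership for every node.

    Returns a DataFrame with one boolean column per gate node plus a
    ``gate_leaf`` column holding the deepest leaf gate containing the event
    (document order breaks ties), or ``"ungated"``.
    """
    root.node_names()  # validates uniqueness
    membership: dict[str, np.ndarray] = {}

    def descend(node: GateNode, parent_mask: np.ndarray) -> None:
        mask = parent_mask & node._local_mask(events)
        membership[node.name] = mask
        for child in node.children:
            descend(child, mask)

    descend(root, np.ones(events.n_events, dtype=bool))
    table = pd.DataFrame(membership)

    leaf = np.full(events.n_events, "ungated", dtype=object)
    best_depth = np.full(events.n_events, -1)
    for node, depth in root.walk():
        if node.children:
            continue
        mask = membership[node.name] & (depth > best_depth)
        leaf[mask] = node.name
        best_depth[mask] = depth
    table["gate_leaf"] = leaf
    return table


def build_default_gate_tree() -> GateNode:
    """A CD45+ -> CD34 +/- -> early (CD34+CD38-) gate scheme on arcsinh scale.

    Thresholds are calibrated for the bundled simulator's default dynamics
    (CD45 baseline ~3, CD34 high ~4 falling late, CD38 switching on mid-
    trajectory); real panels should ship their own tree in config.
    """
    root = GateNode("CD45+", {"CD45": (1.0, None)})
    cd34pos = root.add(GateNode("CD34+", {"CD34": (2.0, None)}))
    root.add(GateNode("CD34-", {"CD34": (2.0, None)}, polarity="outside"))
    cd34pos.add(GateNode("CD34+CD38-", {"CD38": (None, 1.5)}))
    cd34pos.add(GateNode("CD34+CD38+", {"CD38": (1.5, None)}))
    return root


# ---------------------------------------------------------------------------
# Balanced downsampling
# ---------------------------------------------------------------------------

def _water_fill(sizes: dict[str, int], total_n: int) -> dict[str, int]:
    """Per-group quotas, as equal as possible, redistributing deficits.

    Iterative water-filling over groups in deterministic name order: groups
    smaller than the current fair share keep all events; the remainder is
    split over the rest, ±1 via name order.
    """
    quotas = {g: 0 for g in sizes}
    remaining = dict(sizes)
    budget = total_n
    while budget > 0 and remaining:
        names = sorted(remaining)
        share, extra = divmod(budget, len(names))
        fair = {g: share + (1 if i < extra else 0) for i, g in enumerate(names)}
        exhausted = {g for g in names if remaining[g] <= fair[g]}
        if exhausted:
            for g in exhausted:
                quotas[g] += remaining[g]
                budget -= remaining[g]
                del remaining[g]
            continue
        for g in names:
            quotas[g] += fair[g]
        budget = 0
    return quotas


def downsample_balanced(events: EventMatrix, group_keys: Sequence[str],
                        total_n: int, seed: int) -> EventMatrix:
    """Sample ``total_n`` events with per-group quotas as equal as possible.

    Groups are the distinct combinations of ``group_keys`` metadata columns
    (e.g. tissue x donor).  Groups smaller than their quota keep all events
    and the deficit is redistributed; sampling is without replacement and
    deterministic under ``seed``.
    """
    if total_n <= 0:
        raise PreprocessError("total_n must be positive")
    if total_n > events.n_events:
        raise PreprocessError(
            f"requested {total_n} events but only {events.n_events} available")
    key = events.meta[list(group_keys)].astype(str).agg("|".join, axis=1)
    sizes = key.value_counts().to_dict()
    quotas = _water_fill({str(k): int(v) for k, v in sizes.items()}, total_n)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for group in sorted(quotas):
        idx = np.flatnonzero((key == group).to_numpy())
        take = quotas[group]
        chosen.append(np.sort(rng.choice(idx, size=take, replace=False)))
    rows = np.sort(np.concatenate(chosen))
    return events.subset_rows(rows)
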