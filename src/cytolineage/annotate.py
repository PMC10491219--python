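"""Metacluster annotation and cluster-constrained knn label transfer.

Over-clustered Leiden partitions are merged into annotated metaclusters
(many clusters -> one biological label), and reference (bone-marrow)
metacluster labels are transferred to query tissues with a knn classifier
constrained to reference cells of the *same joint Leiden cluster*.  Query
cells in clusters holding too few reference cells come back "unannotated" —
the mechanism that keeps phenotypes absent from the reference (e.g. fetal-
liver-specific states) from being forced into reference labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.neighbors import NearestNeighbors

from .events import EventMatrix
from .graph import ClusterPartition

UNANNOTATED = "unannotated"

LINEAGE_GROUPS = ("early", "lymphoid", "myeloid", "erythroid", "mature",
                  "unassigned")

#: Default population -> lineage grouping for the simulator's tree.
DEFAULT_LINEAGE_OF = {
    "HSC": "early", "MPP": "early", "EMP1": "early",
    "EMP2": "erythroid", "EMP3": "erythroid", "Ery": "erythroid",
    "MP": "myeloid", "MDP": "myeloid", "pDCP": "myeloid", "pDC": "mature",
    "Mono": "mature", UNANNOTATED: "unassigned",
}


class AnnotationError(ValueError):
    pass


@dataclass
class MetaclusterMap:
    """cluster id -> metacluster label, and label -> lineage group."""

    cluster_to_label: dict[int, str]
    label_to_lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, lineage in self.label_to_lineage.items():
            if lineage not in LINEAGE_GROUPS:
                raise AnnotationError(f"unknown lineage group {lineage!r} for {label}")
        for label in set(self.cluster_to_label.values()):
            self.label_to_lineage.setdefault(
                label, DEFAULT_LINEAGE_OF.get(label, "unassigned"))

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.cluster_to_label.values()))

    def lineage_of(self, label: str) -> str:
        return self.label_to_lineage.get(label, "unassigned")

    def to_yaml(self, path) -> None:
        payload = {
            "clusters": {int(k): v for k, v in sorted(self.cluster_to_label.items())},
            "lineages": dict(sorted(self.label_to_lineage.items())),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MetaclusterMap":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls({int(k): v for k, v in payload["clusters"].items()},
                   dict(payload.get("lineages", {})))


def majority_vote_map(partition: ClusterPartition,
                      truth_labels: np.ndarray | pd.Series) -> MetaclusterMap:
    """Annotate each cluster with its majority ground-truth population.

    The synthetic stand-in for manual metacluster annotation: with known
    per-cell truth, each over-clustered Leiden cluster takes the label of
    the population most of its cells belong to.
    """
    truth = np.asarray(truth_labels)
    mapping: dict[int, str] = {}
    for c in range(partition.n_clusters):
        members = truth[partition.labels == c]
        if members.size == 0:
            mapping[c] = UNANNOTATED
            continue
        values, counts = np.unique(members, return_counts=True)
        mapping[c] = str(values[np.argmax(counts)])
    return MetaclusterMap(mapping)


def apply_metaclusters(partition: ClusterPartition, annotation: MetaclusterMap,
                       events: EventMatrix | None = None,
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-cell metacluster labels plus a per-label summary table.

    The summary holds metacluster sizes and, when ``events`` is supplied,
    per-metacluster median expression (the input to annotation heatmaps).
    Every cluster id present in the partition must be mapped.
    """
    unmapped = set(np.unique(partition.labels)) - set(annotation.cluster_to_label)
    if unmapped:
        raise AnnotationError(f"clusters with no metacluster label: {sorted(unmapped)}")
    lut = np.array([annotation.cluster_to_label.get(c, UNANNOTATED)
                    for c in range(partition.n_clusters)], dtype=object)
    labels = lut[partition.labels]
    rows = []
    for label in sorted(set(labels.tolist())):
        mask = labels == label
        row = {"metacluster": label, "n_cells": int(mask.sum()),
               "lineage": annotation.lineage_of(label)}
        if events is not None:
            med = np.median(events.values[mask], axis=0)
            row.update({ch: med[j] for j, ch in enumerate(events.channels)})
        rows.append(row)
    return labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cluster-constrained knn transfer
# ---------------------------------------------------------------------------

@dataclass
class TransferResult:
    """Per query cell: assigned label (or "unannotated"), vote margin, k used."""

    labels: np.ndarray
    margin: np.ndarray
    n_neighbors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "vote_margin": self.margin,
                             "n_neighbors": self.n_neighbors})


def constrained_knn_transfer(joint_partition: ClusterPartition,
                             X: np.ndarray,
                             is_reference: np.ndarray,
                             ref_labels: np.ndarray,
                             k: int = 15,
                             min_ref: int | None = None,
                             self_transfer: bool = False) -> TransferResult:
    """Transfer reference labels to query cells within joint Leiden clusters.

    For each query cell, the candidate set is the reference cells sharing its
    joint cluster.  Clusters with fewer than ``min_ref`` (default: k)
    reference cells yield "unannotated".  Otherwise the k nearest candidates
    (Euclidean, in the scaled expression space ``X``) vote by unweighted
    majority; ties go to the label of the single nearest neighbor.  The vote
    margin is the winning label's fraction of the votes cast.

    With ``self_transfer=True`` the reference is scored as its own query,
    leave-one-out within each candidate set (a consistency check of the
    reference annotation).
    """
    if k < 1:
        raise AnnotationError("k must be >= 1")
    if min_ref is None:
        min_ref = k
    X = np.asarray(X, dtype=np.float64)
    is_reference = np.asarray(is_reference, dtype=bool)
    ref_labels = np.asarray(ref_labels)
    if ref_labels.shape[0] != int(is_reference.sum()):
        raise AnnotationError("ref_labels must cover exactly the reference cells")
    if pd.isna(ref_labels).any():
        raise AnnotationError("reference labels contain missing values")

    ref_idx = np.flatnonzero(is_reference)
    query_idx = ref_idx if self_transfer else np.flatnonzero(~is_reference)
    ref_label_of = dict(zip(ref_idx.tolist(), ref_labels.tolist()))
    labels = np.full(query_idx.size, UNANNOTATED, dtype=object)
    margin = np.zeros(query_idx.size)
    n_used = np.zeros(query_idx.size, dtype=np.int64)

    clusters = joint_partition.labels
    for c in np.unique(clusters[query_idx]):
        q_local = np.flatnonzero(clusters[query_idx] == c)
        cand = ref_idx[clusters[ref_idx] == c]
        min_needed = min_ref + 1 if self_transfer else min_ref
        if cand.size < min_needed:
            continue
        n_nb = min(k + 1 if self_transfer else k, cand.size)
        nn = NearestNeighbors(n_neighbors=n_nb).fit(X[cand])
        _, nbr = nn.kneighbors(X[query_idx[q_local]])
        for row, ql in enumerate(q_local):
            nbrs = nbr[row]
            if self_transfer:
                # leave-one-out: drop the query cell itself from its votes
                self_cand = np.flatnonzero(cand[nbrs] == query_idx[ql])
                keep = np.ones(nbrs.size, dtype=bool)
                keep[self_cand[0] if self_cand.size else 0] = False
                nbrs = nbrs[keep][:k]
            votes = [ref_label_of[int(cand[j])] for j in nbrs]
            values, counts = np.unique(votes, return_counts=True)
            top = counts.max()
            winners = values[counts == top]
            # tie-break: the label of the single nearest candidate
            winner = votes[0] if len(winners) > 1 else winners[0]
            labels[ql] = winner
            margin[ql] = counts[values == winner][0] / len(votes)
            n_used[ql] = len(votes)
    return TransferResult(labels, margin, n_used)


# ---------------------------------------------------------------------------
# Composition tables
# ---------------------------------------------------------------------------

def composition_table(labels: np.ndarray | pd.Series,
                      sample_ids: np.ndarray | pd.Series,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x label proportion matrix (rows sum to 1) plus raw counts."""
    counts = pd.crosstab(pd.Series(np.asarray(sample_ids), name="sample_id"),
                         pd.Series(np.asarray(labels), name="label"))
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return proportions, counts


def group_by_lineage(proportions: pd.DataFrame,
                     annotation: MetaclusterMap) -> pd.DataFrame:
    """Sum metacluster proportion columns into their lineage groups."""
    lineages = {col: annotation.lineage_of(col) for col in proportions.columns}
    return proportions.T.groupby(pd.Series(lineages)).sum().T
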