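"""End-to-end orchestration: simulate/read -> preprocess -> correct -> gate ->
downsample -> graph/cluster -> annotate/transfer -> trajectory subsets -> stats.

Every stage writes flat TSV/YAML artifacts into the run directory and the
run closes with a manifest recording the config, per-stage seeds, package
versions, and a sha256 checksum per artifact — two runs from the same config
produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (MetaclusterMap, apply_metaclusters, composition_table,
                       constrained_knn_transfer, group_by_lineage,
                       majority_vote_map)
from .batch import correct_batches, correction_report
from .config import RunConfig, stage_seed, validate_config
from .events import EventMatrix
from .fcs import read_fcs_set
from .graph import run_trajectory, subset_and_reanalyze
from .preprocess import (apply_gate_tree, arcsinh_transform,
                         build_default_gate_tree, downsample_balanced,
                         percentile_scale)
from .simulate import (ERYTHROID_CHANNELS, MYELOID_CHANNELS,
                       build_default_batch_effects, build_default_dynamics,
                       build_default_lineage, build_default_panel,
                       build_default_samples, simulate_dataset)
from .stats import (bin_pseudotime, compare_groups,
                    default_positivity_thresholds, expression_derivative,
                    percent_positive, sample_dissimilarity)

log = logging.getLogger(__name__)

#: Trajectory subset definitions mirroring the erythroid / myeloid re-analyses.
TRAJECTORY_SUBSETS = {
    "erythroid": {
        "labels": ["HSC", "EMP1", "EMP2", "EMP3", "Ery"],
        "channels": ERYTHROID_CHANNELS,
    },
    "myeloid": {
        "labels": ["HSC", "MPP", "MP", "MDP", "pDCP", "pDC", "Mono"],
        "channels": MYELOID_CHANNELS,
    },
}


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the manifest dictionary."""
    errors = validate_config(config)
    if errors:
        raise PipelineError("validate", "config-invalid", "; ".join(errors))
    outdir = Path(config.paths.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    # -- acquire events ------------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate.enabled:
            sim = config.simulate
            lineage = build_default_lineage(tissues=tuple(sim.tissues))
            panel = build_default_panel()
            dynamics = build_default_dynamics(lineage)
            if sim.noise_sd is not None or sim.zero_inflation is not None:
                dynamics = dynamics.scaled(sim.noise_sd, sim.zero_inflation)
            samples = build_default_samples(sim.n_batches, tuple(sim.tissues),
                                            sim.samples_per_tissue_per_batch)
            batch_effects = build_default_batch_effects(
                sorted({s.batch_id for s in samples}), panel.markers,
                seed=stage_seed(config.seed, "simulate"))
            events, truth = simulate_dataset(
                lineage, dynamics, batch_effects, sim.n_events_per_sample,
                samples, seed=stage_seed(config.seed, "simulate"))
        else:
            stage = "read"
            fcs_dir = Path(config.paths.fcs_dir)
            paths = sorted(fcs_dir.glob("*.fcs"))
            if not paths:
                raise PipelineError(stage, "no-fcs", f"no FCS files in {fcs_dir}")
            events = read_fcs_set(paths, config.paths.metadata)
            lineage = build_default_lineage()
            panel = build_default_panel()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, "acquire-failed", str(exc)) from exc

    # -- transform + correct -------------------------------------------------
    stage = "preprocess"
    try:
        events = arcsinh_transform(events, cofactor=config.preprocess.cofactor)
    except Exception as exc:
        raise PipelineError(stage, "transform-failed", str(exc)) from exc

    if config.correct.enabled:
        stage = "correct"
        try:
            before = events
            events, transform = correct_batches(
                events, seed=stage_seed(config.seed, "correct"),
                percentile=config.correct.percentile)
            transform.to_yaml(outdir / "anchor_transform.yaml")
            artifacts.append(outdir / "anchor_transform.yaml")
            artifacts.append(_write_tsv(correction_report(before, events),
                                        outdir / "correction_report.tsv"))
        except Exception as exc:
            raise PipelineError(stage, "correction-failed", str(exc)) from exc

    # -- gate ---------------------------------------------------------------
    if config.preprocess.apply_gates:
        stage = "gate"
        try:
            gates = apply_gate_tree(events, build_default_gate_tree())
            events.meta["gate_leaf"] = gates["gate_leaf"].to_numpy()
            artifacts.append(_write_tsv(gates, outdir / "gates.tsv", index=True))
        except Exception as exc:
            raise PipelineError(stage, "gating-failed", str(exc)) from exc

    # -- downsample + scale --------------------------------------------------
    if config.downsample.enabled:
        stage = "downsample"
        try:
            events = downsample_balanced(
                events, config.downsample.group_keys, config.downsample.total_n,
                seed=stage_seed(config.seed, "downsample"))
        except Exception as exc:
            raise PipelineError(stage, "downsample-failed", str(exc)) from exc

    stage = "scale"
    try:
        events = percentile_scale(events, q=config.preprocess.scale_percentile)
    except Exception as exc:
        raise PipelineError(stage, "scaling-failed", str(exc)) from exc

    # -- graph / clustering / pseudotime ------------------------------------
    stage = "graph"
    g = config.graph
    has_truth = "population" in events.meta.columns
    try:
        root_labels = (events.meta["population"].to_numpy() if has_truth
                       else np.full(events.n_events, g.root_population))
        traj = run_trajectory(
            events.values, root_labels, root_population=g.root_population,
            k=g.k, m=g.m, resolution=g.resolution,
            edge_threshold=g.edge_threshold,
            seed=stage_seed(config.seed, "graph"),
            pseudotime_method=g.pseudotime_method)
        cells = pd.DataFrame({
            "sample_id": events.meta["sample_id"],
            "cluster": traj.partition.labels,
            "pseudotime": traj.pseudotime.values,
            "unreachable": traj.pseudotime.unreachable,
        })
        artifacts.append(_write_tsv(cells, outdir / "cells.tsv", index=True))
        artifacts.append(_write_tsv(traj.knn_diffusion.edge_list(),
                                    outdir / "knn_edges.tsv"))
        edges = pd.DataFrame(traj.cluster_graph.retained_edges(),
                             columns=["cluster_i", "cluster_j", "score"])
        artifacts.append(_write_tsv(edges, outdir / "cluster_edges.tsv"))
        emb = pd.DataFrame(traj.embedding.coordinates,
                           columns=[f"DC{i+1}" for i in range(traj.embedding.m)])
        artifacts.append(_write_tsv(emb, outdir / "diffusion_coords.tsv", index=True))
        log.info("graph: %d clusters over %d cells (%d components)",
                 traj.partition.n_clusters, events.n_events,
                 traj.embedding.component.max() + 1)
    except Exception as exc:
        raise PipelineError(stage, "graph-failed", str(exc)) from exc

    # -- annotation ----------------------------------------------------------
    stage = "annotate"
    try:
        if config.paths.annotation:
            annotation = MetaclusterMap.from_yaml(config.paths.annotation)
        elif has_truth:
            annotation = majority_vote_map(traj.partition,
                                           events.meta["population"].to_numpy())
        else:
            raise PipelineError(stage, "no-annotation",
                                "no annotation map and no truth labels")
        meta_labels, summary = apply_metaclusters(traj.partition, annotation, events)
        events.meta["metacluster"] = meta_labels
        annotation.to_yaml(outdir / "metacluster_map.yaml")
        artifacts.append(outdir / "metacluster_map.yaml")
        artifacts.append(_write_tsv(summary, outdir / "metacluster_summary.tsv"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, "annotation-failed", str(exc)) from exc

    # -- cross-tissue transfer ----------------------------------------------
    tissues = events.meta["tissue"].unique().tolist()
    if config.transfer.enabled and len(tissues) > 1:
        stage = "transfer"
        try:
            is_anchor = events.meta.get(
                "is_anchor", pd.Series(False, index=events.meta.index))
            is_ref = ((events.meta["tissue"] == config.transfer.reference_tissue)
                      & ~is_anchor.astype(bool)).to_numpy()
            if not is_ref.any():
                raise PipelineError(stage, "no-reference",
                                    f"no cells from reference tissue "
                                    f"{config.transfer.reference_tissue!r}")
            result = constrained_knn_transfer(
                traj.partition, events.values, is_ref,
                np.asarray(events.meta["metacluster"])[is_ref],
                k=config.transfer.k, min_ref=config.transfer.min_ref)
            table = result.to_frame()
            table.insert(0, "event", np.flatnonzero(~is_ref))
            artifacts.append(_write_tsv(table, outdir / "transfer.tsv"))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, "transfer-failed", str(exc)) from exc

    # -- trajectory subsets --------------------------------------------------
    subset_results = {}
    for name, defn in TRAJECTORY_SUBSETS.items():
        stage = f"subset-{name}"
        wanted = [l for l in defn["labels"]
                  if l in set(annotation.cluster_to_label.values())]
        if len(wanted) < 2:
            log.info("%s: skipped, no matching metaclusters", stage)
            continue
        try:
            sub = subset_and_reanalyze(
                events.values, events.channels, traj.partition,
                traj.cluster_graph, annotation.cluster_to_label, wanted,
                [c for c in defn["channels"] if c in events.channels],
                root_labels, root_population=g.root_population,
                k=g.k, m=g.m, resolution=g.resolution,
                edge_threshold=g.edge_threshold,
                seed=stage_seed(config.seed, "graph"),
                pseudotime_method=g.pseudotime_method)
            subset_results[name] = sub
            sub_cells = pd.DataFrame({
                "event": sub.cell_index,
                "cluster": sub.partition.labels,
                "pseudotime": sub.pseudotime.values,
            })
            artifacts.append(_write_tsv(sub_cells, outdir / f"subset_{name}.tsv"))
        except Exception as exc:
            raise PipelineError(stage, "subset-failed", str(exc)) from exc

    # -- downstream statistics ----------------------------------------------
    stage = "stats"
    try:
        st = config.stats
        sample_ids = events.meta["sample_id"].to_numpy()
        proportions, counts = composition_table(
            traj.partition.labels, sample_ids)
        artifacts.append(_write_tsv(proportions, outdir / "composition.tsv",
                                    index=True))
        dm = sample_dissimilarity(proportions, linkage=st.linkage)
        artifacts.append(_write_tsv(dm.matrix, outdir / "sample_distance.tsv",
                                    index=True))
        linkage_df = pd.DataFrame(dm.linkage,
                                  columns=["left", "right", "height", "size"])
        artifacts.append(_write_tsv(linkage_df, outdir / "dendrogram.tsv"))

        # pseudotime summaries per subset trajectory
        for name, sub in subset_results.items():
            markers = [c for c in TRAJECTORY_SUBSETS[name]["channels"]
                       if c in events.channels]
            col_idx = [events.channels.index(c) for c in markers]
            finite = np.isfinite(sub.pseudotime.values)
            if finite.sum() < st.n_bins:
                continue
            binned = bin_pseudotime(
                sub.pseudotime.values,
                events.values[np.ix_(sub.cell_index, col_idx)], markers,
                n_bins=st.n_bins)
            artifacts.append(_write_tsv(binned.to_frame(),
                                        outdir / f"binned_{name}.tsv", index=True))
            deriv = expression_derivative(binned, st.smoothing_window)
            artifacts.append(_write_tsv(deriv.to_frame(),
                                        outdir / f"derivative_{name}.tsv",
                                        index=True))

        # tissue comparison of lineage-group composition
        meta_prop, _ = composition_table(events.meta["metacluster"], sample_ids)
        lineage_prop = group_by_lineage(meta_prop, annotation)
        artifacts.append(_write_tsv(lineage_prop, outdir / "lineage_composition.tsv",
                                    index=True))
        tissue_of = events.meta.groupby("sample_id")["tissue"].first()
        groups = tissue_of.loc[lineage_prop.index]
        counts_per_tissue = groups.value_counts()
        if (len(counts_per_tissue) == 2 and (counts_per_tissue >= 2).all()):
            tests = compare_groups(lineage_prop, groups.to_numpy())
            artifacts.append(_write_tsv(tests, outdir / "group_tests.tsv"))

        # percent positive within the early gate (or all cells)
        subset_mask = (events.meta["gate_leaf"] == "CD34+CD38-"
                       if "gate_leaf" in events.meta.columns
                       else pd.Series(True, index=events.meta.index)).to_numpy()
        if subset_mask.any():
            thresholds = default_positivity_thresholds(
                events.values, events.channels, q=st.positivity_percentile)
            pp = percent_positive(events.values, events.channels, sample_ids,
                                  subset_mask, thresholds)
            artifacts.append(_write_tsv(pp, outdir / "percent_positive.tsv",
                                        index=True))
    except Exception as exc:
        raise PipelineError(stage, "stats-failed", str(exc)) from exc

    # -- manifest ------------------------------------------------------------
    manifest = {
        "package": {"name": "cytolineage", "version": __version__},
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("simulate", "correct", "downsample", "graph",
                                  "transfer", "stats")},
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
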