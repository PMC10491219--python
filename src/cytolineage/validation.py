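"""Synthetic-truth validation experiments for the whole pipeline.

Each function runs one end-to-end experiment on generated data with known
ground truth and returns plain scalar metrics: batch-correction fidelity,
lineage-topology recovery, erythroid-arm re-analysis, cross-tissue label
transfer, small exact oracles, inflection detection, and pipeline
determinism.  The test suite asserts bounds on these metrics and the
reproduction script reports them.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from .annotate import (MetaclusterMap, apply_metaclusters,
                       constrained_knn_transfer, majority_vote_map)
from .batch import correct_batches, split_anchors
from .config import RunConfig
from .events import EventMatrix
from .graph import (TrajectoryResult, build_knn_graph, diffusion_map,
                    leiden_partition, population_connectivity, run_trajectory,
                    subset_and_reanalyze)
from .pipeline import run_pipeline
from .preprocess import arcsinh_transform, percentile_scale
from .simulate import (ERYTHROID_CHANNELS, BatchEffectSpec, LineageSpec,
                       SampleDef, SyntheticTruth, build_default_batch_effects,
                       build_default_dynamics, build_default_lineage,
                       build_default_panel, build_default_samples,
                       simulate_dataset, simulate_default)
from .stats import bin_pseudotime, expression_derivative

#: Events per sample giving ~20k cells with the default 9-sample sheet.
DEFAULT_EVENTS_PER_SAMPLE = 2223
DEFAULT_RESOLUTION = 4.0

ERYTHROID_PATH = ["HSC", "EMP1", "EMP2", "EMP3", "Ery"]
ERYTHROID_CHAIN = {frozenset(p) for p in zip(ERYTHROID_PATH, ERYTHROID_PATH[1:])}


# ---------------------------------------------------------------------------
# 1. Batch correction
# ---------------------------------------------------------------------------

def batch_correction_experiment(seed: int,
                                n_events_per_sample: int = DEFAULT_EVENTS_PER_SAMPLE,
                                n_batches: int = 3) -> dict[str, float]:
    """Correct a 3-batch set with systematic gain/shift distortions.

    Distortions are per-channel gains in [0.7, 1.4] plus additive shifts;
    the instrument noise floor is off so that corrected values can be
    compared rank-wise against the pre-distortion truth (stochastic
    per-event noise is not a batch effect and no per-channel transform can
    undo it).
    """
    lineage = build_default_lineage()
    panel = build_default_panel()
    dynamics = build_default_dynamics(lineage)
    samples = build_default_samples(n_batches)
    effects = build_default_batch_effects(
        sorted({s.batch_id for s in samples}), panel.markers, seed=seed,
        floor_sd=0.0)
    events, truth = simulate_dataset(lineage, dynamics, effects,
                                     n_events_per_sample, samples, seed=seed)
    arc = arcsinh_transform(events)
    corrected, transform = correct_batches(arc, seed=seed)

    anchors_before = split_anchors(arc)
    post_shift_medians = np.vstack([
        np.median(anchors_before[b].values - transform.shift[b][None, :], axis=0)
        for b in transform.batches])
    median_spread = float(np.max(np.ptp(post_shift_medians, axis=0)))

    anchors_after = split_anchors(corrected)
    worst_gap_excess = 0.0
    for b in transform.batches:
        vals = anchors_after[b].values
        n = vals.shape[0]
        rank = int(round(0.998 * (n - 1)))
        achieved = np.percentile(vals, 99.8, axis=0)
        for j in range(vals.shape[1]):
            col = np.sort(vals[:, j])
            gap = col[min(rank + 1, n - 1)] - col[max(rank - 1, 0)]
            excess = abs(achieved[j] - transform.target_p[j]) - gap
            worst_gap_excess = max(worst_gap_excess, float(excess))

    anchor_mask = corrected.meta["is_anchor"].to_numpy()
    clean_arc = np.arcsinh(truth.clean_values / 5.0)
    rho_post, rho_pre = [], []
    for j in range(corrected.n_channels):
        rho_post.append(scipy.stats.spearmanr(
            corrected.values[anchor_mask, j], clean_arc[anchor_mask, j]).statistic)
        rho_pre.append(scipy.stats.spearmanr(
            arc.values[anchor_mask, j], clean_arc[anchor_mask, j]).statistic)
    return {
        "n_cells": events.n_events,
        "anchor_median_spread_post_shift": median_spread,
        "n_negative_values": int((corrected.values < 0).sum()),
        "percentile_gap_excess": worst_gap_excess,
        "min_anchor_spearman": float(np.min(rho_post)),
        "min_anchor_spearman_uncorrected": float(np.min(rho_pre)),
    }


# ---------------------------------------------------------------------------
# 2/3. Default analysis: trajectory recovery + erythroid re-analysis
# ---------------------------------------------------------------------------

@dataclass
class DefaultAnalysis:
    """One full run of the scaffold on the default ~20k-cell simulation."""

    scaled: EventMatrix
    truth: SyntheticTruth
    lineage: LineageSpec
    trajectory: TrajectoryResult
    metaclusters: MetaclusterMap
    seed: int


def run_default_analysis(seed: int,
                         n_events_per_sample: int = DEFAULT_EVENTS_PER_SAMPLE,
                         resolution: float = DEFAULT_RESOLUTION,
                         ) -> DefaultAnalysis:
    events, truth, lineage, panel = simulate_default(
        n_events_per_sample=n_events_per_sample, n_batches=3, seed=seed)
    corrected, _ = correct_batches(arcsinh_transform(events), seed=seed)
    scaled = percentile_scale(corrected)
    pops = scaled.meta["population"].to_numpy()
    trajectory = run_trajectory(scaled.values, pops, resolution=resolution,
                                seed=seed)
    metaclusters = majority_vote_map(trajectory.partition, pops)
    return DefaultAnalysis(scaled, truth, lineage, trajectory, metaclusters,
                           seed)


def trajectory_recovery_metrics(analysis: DefaultAnalysis) -> dict[str, float]:
    """Branch-edge recovery, per-branch pseudotime fidelity, metacluster ARI."""
    pops = analysis.scaled.meta["population"].to_numpy()
    traj = analysis.trajectory
    edges = population_connectivity(traj.knn_diffusion, traj.partition,
                                    analysis.metaclusters.cluster_to_label)
    true_edges = analysis.lineage.lineage_edges()
    found = sum(1 for e in true_edges if e in edges)
    spurious = sum(1 for e in edges if e not in true_edges)

    latent = analysis.scaled.meta["latent_time"].to_numpy()
    branch = analysis.scaled.meta["branch"].to_numpy()
    pt = traj.pseudotime.values
    rhos = []
    for b in np.unique(branch):
        mask = (branch == b) & np.isfinite(pt)
        rhos.append(scipy.stats.spearmanr(pt[mask], latent[mask]).statistic)

    labels, _ = apply_metaclusters(traj.partition, analysis.metaclusters)
    return {
        "n_cells": analysis.scaled.n_events,
        "n_clusters": traj.partition.n_clusters,
        "lineage_edges_recovered": int(found),
        "spurious_population_edges": int(spurious),
        "min_branch_pseudotime_spearman": float(np.min(rhos)),
        "metacluster_ari": float(adjusted_rand_score(pops, labels)),
    }


def erythroid_subset_metrics(analysis: DefaultAnalysis) -> dict[str, float]:
    """Re-analyze the erythroid arm alone, then again with MPPs added.

    The erythroid-only run must recover an unbranched HSC->...->Ery path
    among the expected populations; adding MPP clusters must attach an
    off-path MPP branch (at HSC/EMP1) without disturbing the path, with the
    branch composed of majority-MPP clusters by construction of the
    projection.
    """
    scaled, traj = analysis.scaled, analysis.trajectory
    pops = scaled.meta["population"].to_numpy()

    def project(sub, expected: set[str]):
        sub_pops = pops[sub.cell_index]
        mc = majority_vote_map(sub.partition, sub_pops)
        edges = population_connectivity(sub.knn_diffusion, sub.partition,
                                        mc.cluster_to_label)
        within = {e: v for e, v in edges.items() if set(e) <= expected}
        return edges, within

    ery = subset_and_reanalyze(
        scaled.values, scaled.channels, traj.partition, traj.cluster_graph,
        analysis.metaclusters.cluster_to_label, set(ERYTHROID_PATH),
        ERYTHROID_CHANNELS, pops, resolution=DEFAULT_RESOLUTION,
        seed=analysis.seed)
    _, ery_within = project(ery, set(ERYTHROID_PATH))
    chain_found = sum(1 for e in ERYTHROID_CHAIN if e in ery_within)
    off_chain = sum(1 for e in ery_within if e not in ERYTHROID_CHAIN)

    with_mpp = subset_and_reanalyze(
        scaled.values, scaled.channels, traj.partition, traj.cluster_graph,
        analysis.metaclusters.cluster_to_label, set(ERYTHROID_PATH) | {"MPP"},
        ERYTHROID_CHANNELS, pops, resolution=DEFAULT_RESOLUTION,
        seed=analysis.seed)
    mpp_edges, mpp_within = project(with_mpp, set(ERYTHROID_PATH) | {"MPP"})
    mpp_attach = {next(iter(e - {"MPP"})) for e in mpp_within if "MPP" in e}
    chain_found_mpp = sum(1 for e in ERYTHROID_CHAIN if e in mpp_within)
    mpp_cells = pops[with_mpp.cell_index] == "MPP"
    return {
        "erythroid_chain_edges_recovered": int(chain_found),
        "erythroid_off_chain_edges": int(off_chain),
        "chain_edges_with_mpp_added": int(chain_found_mpp),
        "mpp_branch_attached": int(bool(mpp_attach)),
        "mpp_attaches_off_path_only": int(mpp_attach <= {"HSC", "EMP1"}),
        "mpp_truth_cells_in_subset": int(mpp_cells.sum()),
    }


# ---------------------------------------------------------------------------
# 4. Constrained transfer
# ---------------------------------------------------------------------------

def transfer_experiment(seed: int,
                        n_events_per_sample: int = DEFAULT_EVENTS_PER_SAMPLE,
                        n_novel: int = 400,
                        displacement_sds: float = 5.0) -> dict[str, float]:
    """Self-transfer, BM->mPB transfer, and novel-population rejection.

    A block of query cells is displaced by ``displacement_sds`` pooled SDs
    along every channel, creating a phenotype with no reference analog; the
    constrained classifier must leave it unannotated.
    """
    events, truth, lineage, panel = simulate_default(
        n_events_per_sample=n_events_per_sample, n_batches=3, seed=seed)
    corrected, _ = correct_batches(arcsinh_transform(events), seed=seed)
    scaled = percentile_scale(corrected)
    pops = scaled.meta["population"].to_numpy().copy()
    tissue = scaled.meta["tissue"].to_numpy()
    anchor = scaled.meta["is_anchor"].to_numpy()
    keep = ((tissue == "BM") & ~anchor) | (tissue == "mPB")
    X = scaled.values[keep].copy()
    pops = pops[keep]
    is_ref = ((tissue == "BM") & ~anchor)[keep]

    rng = np.random.default_rng(seed)
    novel = rng.choice(np.flatnonzero(~is_ref), n_novel, replace=False)
    X[novel] += displacement_sds * X.std(axis=0)[None, :]
    pops[novel] = "NOVEL"

    g1 = build_knn_graph(X, k=15)
    emb = diffusion_map(g1, m=15)
    g2 = build_knn_graph(emb.coordinates, k=15, space="diffusion-space")
    part = leiden_partition(g2, resolution=DEFAULT_RESOLUTION, seed=seed)

    ref_labels = pops[is_ref]
    transferred = constrained_knn_transfer(part, X, is_ref, ref_labels, k=15)
    self_check = constrained_knn_transfer(part, X, is_ref, ref_labels, k=15,
                                          self_transfer=True)
    query_pops = pops[~is_ref]
    novel_mask = query_pops == "NOVEL"
    return {
        "n_cells": int(X.shape[0]),
        "self_transfer_accuracy": float(
            (self_check.labels == ref_labels).mean()),
        "query_transfer_accuracy": float(
            (transferred.labels[~novel_mask] == query_pops[~novel_mask]).mean()),
        "novel_unannotated_fraction": float(
            (transferred.labels[novel_mask] == "unannotated").mean()),
    }


# ---------------------------------------------------------------------------
# 5. Exact oracles
# ---------------------------------------------------------------------------

def exact_oracle_metrics(seed: int) -> dict[str, float]:
    """Small closed-form / enumeration cross-checks of the statistics layer."""
    import itertools

    from .stats import (_wilcoxon_rank_sum, sample_dissimilarity)

    rng = np.random.default_rng(seed)

    raw = rng.random((10, 7))
    prop = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True))
    D = sample_dissimilarity(prop).matrix.to_numpy()
    brute = np.zeros_like(D)
    for i in range(10):
        for j in range(10):
            brute[i, j] = np.sum(np.abs(prop.to_numpy()[i] - prop.to_numpy()[j]))
    manhattan_err = float(np.max(np.abs(D - brute)))

    _, p_extreme = _wilcoxon_rank_sum(np.array([1.0, 2, 3]),
                                      np.array([10.0, 11, 12]))

    def brute_p(x, y):
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        n = len(x)
        observed = ranks[:n].sum()
        mean = n * (len(pooled) + 1) / 2.0
        stats = np.array([ranks[list(c)].sum() for c in
                          itertools.combinations(range(len(pooled)), n)])
        return float(np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-12))

    wilcoxon_err = 0.0
    for nx, ny in [(3, 3), (4, 4), (5, 6), (6, 6)]:
        vals = rng.permutation(np.arange(1.0, nx + ny + 1))
        x, y = vals[:nx], vals[nx:]
        _, p = _wilcoxon_rank_sum(x, y)
        wilcoxon_err = max(wilcoxon_err, abs(p - brute_p(x, y)))

    pt = rng.random(977)
    X = rng.normal(0, 3, (977, 4))
    binned = bin_pseudotime(pt, X, list("abcd"), n_bins=100)
    overall = (binned.means * binned.counts[:, None]).sum(axis=0) / 977
    bin_mean_err = float(np.max(np.abs(overall - X.mean(axis=0))))

    deriv = expression_derivative(binned, smoothing_window=1)
    steps = np.diff(binned.midpoints)
    integral = (deriv.rates * steps[:, None]).sum(axis=0)
    ftc_err = float(np.max(np.abs(integral
                                  - (binned.means[-1] - binned.means[0]))))
    return {
        "manhattan_vs_bruteforce_max_error": manhattan_err,
        "wilcoxon_extreme_exact_p": float(p_extreme),
        "wilcoxon_vs_enumeration_max_error": float(wilcoxon_err),
        "bin_mean_conservation_error": bin_mean_err,
        "derivative_integration_error": ftc_err,
    }


# ---------------------------------------------------------------------------
# 6. Inflection detection
# ---------------------------------------------------------------------------

def inflection_experiment(seed: int, replicates: int = 20,
                          n_cells: int = 8000, t0: float = 0.6,
                          amplitude: float = 3.0, steepness: float = 0.02,
                          noise_sd: float = 0.22) -> dict[str, float]:
    """Hit rate of max-|derivative| localization for a logistic marker.

    Marker parameters mirror the simulator's defaults (amplitude ~3 on the
    arcsinh scale, boundary-centered ramp of steepness 0.02, noise SD 0.22).
    A replicate scores a hit when the maximal-rate location lies within
    +/-3 bins of the bin containing the true inflection time.  Rates are
    estimated at bin *boundaries* (between bins i and i+1), so boundary i
    counts as a hit when either adjacent bin is within the window.
    """
    hits = 0
    for r in range(replicates):
        rng = np.random.default_rng((seed, r))
        t = rng.random(n_cells)
        y = (0.3 + amplitude / (1.0 + np.exp(-(t - t0) / steepness))
             + rng.normal(0, noise_sd, n_cells))
        binned = bin_pseudotime(t, y[:, None], ["m"], n_bins=200)
        deriv = expression_derivative(binned, smoothing_window=9)
        true_bin = int(np.argmin(np.abs(binned.midpoints - t0)))
        boundary = deriv.max_rate_bin["m"]
        if min(abs(boundary - true_bin), abs(boundary + 1 - true_bin)) <= 3:
            hits += 1
    return {"replicates": replicates,
            "inflection_hit_rate": hits / replicates}


# ---------------------------------------------------------------------------
# 7. Determinism
# ---------------------------------------------------------------------------

def determinism_experiment(seed: int, workdir: str | Path | None = None,
                           n_events_per_sample: int = 1200) -> dict[str, float]:
    """Run the demo pipeline twice from one config; compare checksums."""
    import time

    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="cytolin-"))
    config = RunConfig()
    config.seed = int(seed)
    config.simulate.n_events_per_sample = n_events_per_sample
    config.simulate.n_batches = 3
    config.paths.output_dir = str(base / "demo-run")
    t0 = time.time()
    m1 = run_pipeline(config)
    m2 = run_pipeline(config)
    elapsed = time.time() - t0
    return {
        "n_artifacts": len(m1["artifacts"]),
        "identical_artifact_checksums": int(m1["artifacts"] == m2["artifacts"]),
        "two_run_seconds": float(elapsed),
    }
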