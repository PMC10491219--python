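# cytolineage

Graph-based trajectory analysis of mass-cytometry (CyTOF) data from human
hematopoietic stem and progenitor cells (HSPCs), packaged as a tested,
reusable pipeline with a synthetic-truth simulator.

Mass cytometry measures ~30–40 protein markers (surface antigens plus
intracellular transcription factors and regulators) on millions of single
cells. Analyzing multi-batch, multi-tissue HSPC panels requires a chain of
steps whose details matter: per-channel `arcsinh(x/5)` transformation,
batch correction anchored on a common sample acquired in every batch,
percentile scaling, hierarchical gating, knn/diffusion-map trajectory
inference with Leiden over-clustering and a partition-level (PAGA-style)
cluster graph, root-anchored pseudotime, cluster-constrained label transfer
across tissues, and composition statistics. `cytolineage` implements each
step as a plain, documented function and validates the whole chain against
a bundled generator of branching hematopoiesis with known ground truth.

## The core methods

**Anchor batch correction.** For each channel and batch, the anchor
(common) sample's median is shifted down to the cross-batch minimum
(`x ↦ x − δ_b`); values driven below zero are resampled from a half-normal
noise floor `|N(0, σ²)|`; each batch is then rescaled multiplicatively so
its anchor's 99.8th percentile matches the cross-batch minimum. The
transform fitted on each batch's anchor is applied to all samples of that
batch.

**Trajectory scaffold.** A knn graph (adaptive Gaussian kernel,
`w_ij = exp(−d_ij²/s_i s_j)` with `s_i` the distance to the k-th neighbor)
is embedded by diffusion maps (eigenpairs of the random-walk operator
`D⁻¹W`); a second knn graph in diffusion coordinates is partitioned by
Leiden at an over-clustering resolution; the cluster graph scores each
cluster pair by observed inter-cluster edges over their configuration-model
expectation `d_i d_j / 2m`; pseudotime is the diffusion distance from a
randomly chosen root HSC, with components not containing the root flagged
unreachable. Lineage arms (erythroid, myeloid) are re-analyzed in isolation
on arm-specific channel subsets.

**Constrained transfer.** Reference (bone-marrow) metacluster labels move
to query-tissue cells by majority vote of the k nearest reference cells
*within the same joint Leiden cluster*; clusters with too few reference
cells yield `unannotated`, so phenotypes absent from the reference are
never force-labeled.

**Downstream statistics.** 200 equal-count pseudotime bins with smoothed
finite-difference expression derivatives and inflection detection;
Manhattan distance between per-sample cluster-proportion vectors with
hierarchical clustering; two-sided Wilcoxon rank-sum tests (exact for small
groups) with local-FDR or Benjamini–Hochberg control; percent-positive
summaries.

## The simulator

`cytolineage.simulate` emulates branching hematopoiesis: an 11-population
tree (HSC→EMP1→EMP2→EMP3→erythroid; HSC→MPP→MP→MDP branching to pDCP→pDC
and a monocyte/cDC arm) with a latent differentiation time, logistic marker
ramps on the arcsinh scale for a 30-channel panel (CD34, CD38, CD71, CD84,
CD164, GATA1, GATA2, PBX1, RUNX1, IRF8, CEBPa, TdT, …), per-batch
gain/shift distortions with a replicated anchor sample per batch,
intensity-dependent zero inflation, and an instrument noise floor. Every
event carries its true population, branch, and latent time.

## Worked example

```python
import numpy as np
import scipy.stats
from sklearn.metrics import adjusted_rand_score
import cytolineage as cl

# 1. simulate a 3-batch, two-tissue CyTOF experiment (~18k cells)
events, truth, lineage, panel = cl.simulate_default(
    n_events_per_sample=2000, n_batches=3, seed=1)

# 2. arcsinh -> anchor batch correction -> 99.9th-percentile scaling
arc = cl.arcsinh_transform(events, cofactor=5.0)
corrected, transform = cl.correct_batches(arc, seed=1)
scaled = cl.percentile_scale(corrected)

# 3. knn -> diffusion map -> Leiden -> cluster graph -> pseudotime
pops = scaled.meta["population"].to_numpy()
res = cl.run_trajectory(scaled.values, pops, root_population="HSC", seed=1)

# 4. merge clusters into truth-majority metaclusters, score the recovery
mc = cl.majority_vote_map(res.partition, pops)
labels, _ = cl.apply_metaclusters(res.partition, mc)
edges = cl.population_connectivity(res.knn_diffusion, res.partition,
                                   mc.cluster_to_label)
```

Output of the full script (`seed=1`):

```
simulated 18000 events, 30 channels, 9 samples
anchor median spread across batches: 0.624 -> 0.071
85 Leiden clusters over 11 true populations
metacluster vs truth ARI: 0.906
lineage edges recovered: 10/10, spurious: 0
pseudotime vs latent time (all cells): Spearman rho = 0.831
  branch Ery: pseudotime vs latent time rho = 0.991
  branch Mono: pseudotime vs latent time rho = 0.994
  branch pDC: pseudotime vs latent time rho = 0.993
```

The anchor-median spread line shows the batch effect the correction
removed (arcsinh units, worst channel). The cluster graph, projected onto
truth-majority labels, recovers all ten lineage edges with none spurious,
and pseudotime orders each branch almost perfectly (the pooled correlation
is lower only because the two arms share the early pseudotime range).

## Command line

```sh
cytolineage simulate --out data/sim --events-per-sample 2000 --batches 3
cytolineage validate-config --config config.yaml
cytolineage run-all --config config.yaml
```

`run-all` executes every enabled stage from one YAML config and writes flat
TSV/YAML artifacts plus a manifest with per-artifact sha256 checksums;
re-running the same config reproduces the checksums bit for bit.

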