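# Methods

This note records the models, parameter choices, and numerical decisions
behind `cytolineage`, and what the synthetic validation does and does not
demonstrate about real mass-cytometry data.

## Scales and transforms

Raw ion counts are non-negative and right-skewed. All analysis happens on
the `arcsinh(x / c)` scale with cofactor `c = 5`, the CyTOF standard: the
transform is linear near zero and logarithmic for large counts. Every
`EventMatrix` carries a scale tag (`raw` → `arcsinh` → `scaled`) and each
stage asserts the tag it expects, which catches the classic mistake of
double-transforming or gating on the wrong scale. Percentile scaling
divides each channel by its 99.9th percentile computed over the pooled
analysis set (not per sample), so one outlier channel cannot dominate knn
distances; all-zero channels are left unchanged and logged.

## Anchor batch correction

One aliquot of a common sample is acquired in every batch. Per channel:

1. **Median alignment.** Each batch's anchor median is shifted down to the
   cross-batch minimum; the lowest batch is the implicit reference. The
   shift is exact: post-shift anchor medians agree to machine precision.
2. **Negative resampling.** Values pushed below zero are replaced by
   half-normal draws `|N(0, σ²)|`. σ is estimated, per batch and channel,
   as the RMS about zero of the post-shift *negative* anchor values — the
   width of the noise-floor block actually being replaced. An earlier
   candidate (SD of all sub-median values reflected about zero) is wrong on
   high-expression channels: a channel with median ≈ 3.5 gets σ ≈ 3, and
   resampled events spray across the entire signal range. With the
   floor-block estimator, corrected anchor ranks track the pre-distortion
   truth at Spearman ≥ 0.97 per channel under default gain+shift
   distortions, versus ≈ 0.80 uncorrected.
3. **Percentile normalization.** Each batch is rescaled multiplicatively so
   its anchor's 99.8th percentile equals the cross-batch minimum
   ("downward"); a multiplicative rescale cannot reintroduce negatives.

The resampling RNG is keyed by `(seed, batch, channel)`, so results are
independent of processing order. Medians and percentiles include zeros.
Correction operates on the arcsinh scale, where the anchor transform is
fitted alongside the other pre-processing steps; the QC report
(`correction_report`) records anchor medians and 99.8th percentiles before
and after, plus the residual cross-batch spread.

The correction-fidelity experiment injects *systematic* distortions only
(per-channel gains in [0.7, 1.4] and additive shifts, no stochastic floor
noise): rank correlation against pre-distortion truth measures how well the
batch component is removed, and no per-channel monotone transform can undo
per-event instrument noise. The simulator's default noise floor
(`floor_sd = 1`) stays on in every other experiment.

## The simulator

The generator is the package's ground-truth test surface, so its guiding
constraint is that the populations it claims exist are identifiable in its
output while differentiation remains a continuum.

- **Tree and latent time.** Eleven populations on two arms
  (HSC→EMP1→EMP2→EMP3→Ery; HSC→MPP→MP→MDP→{pDCP→pDC, Mono}), each owning a
  latent-time window in [0, 1] that tiles its arm; a cell draws its
  population from per-tissue weights and its time uniformly within the
  window. Trunk cells are assigned uniformly to one descendant branch.
- **Marker dynamics.** Each (marker, branch) follows a logistic
  `μ(t) = b + a·sigmoid((t − t0)/s)` on the arcsinh scale; amplitude may be
  negative. Discriminative ramps are centered on population boundaries
  (erythroid 0.2/0.4/0.6/0.8; myeloid 0.2/0.4/0.55/0.7/0.85) with
  transition width `4s ≈ 0.06–0.08` — about a third of a population's
  dwell time — so each boundary is covered by at least two steep ramps and
  roughly two-thirds of each population is plateau. Branch-specific curves
  agree on shared trunk populations (equal amplitudes before the branch
  point, or `t0` past it), so sibling populations just past a branch point
  are intentionally near-identical: a continuum branch point has no sharp
  edge, and the validation tolerates the corresponding sibling edge in the
  recovered topology.
- **Noise and zeros.** Gaussian noise (SD 0.22 arcsinh units) is added to
  the signal before inversion to raw counts (`5·sinh(·)`, log-normal-like).
  Zero inflation is intensity-dependent: `P(drop) = zi·exp(−count/10)` with
  `zi = 0.05`. Uniform dropout was rejected because high-abundance ion
  signals do not vanish in CyTOF, and simulating that artifact fabricates
  phenotype bridges between unrelated populations (it cost ~0.25 ARI and
  produced spurious lineage edges that no analysis could remove).
- **Batch effects.** Per (batch, channel) gain `g ∈ [0.7, 1.4]` and shift
  `d ∈ [0, 2]` raw counts (≈10% of a typical median signal), applied as
  `max(0, g·(signal + N(0, 1)) + d)` after zero inflation; the first batch
  is the identity reference. These magnitudes are fixture choices, not
  estimates of any instrument.
- **Anchors.** All anchor samples share one population/latent-time draw
  (keyed by the global seed only), so their truth-label composition is
  identical across batches and they differ only through noise and batch
  effects — exactly the premise of the correction.

What passing on this generator does *not* show: robustness to doublets,
bead/debris events, acquisition drift within a run, isotope spillover,
non-logistic (transient) marker dynamics, or population structure not
expressible as a tree.

## Trajectory scaffold

Defaults: `k = 15` for both knn graphs, `m = 15` diffusion components,
Leiden (RB-configuration) resolution 4.0, fine cluster-graph edge threshold
0.1. The resolution deliberately over-clusters (~120 clusters on 20k cells
for 11 populations) so metacluster merging never fuses small populations.
The edge threshold is used by the subset-connectivity filter; 0.05–0.2
behave identically on synthetic data, while ≥ 0.3 occasionally fragments a
true chain at this cluster granularity. All of these are config-exposed.

Numerical details: the diffusion operator is eigendecomposed through its
symmetric conjugate with a fixed start vector and a deterministic sign
convention (largest-magnitude entry positive), making embeddings bitwise
reproducible; disconnected graphs are embedded per component, never NaN;
near-tied eigenvalues set a `degenerate` flag. Pseudotime is the Euclidean
distance from a randomly selected root HSC in diffusion coordinates
rescaled by `λ/(1−λ)` per component (a graph-geodesic alternative is
config-selectable); cells outside the root's component are flagged
unreachable rather than assigned.

**Topology readout.** To compare a recovered cluster graph against the true
tree, clusters are labeled by their majority truth population, clusters
sharing a label are merged, and the observed/expected connectivity score is
recomputed on the merged partition. The maximum score over fine cluster
pairs was rejected: single interface clusters absorb boundary edges and the
statistic swings by orders of magnitude across seeds. Merged populations
pool thousands of cells, so expectations are large and scores small; the
population-edge threshold is 0.002, chosen with a two-fold margin against
both the weakest true edge and the strongest spurious edge over eight
seeds. In the erythroid re-analysis, cells enter by *cluster* (as the
selection is cluster-based, a few truth-MPP stowaways ride along inside
HSC-labeled clusters); the path test therefore evaluates edges among the
expected populations, and the MPP-addition test requires the MPP node to
attach only at HSC/EMP1, off the erythroid path.

## Label transfer

Votes are unweighted over the k = 15 nearest reference cells within the
query cell's joint Leiden cluster, with Euclidean distance in scaled marker
space (diffusion space is a config switch); a cluster must hold at least
`min_ref = k` reference cells to vote; ties go to the single nearest
neighbor (deterministic and order-independent). Self-transfer runs the
reference as its own query with leave-one-out candidate sets. The
novel-population experiment displaces a block of query cells by 5 pooled
SDs per channel; such cells land in clusters with no reference members and
must come back `unannotated`.

## Downstream statistics

- **Binning.** Cells are rank-ordered by pseudotime and split into 200
  equal-count bins (remainder spread over the leading bins). The weighted
  mean of bin means reproduces the overall mean to 1e-9.
- **Derivatives.** Bin means are smoothed by a centered moving average
  (window 9 bins — raw 200-bin means of finite samples are too noisy for
  sign-change detection; window 1 disables smoothing, in which case the
  rates integrate exactly back to the net expression change). Rates are
  finite differences against bin pseudotime midpoints and live at the
  B−1 bin boundaries; inflection points are sign changes of the smoothed
  rate. Localization is validated under simulator-like ramps (amplitude 3,
  steepness 0.02, noise 0.22): the maximal-rate boundary falls within ±3
  bins of the true inflection bin in ≥ 90% of replicates, counting a
  boundary as a hit if either adjacent bin is in the window.
- **Dissimilarity.** Manhattan distance on per-sample Leiden-proportion
  vectors (rows must sum to 1 within 1e-6), average-linkage hierarchical
  clustering; the metric and linkage are config-exposed.
- **Group tests.** Two-sided Wilcoxon rank-sum: exact for groups ≤ 12
  without ties, tie-corrected normal approximation otherwise. FDR control
  uses local FDR (empirical-null, via z-transformed p-values) for families
  of ≥ 50 features and Benjamini–Hochberg below that — local FDR is
  unstable for small families; the method used is recorded per table.
- **Percent positive.** Thresholds default to the 95th percentile of the
  pooled marker distribution, config-overridable; samples with an empty
  subset are reported missing, never zero.

## Pipeline and reproducibility

One YAML config drives all stages; a single global seed fans out to
per-stage streams by fixed offsets. Artifacts are flat TSV/YAML (FCS for
event data) and the manifest records a sha256 checksum per artifact; two
runs from one config are bit-identical. FCS IO is a minimal in-package
FCS 3.1 float32 reader/writer (single data segment, list mode) with sample
metadata in a TSV sidecar.

## Validation problem sizes

The validation experiments use ~20k cells (9 samples × 2223 events, 3
batches) for correction and trajectory recovery, ~13k for transfer, 20
replicates × 8k cells for inflection detection, and a ~11k-cell demo run
(executed twice) for determinism. These sizes put every recovery metric
well past its decision boundary while keeping a full validation run in the
low minutes on one CPU; the metrics quoted above (Spearman ≥ 0.97 per
channel, ARI ≈ 0.9, 10/10 lineage edges) are recomputed by the test suite
and `scripts/acceptance.py`, not asserted constants.

## Known limitations

Gates are axis-aligned rectangles (no polygons). The transfer classifier
uses unweighted votes. The cluster-graph score is a ratio to a
configuration-model expectation without a significance calibration. The
simulator's marker dynamics are monotone per branch, so transient
(up-then-down) expression exists in the data only across branch
comparisons, not within one branch. Real manual gate thresholds and the
original acquisition-scale batch magnitudes are not modeled.
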