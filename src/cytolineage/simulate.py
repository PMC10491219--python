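"""Synthetic multi-batch, multi-tissue mass-cytometry data with known lineage truth.

The generator emulates branching human hematopoiesis as measured by CyTOF:

* a rooted lineage tree (default: HSC -> EMP1 -> EMP2 -> EMP3 -> Ery on the
  erythroid/megakaryocyte arm, and HSC -> MPP -> MP -> MDP branching to
  pDCP -> pDC and to a monocyte/cDC arm terminal) with a latent
  differentiation time t in [0, 1];
* sigmoidal (logistic) marker dynamics along each branch on the arcsinh
  scale, so that populations are defined by coordinated marker ramps rather
  than discrete jumps — hematopoiesis as a continuum;
* per-batch multiplicative/additive channel distortions plus a Gaussian
  noise floor on the raw ion-count scale, the effects the anchor-based
  correction is designed to remove;
* one replicated anchor sample per batch, drawn from an identical population
  mixture so anchors differ across batches only through batch effects and
  measurement noise;
* zero inflation applied before batch distortion, producing the non-zero
  noise floor that the correction's negative-resampling step models.

Every event carries its ground truth (latent time, branch, population) so
that downstream clustering, pseudotime, transfer, and statistics can be
scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .events import EventMatrix, PanelDef

ROOT_POPULATION = "HSC"
DEFAULT_COFACTOR = 5.0
#: Raw-count scale over which zero-inflation (dropout) probability decays.
DROPOUT_SCALE = 10.0


# ---------------------------------------------------------------------------
# Lineage specification
# ---------------------------------------------------------------------------

class LineageError(ValueError):
    pass


@dataclass
class LineageSpec:
    """A rooted lineage tree with latent-time intervals and tissue mixtures.

    ``intervals`` maps each population to its latent-time window
    ``[t_start, t_end]``; a child's window starts at or after its parent's
    start.  ``tissue_weights`` maps tissue -> population -> sampling weight
    (non-negative, summing to 1 per tissue).
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    intervals: dict[str, tuple[float, float]]
    tissue_weights: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nodes = set(self.nodes)
        parents: dict[str, str] = {}
        for parent, child in self.edges:
            if parent not in nodes or child not in nodes:
                raise LineageError(f"edge ({parent}, {child}) references unknown node")
            if child in parents:
                raise LineageError(f"node {child} has two parents")
            parents[child] = parent
        roots = [n for n in self.nodes if n not in parents]
        if len(roots) != 1:
            raise LineageError(f"tree must have exactly one root, found {roots}")
        if len(self.edges) != len(self.nodes) - 1:
            raise LineageError("edge count must be node count - 1")
        # reachability from root rules out cycles among the child-unique edges
        seen = {roots[0]}
        frontier = [roots[0]]
        while frontier:
            cur = frontier.pop()
            for p, c in self.edges:
                if p == cur and c not in seen:
                    seen.add(c)
                    frontier.append(c)
        if seen != nodes:
            raise LineageError("graph is not a connected tree")
        for node in self.nodes:
            if node not in self.intervals:
                raise LineageError(f"no latent-time interval for {node}")
            lo, hi = self.intervals[node]
            if not (0.0 <= lo < hi <= 1.0):
                raise LineageError(f"bad interval {self.intervals[node]} for {node}")
        for child, parent in parents.items():
            if self.intervals[child][0] < self.intervals[parent][0]:
                raise LineageError(
                    f"{child} interval starts before its parent {parent}")
        for tissue, weights in self.tissue_weights.items():
            if set(weights) - nodes:
                raise LineageError(f"tissue {tissue} weights unknown nodes")
            vals = np.array([weights.get(n, 0.0) for n in self.nodes])
            if (vals < 0).any():
                raise LineageError(f"negative weight in tissue {tissue}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise LineageError(f"tissue {tissue} weights sum to {vals.sum()}")

    # -- structure helpers ---------------------------------------------------

    @property
    def root(self) -> str:
        children = {c for _, c in self.edges}
        return next(n for n in self.nodes if n not in children)

    def children(self, node: str) -> list[str]:
        return [c for p, c in self.edges if p == node]

    def leaves(self) -> list[str]:
        return [n for n in self.nodes if not self.children(n)]

    def path_to(self, node: str) -> list[str]:
        """Populations from the root down to ``node`` inclusive."""
        parents = {c: p for p, c in self.edges}
        path = [node]
        while path[-1] in parents:
            path.append(parents[path[-1]])
        return path[::-1]

    def branches(self) -> dict[str, list[str]]:
        """Leaf name -> ordered root-to-leaf population path."""
        return {leaf: self.path_to(leaf) for leaf in self.leaves()}

    def branches_through(self, node: str) -> list[str]:
        return sorted(leaf for leaf, path in self.branches().items() if node in path)

    def lineage_edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.edges}


def build_default_lineage(
    tissues: tuple[str, ...] = ("BM", "mPB"),
    early_boost: float = 2.0,
) -> LineageSpec:
    """The default two-arm hematopoietic tree (11 populations, 10 edges).

    Erythroid arm: HSC -> EMP1 -> EMP2 -> EMP3 -> Ery.  Myeloid arm:
    HSC -> MPP -> MP -> MDP, branching at MDP into pDCP -> pDC and into a
    monocyte/conventional-DC arm terminal (``Mono``).

    ``BM`` gets a balanced mixture; every other requested tissue gets the
    early compartments (HSC, MPP) up-weighted by ``early_boost``, emulating
    the early-HSPC enrichment seen in mobilized blood grafts.
    """
    nodes = ["HSC", "EMP1", "EMP2", "EMP3", "Ery",
             "MPP", "MP", "MDP", "pDCP", "pDC", "Mono"]
    edges = [("HSC", "EMP1"), ("EMP1", "EMP2"), ("EMP2", "EMP3"), ("EMP3", "Ery"),
             ("HSC", "MPP"), ("MPP", "MP"), ("MP", "MDP"),
             ("MDP", "pDCP"), ("pDCP", "pDC"), ("MDP", "Mono")]
    intervals = {
        "HSC": (0.00, 0.20),
        "EMP1": (0.20, 0.40), "EMP2": (0.40, 0.60),
        "EMP3": (0.60, 0.80), "Ery": (0.80, 1.00),
        "MPP": (0.20, 0.40), "MP": (0.40, 0.55), "MDP": (0.55, 0.70),
        "pDCP": (0.70, 0.85), "pDC": (0.85, 1.00),
        "Mono": (0.70, 1.00),
    }
    base = {"HSC": 0.10, "EMP1": 0.09, "EMP2": 0.09, "EMP3": 0.09, "Ery": 0.08,
            "MPP": 0.10, "MP": 0.09, "MDP": 0.09, "pDCP": 0.09, "pDC": 0.09,
            "Mono": 0.09}
    tissue_weights: dict[str, dict[str, float]] = {}
    for tissue in tissues:
        w = dict(base)
        if tissue != "BM":
            w["HSC"] *= early_boost
            w["MPP"] *= early_boost
        total = sum(w.values())
        tissue_weights[tissue] = {k: v / total for k, v in w.items()}
    return LineageSpec(nodes, edges, intervals, tissue_weights)


# ---------------------------------------------------------------------------
# Marker dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticCurve:
    """mu(t) = baseline + amplitude * sigmoid((t - t0) / steepness).

    Amplitude may be negative (downregulation); the curve is monotone in t.
    """

    baseline: float
    amplitude: float
    t0: float = 0.5
    steepness: float = 0.05

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise LineageError("steepness must be > 0")
        if not (0.0 <= self.t0 <= 1.0):
            raise LineageError("t0 must lie in [0, 1]")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.baseline + self.amplitude * expit(
            (np.asarray(t, dtype=float) - self.t0) / self.steepness)


@dataclass
class MarkerDynamics:
    """Per (marker, branch) logistic mean curves plus noise parameters.

    ``curves[marker][branch]`` gives the arcsinh-scale mean trajectory of a
    marker along a root-to-leaf branch.  ``noise_sd`` is the per-marker
    Gaussian SD added on the arcsinh scale; ``zero_inflation`` the per-marker
    probability of a structural zero (applied before batch distortion).
    """

    curves: dict[str, dict[str, LogisticCurve]]
    noise_sd: dict[str, float]
    zero_inflation: dict[str, float]

    def __post_init__(self) -> None:
        for marker, p in self.zero_inflation.items():
            if not (0.0 <= p <= 1.0):
                raise LineageError(f"zero-inflation for {marker} outside [0, 1]")
        for marker, sd in self.noise_sd.items():
            if sd < 0:
                raise LineageError(f"negative noise SD for {marker}")

    @property
    def markers(self) -> list[str]:
        return list(self.curves)

    def mean(self, marker: str, branch: str, t: np.ndarray) -> np.ndarray:
        return self.curves[marker][branch](t)

    def scaled(self, noise_sd: float | None = None,
               zero_inflation: float | None = None) -> "MarkerDynamics":
        """Copy with every marker's noise SD / zero-inflation overridden."""
        noise = (dict(self.noise_sd) if noise_sd is None
                 else {m: noise_sd for m in self.noise_sd})
        zi = (dict(self.zero_inflation) if zero_inflation is None
              else {m: zero_inflation for m in self.zero_inflation})
        return MarkerDynamics(self.curves, noise, zi)


#: (marker, class) rows of the default 30-channel panel: 20 surface, 10 regulators.
DEFAULT_PANEL_MARKERS: list[tuple[str, str]] = [
    ("CD34", "surface"), ("CD38", "surface"), ("CD45", "surface"),
    ("CD45RA", "surface"), ("CD33", "surface"), ("CD123", "surface"),
    ("HLA-DR", "surface"), ("CD71", "surface"), ("CD84", "surface"),
    ("CD164", "surface"), ("CD90", "surface"), ("CD49f", "surface"),
    ("CD117", "surface"), ("CD133", "surface"), ("CD105", "surface"),
    ("CD172ab", "surface"), ("CD235ab", "surface"), ("CD41", "surface"),
    ("CD7", "surface"), ("CD10", "surface"),
    ("GATA1", "regulator"), ("GATA2", "regulator"), ("PBX1", "regulator"),
    ("RUNX1", "regulator"), ("IRF8", "regulator"), ("CEBPa", "regulator"),
    ("TdT", "regulator"), ("FOXP1", "regulator"), ("BMI1", "regulator"),
    ("SPI1", "regulator"),
]

#: Trajectory channel subsets: markers informative for each arm.
ERYTHROID_CHANNELS = ["CD34", "CD38", "CD71", "CD84", "CD164", "CD235ab", "CD41",
                      "CD117", "CD133", "GATA1", "GATA2", "PBX1", "RUNX1", "BMI1",
                      "FOXP1"]
MYELOID_CHANNELS = ["CD34", "CD38", "CD45RA", "CD33", "CD123", "HLA-DR",
                    "CD172ab", "CD117", "CD133", "IRF8", "CEBPa", "TdT", "SPI1",
                    "PBX1", "BMI1"]


def build_default_panel() -> PanelDef:
    """30-channel panel mirroring the HSPC markers the analysis revolves around."""
    rows = []
    for marker, cls in DEFAULT_PANEL_MARKERS:
        rows.append({
            "marker": marker,
            "marker_class": cls,
            "use_clustering": True,
            "traj_erythroid": marker in ERYTHROID_CHANNELS,
            "traj_myeloid": marker in MYELOID_CHANNELS,
        })
    return PanelDef(pd.DataFrame(rows))


def build_default_dynamics(lineage: LineageSpec | None = None,
                           noise_sd: float = 0.22,
                           zero_inflation: float = 0.05) -> MarkerDynamics:
    """Default sigmoidal dynamics for the 30-marker panel on the default tree.

    Curves are written on the arcsinh(raw/5) scale.  Branch-distinguishing
    markers place their inflection at a population boundary of the arm they
    mark (e.g. GATA1 turns on at the EMP1|EMP2 boundary, IRF8 at the MDP
    junction, CD123 on the pDC arm), so each consecutive population pair is
    separated by at least two steep ramps — the idealized version of the
    coordinated regulator/surface ramps seen along real trajectories.
    """
    lineage = lineage or build_default_lineage()
    branches = sorted(lineage.branches())  # e.g. ["Ery", "Mono", "pDC"]

    def allb(b, a, t0=0.5, s=0.05):
        return {br: LogisticCurve(b, a, t0, s) for br in branches}

    def per(default: LogisticCurve, **overrides: LogisticCurve):
        out = {br: default for br in branches}
        out.update(overrides)
        return out

    flat = lambda b: LogisticCurve(b, 0.0, 0.5, 0.1)
    C = LogisticCurve
    # Discriminative ramps are centered on population boundaries of their arm
    # (erythroid boundaries 0.2/0.4/0.6/0.8; myeloid 0.2/0.4/0.55/0.7/0.85)
    # with transition width 4*steepness of roughly a third of a population's
    # dwell time, so populations are identifiable yet transitions continuous.
    # Branch-specific curves agree on shared trunk populations (same
    # amplitude before the branch point, or t0 past it).
    curves: dict[str, dict[str, LogisticCurve]] = {
        # pan/trunk markers
        "CD45": allb(3.0, 0.8, 0.5, 0.15),
        "CD34": per(C(4.0, -3.2, 0.85, 0.04),
                    Ery=C(4.0, -3.2, 0.80, 0.03), pDC=C(4.0, -3.2, 0.85, 0.03)),
        "CD133": allb(3.0, -2.4, 0.20, 0.02),
        "CD90": allb(2.5, -2.0, 0.20, 0.02),
        "CD49f": allb(2.2, -1.6, 0.20, 0.03),
        "CD117": per(C(2.5, -1.8, 0.55, 0.03), Ery=C(2.5, -1.8, 0.60, 0.03)),
        "CD105": allb(2.0, -1.2, 0.40, 0.03),
        "CD38": allb(0.8, 2.8, 0.40, 0.02),
        "BMI1": allb(2.5, -1.8, 0.20, 0.02),
        "FOXP1": allb(2.6, -1.6, 0.40, 0.03),
        "CD7": allb(0.3, 0.0, 0.5, 0.1),
        "CD10": allb(0.3, 0.0, 0.5, 0.1),
        # erythroid/megakaryocyte arm
        "RUNX1": per(C(1.0, 1.0, 0.55, 0.03), Ery=C(1.0, 2.2, 0.20, 0.02)),
        "GATA2": per(flat(0.5), Ery=C(0.5, 2.8, 0.20, 0.015)),
        "PBX1": per(C(1.8, -1.4, 0.40, 0.03), Ery=C(1.8, 1.4, 0.20, 0.02)),
        "GATA1": per(flat(0.2), Ery=C(0.2, 3.4, 0.40, 0.015)),
        "CD84": per(flat(0.3), Ery=C(0.3, 2.6, 0.40, 0.02)),
        "CD71": per(flat(0.5), Ery=C(0.5, 3.8, 0.60, 0.015)),
        "CD164": per(flat(0.8), Ery=C(0.8, 1.8, 0.60, 0.02)),
        "CD235ab": per(flat(0.1), Ery=C(0.1, 3.6, 0.80, 0.015)),
        "CD41": per(flat(0.2), Ery=C(0.2, 1.4, 0.80, 0.02)),
        # myeloid arm
        "CEBPa": per(C(0.4, 2.4, 0.20, 0.02), Ery=flat(0.4)),
        "SPI1": per(C(0.5, 2.6, 0.40, 0.02), Ery=flat(0.5)),
        "CD33": per(C(0.5, 2.6, 0.40, 0.02), Ery=flat(0.5)),
        "HLA-DR": per(C(0.6, 2.4, 0.55, 0.02), Ery=flat(0.6)),
        "IRF8": per(flat(0.3), pDC=C(0.3, 2.8, 0.55, 0.015),
                    Mono=C(0.3, 2.8, 0.55, 0.015)),
        "CD123": per(flat(0.4), pDC=C(0.4, 3.0, 0.73, 0.015)),
        "TdT": per(flat(0.2), pDC=C(0.2, 2.2, 0.75, 0.02)),
        "CD172ab": per(flat(0.4), Mono=C(0.4, 2.8, 0.73, 0.015)),
        "CD45RA": per(flat(0.8), pDC=C(0.8, 2.2, 0.85, 0.015),
                      Mono=C(0.8, 1.8, 0.78, 0.03)),
    }
    markers = [m for m, _ in DEFAULT_PANEL_MARKERS]
    curves = {m: curves[m] for m in markers}
    return MarkerDynamics(
        curves,
        noise_sd={m: noise_sd for m in markers},
        zero_inflation={m: zero_inflation for m in markers},
    )


# ---------------------------------------------------------------------------
# Batch effects and sample sheets
# ---------------------------------------------------------------------------

@dataclass
class BatchEffectSpec:
    """Per (batch, channel) raw-scale gain/shift plus a Gaussian noise floor.

    ``gains[batch][channel] > 0`` multiplies raw intensities; ``shifts`` adds
    on the raw scale; ``floor_sd`` is the SD of zero-mean Gaussian instrument
    noise added before gain/shift.  The reference batch has gain 1, shift 0.
    """

    gains: dict[str, dict[str, float]]
    shifts: dict[str, dict[str, float]]
    floor_sd: float = 1.0
    reference_batch: str | None = None

    def __post_init__(self) -> None:
        if self.floor_sd < 0:
            raise LineageError("noise-floor SD must be >= 0")
        for batch, by_ch in self.gains.items():
            for ch, g in by_ch.items():
                if g <= 0:
                    raise LineageError(f"gain for ({batch}, {ch}) must be > 0")
        if self.reference_batch is not None:
            ref_g = self.gains.get(self.reference_batch, {})
            ref_d = self.shifts.get(self.reference_batch, {})
            if any(g != 1.0 for g in ref_g.values()) or any(d != 0.0 for d in ref_d.values()):
                raise LineageError("reference batch must have gain 1 and shift 0")

    @property
    def batches(self) -> list[str]:
        return sorted(self.gains)

    def gain_vector(self, batch: str, channels: list[str]) -> np.ndarray:
        return np.array([self.gains[batch].get(c, 1.0) for c in channels])

    def shift_vector(self, batch: str, channels: list[str]) -> np.ndarray:
        return np.array([self.shifts.get(batch, {}).get(c, 0.0) for c in channels])


def identity_batch_effects(batches: list[str], floor_sd: float = 0.0) -> BatchEffectSpec:
    return BatchEffectSpec(
        gains={b: {} for b in batches}, shifts={b: {} for b in batches},
        floor_sd=floor_sd, reference_batch=sorted(batches)[0])


def build_default_batch_effects(
    batches: list[str],
    channels: list[str],
    seed: int,
    gain_range: tuple[float, float] = (0.7, 1.4),
    shift_max: float = 2.0,
    floor_sd: float = 1.0,
) -> BatchEffectSpec:
    """Random per-channel distortions; the first (sorted) batch is the reference.

    Gain bounds follow the fixture choice of moderate CyTOF batch effects
    (gain in [0.7, 1.4], additive shift at most ~10% of a typical median raw
    signal); these are plumbing defaults, not estimates from real data.
    """
    batches = sorted(batches)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 901]))
    gains: dict[str, dict[str, float]] = {batches[0]: {}}
    shifts: dict[str, dict[str, float]] = {batches[0]: {}}
    for batch in batches[1:]:
        g = rng.uniform(*gain_range, size=len(channels))
        d = rng.uniform(0.0, shift_max, size=len(channels))
        gains[batch] = dict(zip(channels, g.tolist()))
        shifts[batch] = dict(zip(channels, d.tolist()))
    return BatchEffectSpec(gains, shifts, floor_sd, reference_batch=batches[0])


@dataclass(frozen=True)
class SampleDef:
    sample_id: str
    batch_id: str
    tissue: str
    is_anchor: bool = False


def build_default_samples(n_batches: int = 3,
                          tissues: tuple[str, ...] = ("BM", "mPB"),
                          samples_per_tissue_per_batch: int = 1,
                          anchor_tissue: str = "BM") -> list[SampleDef]:
    """One anchor per batch plus per-tissue study samples in every batch."""
    samples = []
    for b in range(1, n_batches + 1):
        batch = f"batch{b}"
        samples.append(SampleDef(f"anchor_{batch}", batch, anchor_tissue, True))
        for tissue in tissues:
            for r in range(1, samples_per_tissue_per_batch + 1):
                samples.append(SampleDef(f"{tissue}_{batch}_s{r}", batch, tissue))
    return samples


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Row-aligned ground truth: per-event labels plus pre-distortion signal.

    ``table`` columns: sample_id, batch_id, tissue, is_anchor, population,
    branch, latent_time.  ``clean_values`` holds the raw-scale signal after
    zero inflation but before any batch distortion (the correction target).
    """

    table: pd.DataFrame
    clean_values: np.ndarray
    channels: list[str]


class SimulationError(ValueError):
    pass


def _simulate_sample_truth(lineage: LineageSpec, tissue: str, n: int,
                           rng: np.random.Generator,
                           mixture: dict[str, float] | None = None,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (population, branch, latent time) for one sample."""
    weights = mixture if mixture is not None else lineage.tissue_weights[tissue]
    nodes = lineage.nodes
    p = np.array([weights.get(node, 0.0) for node in nodes])
    pop_idx = rng.choice(len(nodes), size=n, p=p)
    pops = np.array(nodes, dtype=object)[pop_idx]
    t = np.empty(n)
    branch = np.empty(n, dtype=object)
    branch_options = {node: lineage.branches_through(node) for node in nodes}
    for node in nodes:
        mask = pops == node
        m = int(mask.sum())
        if not m:
            continue
        lo, hi = lineage.intervals[node]
        t[mask] = rng.uniform(lo, hi, size=m)
        opts = branch_options[node]
        branch[mask] = (np.array(opts, dtype=object)[rng.integers(len(opts), size=m)]
                        if len(opts) > 1 else opts[0])
    return pops, branch, t


def simulate_dataset(
    lineage: LineageSpec,
    dynamics: MarkerDynamics,
    batches: BatchEffectSpec,
    n_events_per_sample: int,
    samples: list[SampleDef],
    seed: int,
    cofactor: float = DEFAULT_COFACTOR,
) -> tuple[EventMatrix, SyntheticTruth]:
    """Generate a raw-scale EventMatrix plus row-aligned ground truth.

    Per event, the arcsinh-scale signal is mu(t) + N(0, sd) for its
    (marker, branch); the raw-scale signal is ``cofactor * sinh(signal)``
    (non-negative, right-skewed); structural zeros are applied; and finally
    the batch distortion ``max(0, gain * (signal + floor noise) + shift)``.

    Anchor samples share one population/latent-time draw (keyed by ``seed``
    alone), so their truth-label composition is identical across batches and
    they differ only through noise and batch effects.
    """
    if n_events_per_sample <= 0:
        raise SimulationError("event count per sample must be positive")
    batch_ids = {s.batch_id for s in samples}
    missing = batch_ids - set(batches.batches)
    if missing:
        raise SimulationError(f"samples reference unknown batches: {sorted(missing)}")
    for batch in sorted(batch_ids):
        anchors = [s for s in samples if s.batch_id == batch and s.is_anchor]
        if len(anchors) != 1:
            raise SimulationError(
                f"batch {batch} must have exactly one anchor sample, found {len(anchors)}")
    anchor_tissues = {s.tissue for s in samples if s.is_anchor}
    if len(anchor_tissues) > 1:
        raise SimulationError("all anchor samples must come from the same tissue")
    for s in samples:
        if s.tissue not in lineage.tissue_weights:
            raise SimulationError(f"unknown tissue {s.tissue!r} for sample {s.sample_id}")
    if len({s.sample_id for s in samples}) != len(samples):
        raise SimulationError("sample ids must be unique")

    markers = dynamics.markers
    n = n_events_per_sample
    # one shared truth draw for all anchors: identical composition across batches
    anchor_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA17C]))
    anchor_truth: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    if any(s.is_anchor for s in samples):
        anchor_tissue = next(iter(anchor_tissues))
        anchor_truth = _simulate_sample_truth(lineage, anchor_tissue, n, anchor_rng)

    value_parts, clean_parts, meta_parts = [], [], []
    for i, s in enumerate(samples):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, i]))
        if s.is_anchor:
            pops, branch, t = anchor_truth  # type: ignore[misc]
        else:
            pops, branch, t = _simulate_sample_truth(lineage, s.tissue, n, rng)
        signal = np.empty((n, len(markers)))
        branch_names = sorted(set(branch.tolist()))
        for j, marker in enumerate(markers):
            mu = np.empty(n)
            for br in branch_names:
                mask = branch == br
                mu[mask] = dynamics.mean(marker, br, t[mask])
            sd = dynamics.noise_sd[marker]
            if sd > 0:
                mu = mu + rng.normal(0.0, sd, size=n)
            signal[:, j] = mu
        clean = cofactor * np.sinh(signal)
        np.maximum(clean, 0.0, out=clean)
        # structural zeros, applied before batch distortion; dropout is
        # intensity-dependent (zi at zero signal, decaying with ion count),
        # since high-abundance ion signals do not vanish in mass cytometry
        zi = np.array([dynamics.zero_inflation[m] for m in markers])
        if (zi > 0).any():
            p_drop = zi[None, :] * np.exp(-clean / DROPOUT_SCALE)
            drop = rng.random(size=(n, len(markers))) < p_drop
            clean[drop] = 0.0
        gain = batches.gain_vector(s.batch_id, markers)
        shift = batches.shift_vector(s.batch_id, markers)
        raw = clean
        if batches.floor_sd > 0:
            raw = raw + rng.normal(0.0, batches.floor_sd, size=raw.shape)
        raw = np.maximum(0.0, gain[None, :] * raw + shift[None, :])
        value_parts.append(raw)
        clean_parts.append(clean)
        meta_parts.append(pd.DataFrame({
            "sample_id": s.sample_id, "batch_id": s.batch_id, "tissue": s.tissue,
            "is_anchor": s.is_anchor, "population": pops, "branch": branch,
            "latent_time": t,
        }))

    meta = pd.concat(meta_parts, ignore_index=True)
    events = EventMatrix(np.vstack(value_parts), markers, meta, scale="raw")
    truth = SyntheticTruth(meta.copy(), np.vstack(clean_parts), list(markers))
    return events, truth


def simulate_default(
    n_events_per_sample: int = 2500,
    n_batches: int = 3,
    tissues: tuple[str, ...] = ("BM", "mPB"),
    samples_per_tissue_per_batch: int = 1,
    seed: int = 0,
    noise_sd: float | None = None,
    zero_inflation: float | None = None,
    batch_effects: BatchEffectSpec | None = None,
) -> tuple[EventMatrix, SyntheticTruth, LineageSpec, PanelDef]:
    """Convenience wrapper wiring the default lineage, panel and dynamics."""
    lineage = build_default_lineage(tissues=tissues)
    panel = build_default_panel()
    dynamics = build_default_dynamics(lineage)
    if noise_sd is not None or zero_inflation is not None:
        dynamics = dynamics.scaled(noise_sd=noise_sd, zero_inflation=zero_inflation)
    samples = build_default_samples(n_batches, tissues, samples_per_tissue_per_batch)
    if batch_effects is None:
        batch_effects = build_default_batch_effects(
            sorted({s.batch_id for s in samples}), panel.markers, seed=seed)
    events, truth = simulate_dataset(
        lineage, dynamics, batch_effects, n_events_per_sample, samples, seed)
    return events, truth, lineage, panel
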