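"""Trajectory binning, derivatives, composition dissimilarity, and group tests.

Covers the downstream readouts of the pipeline: 200-bin pseudotime
expression summaries with finite-difference derivatives and inflection
detection; Manhattan-distance sample dissimilarity on Leiden-cluster
proportion vectors with hierarchical clustering; Wilcoxon rank-sum group
comparisons with FDR control (local FDR for large test families,
Benjamini-Hochberg for small ones); and percent-positive summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist, squareform
from scipy.stats import mannwhitneyu, norm
from statsmodels.stats.multitest import local_fdr, multipletests

log = logging.getLogger(__name__)

DEFAULT_BINS = 200
DEFAULT_SMOOTHING_WINDOW = 9
LOCAL_FDR_MIN_FEATURES = 50


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pseudotime binning
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrajectory:
    """Equal-count pseudotime bins with per-bin marker means.

    ``means`` is bins x markers; ``midpoints`` the mean pseudotime per bin;
    ``counts`` the bin occupancies (equal +/-1, larger bins first).
    """

    means: np.ndarray
    midpoints: np.ndarray
    counts: np.ndarray
    markers: list[str]

    @property
    def n_bins(self) -> int:
        return self.means.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.means, columns=self.markers)
        df.insert(0, "pseudotime_mid", self.midpoints)
        df.insert(0, "n_cells", self.counts)
        df.index.name = "bin"
        return df


def bin_pseudotime(pseudotime: np.ndarray, X: np.ndarray, markers: list[str],
                   n_bins: int = DEFAULT_BINS) -> BinnedTrajectory:
    """Rank cells by pseudotime and split into ``n_bins`` equal-count bins.

    Cells with non-finite pseudotime are dropped.  With ``n`` cells and
    remainder ``r = n mod n_bins``, the first ``r`` bins hold one extra cell.
    Per-bin values are the mean expression of member cells.
    """
    if n_bins < 2:
        raise StatsError("need at least 2 bins")
    pseudotime = np.asarray(pseudotime, dtype=float)
    X = np.asarray(X, dtype=float)
    keep = np.isfinite(pseudotime)
    pseudotime, X = pseudotime[keep], X[keep]
    n = pseudotime.size
    if n < n_bins:
        raise StatsError(f"{n} cells cannot fill {n_bins} bins")
    order = np.argsort(pseudotime, kind="stable")
    base, r = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:r] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    means = np.empty((n_bins, X.shape[1]))
    mids = np.empty(n_bins)
    for b in range(n_bins):
        rows = order[bounds[b]:bounds[b + 1]]
        means[b] = X[rows].mean(axis=0)
        mids[b] = pseudotime[rows].mean()
    return BinnedTrajectory(means, mids, sizes, list(markers))


# ---------------------------------------------------------------------------
# Derivatives and inflection points
# ---------------------------------------------------------------------------

@dataclass
class DerivativeTable:
    """Finite-difference expression rates at the B-1 bin boundaries.

    ``rates[i, j]`` is marker j's rate of change between (smoothed) bins i
    and i+1, evaluated against bin pseudotime midpoints.  ``inflections``
    lists, per marker, boundary indices where the rate changes sign;
    ``max_rate_bin`` is the boundary of maximal absolute rate per marker.
    """

    rates: np.ndarray
    boundary_mid: np.ndarray
    markers: list[str]
    inflections: dict[str, list[int]]
    max_rate_bin: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, columns=self.markers)
        df.insert(0, "pseudotime_mid", self.boundary_mid)
        df.index.name = "boundary"
        return df


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shorter windows at ends)."""
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def expression_derivative(binned: BinnedTrajectory,
                          smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                          ) -> DerivativeTable:
    """Smooth bin means, then finite-difference them along pseudotime.

    ``smoothing_window`` must be odd (a centered window) and smaller than
    the bin count; ``smoothing_window=1`` disables smoothing, in which case
    the rates satisfy the discrete fundamental theorem exactly: the sum of
    rate x step over all boundaries equals last-bin mean minus first-bin
    mean.  Inflection points are sign changes of the smoothed rate; per
    monotone run the boundary of maximal |rate| is also reported.
    """
    B = binned.n_bins
    if B < 3:
        raise StatsError("need at least 3 bins to differentiate")
    if smoothing_window % 2 == 0:
        raise StatsError("smoothing window must be odd")
    if smoothing_window >= B:
        raise StatsError("smoothing window must be smaller than the bin count")
    x = binned.midpoints
    dx = np.diff(x)
    if (dx <= 0).any():
        # equal-count bins of heavily tied pseudotime can produce zero steps
        dx = np.where(dx <= 0, np.finfo(float).eps, dx)
    rates = np.empty((B - 1, len(binned.markers)))
    inflections: dict[str, list[int]] = {}
    max_rate: dict[str, int] = {}
    for j, marker in enumerate(binned.markers):
        y = binned.means[:, j]
        if smoothing_window > 1:
            y = _moving_average(y, smoothing_window)
        d = np.diff(y) / dx
        rates[:, j] = d
        sign = np.sign(d)
        flips = [i + 1 for i in range(len(d) - 1)
                 if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]]
        inflections[marker] = flips
        max_rate[marker] = int(np.argmax(np.abs(d)))
    boundary_mid = (x[:-1] + x[1:]) / 2.0
    return DerivativeTable(rates, boundary_mid, list(binned.markers),
                           inflections, max_rate)


# ---------------------------------------------------------------------------
# Sample dissimilarity
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    matrix: pd.DataFrame
    metric: str
    linkage: np.ndarray          # scipy linkage (merge order + heights)
    linkage_method: str

    def dendrogram_order(self) -> list[str]:
        order = sch.leaves_list(self.linkage)
        return [self.matrix.index[i] for i in order]


def sample_dissimilarity(proportions: pd.DataFrame,
                         linkage: str = "average") -> DistanceMatrix:
    """Pairwise Manhattan distance on composition vectors + dendrogram.

    ``proportions`` rows are per-sample cluster-proportion vectors and must
    sum to 1 (within 1e-6).  D(a, b) = sum_c |p_ac - p_bc|, bounded by 2.
    """
    if proportions.shape[0] < 2:
        raise StatsError("need at least two samples")
    sums = proportions.sum(axis=1).to_numpy()
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise StatsError("composition rows must sum to 1")
    D = cdist(proportions.to_numpy(), proportions.to_numpy(), metric="cityblock")
    Z = sch.linkage(squareform(D, checks=False), method=linkage)
    matrix = pd.DataFrame(D, index=proportions.index, columns=proportions.index)
    return DistanceMatrix(matrix, "manhattan", Z, linkage)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

EXACT_MAX_N = 12


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p: exact for small tie-free groups, else normal."""
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = ("exact" if (x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N
                          and not has_ties) else "asymptotic")
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(values: pd.DataFrame, groups: np.ndarray | pd.Series,
                   fdr_method: str = "auto") -> pd.DataFrame:
    """Per-feature two-group Wilcoxon rank-sum tests with FDR control.

    ``values`` is samples x features; ``groups`` assigns each sample to one
    of exactly two groups with >= 2 samples each.  p-values are exact for
    group sizes <= 12 without ties and use the tie-corrected normal
    approximation otherwise.  q-values use local FDR (empirical null) when
    the family has >= 50 features, Benjamini-Hochberg below that;
    ``fdr_method`` can force ``"bh"`` or ``"local"``.  The method used is
    recorded in the output.
    """
    groups = np.asarray(groups)
    names = np.unique(groups)
    if names.size != 2:
        raise StatsError(f"need exactly two groups, got {names.tolist()}")
    a_mask, b_mask = groups == names[0], groups == names[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise StatsError("each group needs at least 2 samples")

    rows = []
    for feature in values.columns:
        x = values.loc[a_mask, feature].to_numpy(dtype=float)
        y = values.loc[b_mask, feature].to_numpy(dtype=float)
        stat, p = _wilcoxon_rank_sum(x, y)
        rows.append({"feature": feature,
                     f"median_{names[0]}": float(np.median(x)),
                     f"median_{names[1]}": float(np.median(y)),
                     "statistic": stat, "p": p})
    out = pd.DataFrame(rows)

    n_features = len(out)
    if fdr_method == "auto":
        fdr_method = "local" if n_features >= LOCAL_FDR_MIN_FEATURES else "bh"
    if fdr_method == "local":
        # two-sided p -> |z| against the theoretical null, signed by direction
        p = out["p"].clip(1e-300, 1.0).to_numpy()
        direction = np.sign(
            out[f"median_{names[0]}"].to_numpy() - out[f"median_{names[1]}"].to_numpy())
        z = norm.isf(p / 2.0) * np.where(direction == 0, 1.0, direction)
        try:
            out["q"] = np.clip(local_fdr(z), 0.0, 1.0)
        except Exception:  # empirical-null fit can fail on tiny/degenerate input
            log.warning("local FDR estimation failed; falling back to BH")
            fdr_method = "bh"
    if fdr_method == "bh":
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    elif fdr_method != "local":
        raise StatsError(f"unknown FDR method {fdr_method!r}")
    out["fdr_method"] = fdr_method
    return out


# ---------------------------------------------------------------------------
# Percent positive
# ---------------------------------------------------------------------------

def default_positivity_thresholds(X: np.ndarray, markers: list[str],
                                  q: float = 95.0) -> dict[str, float]:
    """Positivity gates at the q-th percentile of each pooled marker."""
    cuts = np.percentile(X, q, axis=0)
    return dict(zip(markers, cuts.tolist()))


def percent_positive(X: np.ndarray, markers: list[str],
                     sample_ids: np.ndarray | pd.Series,
                     subset: np.ndarray,
                     thresholds: dict[str, float]) -> pd.DataFrame:
    """Per sample and marker: % of subset cells above the marker's threshold.

    Samples whose subset is empty are reported as missing (NaN, with a
    warning), never as zero.
    """
    subset = np.asarray(subset, dtype=bool)
    sample_ids = np.asarray(sample_ids)
    missing = [m for m in markers if m not in thresholds]
    if missing:
        raise StatsError(f"no threshold for markers: {missing}")
    col = {m: i for i, m in enumerate(markers)}
    rows = {}
    for sample in np.unique(sample_ids):
        mask = subset & (sample_ids == sample)
        if not mask.any():
            log.warning("percent_positive: sample %s has an empty subset", sample)
            rows[sample] = {m: np.nan for m in markers}
            continue
        block = X[mask]
        rows[sample] = {m: 100.0 * float(np.mean(block[:, col[m]] > thresholds[m]))
                        for m in markers}
    out = pd.DataFrame.from_dict(rows, orient="index")[list(markers)]
    out.index.name = "sample_id"
    return out
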