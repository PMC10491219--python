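"""Anchor-sample batch correction.

A single anchor (common) sample is acquired in every batch.  Per channel:

1. the anchor median is computed per batch and every batch is shifted
   *downward* so all anchor medians equal the cross-batch minimum;
2. values driven below zero by the shift are resampled from a half-normal
   |N(0, sigma^2)| noise floor, with sigma estimated from the spread of the
   anchor events the shift drives negative (the floor being replaced);
3. each batch is rescaled multiplicatively so its anchor's 99.8th percentile
   matches the cross-batch minimum post-shift 99.8th percentile
   (normalization *downward*).

The transform fitted on each batch's anchor is applied to every sample of
that batch.  Correction operates on the arcsinh scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .events import EventMatrix

PERCENTILE = 99.8


class BatchCorrectionError(ValueError):
    pass


@dataclass
class AnchorTransform:
    """Fitted per-(batch, channel) correction parameters.

    ``shift[batch]`` (delta, subtracted), ``observed_p[batch]`` (post-shift
    anchor 99.8th percentile P_o), ``target_p`` (cross-batch minimum P_t),
    and ``noise_sd[batch]`` (sigma for half-normal negative resampling) are
    each channel-length arrays aligned with ``channels``.
    """

    channels: list[str]
    shift: dict[str, np.ndarray]
    observed_p: dict[str, np.ndarray]
    target_p: np.ndarray
    noise_sd: dict[str, np.ndarray]
    percentile: float = PERCENTILE

    @property
    def batches(self) -> list[str]:
        return sorted(self.shift)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for batch in self.batches:
            for j, ch in enumerate(self.channels):
                rows.append({
                    "batch_id": batch, "channel": ch,
                    "median_shift": self.shift[batch][j],
                    "observed_p": self.observed_p[batch][j],
                    "target_p": self.target_p[j],
                    "noise_sd": self.noise_sd[batch][j],
                })
        return pd.DataFrame(rows)

    def to_yaml(self, path) -> None:
        payload = {
            "percentile": float(self.percentile),
            "channels": list(self.channels),
            "target_p": [float(x) for x in self.target_p],
            "batches": {
                b: {
                    "median_shift": [float(x) for x in self.shift[b]],
                    "observed_p": [float(x) for x in self.observed_p[b]],
                    "noise_sd": [float(x) for x in self.noise_sd[b]],
                } for b in self.batches
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _noise_floor_sd(x: np.ndarray, delta: float) -> float:
    """Noise-floor SD proxy: RMS of the anchor values the shift drives negative.

    The events below the median shift ``delta`` are the channel's noise-floor
    block — exactly the events the resampling step will replace.  Reflecting
    their post-shift values about zero gives a symmetric sample whose SD
    (the RMS) sets the half-normal scale, so resampled values reproduce the
    width of the floor being replaced instead of spraying into the signal
    range.
    """
    neg = x[x < delta] - delta
    if neg.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(neg**2)))


def split_anchors(events: EventMatrix) -> dict[str, EventMatrix]:
    """Anchor events per batch; errors unless each batch has exactly one anchor."""
    if "is_anchor" not in events.meta.columns:
        raise BatchCorrectionError("metadata carries no is_anchor column")
    anchors: dict[str, EventMatrix] = {}
    for batch in sorted(events.meta["batch_id"].unique()):
        in_batch = events.meta["batch_id"] == batch
        anchor_samples = events.meta.loc[in_batch & events.meta["is_anchor"],
                                         "sample_id"].unique()
        if len(anchor_samples) != 1:
            raise BatchCorrectionError(
                f"batch {batch} has {len(anchor_samples)} anchor samples, expected 1")
        mask = in_batch & (events.meta["sample_id"] == anchor_samples[0])
        anchors[batch] = events.subset_rows(mask.to_numpy())
    return anchors


def fit_anchor_transform(anchors: dict[str, EventMatrix],
                         percentile: float = PERCENTILE) -> AnchorTransform:
    """Fit the shift / resample / rescale transform from per-batch anchors.

    Target median per channel = cross-batch minimum anchor median (all
    batches shift downward); target percentile = cross-batch minimum
    post-shift anchor percentile (all batches rescale downward).
    """
    if not anchors:
        raise BatchCorrectionError("no anchors supplied")
    batches = sorted(anchors)
    channels = list(anchors[batches[0]].channels)
    for batch in batches:
        if list(anchors[batch].channels) != channels:
            raise BatchCorrectionError("anchors must share an identical channel list")
        if anchors[batch].scale != "arcsinh":
            raise BatchCorrectionError("anchor correction expects arcsinh-scale data")

    medians = {b: np.median(anchors[b].values, axis=0) for b in batches}
    target_median = np.min(np.vstack([medians[b] for b in batches]), axis=0)
    shift = {b: medians[b] - target_median for b in batches}
    observed_p = {
        b: np.percentile(anchors[b].values - shift[b][None, :], percentile, axis=0)
        for b in batches
    }
    target_p = np.min(np.vstack([observed_p[b] for b in batches]), axis=0)
    noise_sd = {
        b: np.array([_noise_floor_sd(anchors[b].values[:, j], shift[b][j])
                     for j in range(len(channels))])
        for b in batches
    }
    return AnchorTransform(channels, shift, observed_p, target_p, noise_sd,
                           percentile=percentile)


def apply_anchor_transform(events: EventMatrix, transform: AnchorTransform,
                           seed: int) -> EventMatrix:
    """Apply the per-batch transform to every sample of each batch.

    Per channel and batch: subtract the median shift; replace negatives by
    half-normal |N(0, sigma^2)| draws; rescale by P_t / P_o.  The resampling
    RNG stream is keyed by (batch, channel), so results do not depend on the
    order batches are processed in.  No negative values remain.
    """
    if list(events.channels) != transform.channels:
        raise BatchCorrectionError("event channels do not match the fitted transform")
    known = set(transform.batches)
    unknown = set(events.meta["batch_id"].unique()) - known
    if unknown:
        raise BatchCorrectionError(f"events reference unfitted batches: {sorted(unknown)}")

    out = events.values.copy()
    batch_col = events.meta["batch_id"].to_numpy()
    for bi, batch in enumerate(transform.batches):
        rows = np.flatnonzero(batch_col == batch)
        if rows.size == 0:
            continue
        block = out[rows] - transform.shift[batch][None, :]
        for j in range(len(transform.channels)):
            neg = block[:, j] < 0
            if not neg.any():
                continue
            sigma = transform.noise_sd[batch][j]
            if sigma == 0:
                block[neg, j] = 0.0
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 2, bi, j]))
            block[neg, j] = np.abs(rng.normal(0.0, sigma, size=int(neg.sum())))
        scale = np.where(transform.observed_p[batch] > 0,
                         transform.target_p / np.where(
                             transform.observed_p[batch] > 0,
                             transform.observed_p[batch], 1.0),
                         1.0)
        out[rows] = block * scale[None, :]
    return events.with_values(out)


def correct_batches(events: EventMatrix, seed: int,
                    percentile: float = PERCENTILE,
                    ) -> tuple[EventMatrix, AnchorTransform]:
    """Fit on the anchors found in ``events`` and apply to all samples."""
    transform = fit_anchor_transform(split_anchors(events), percentile=percentile)
    return apply_anchor_transform(events, transform, seed=seed), transform


def correction_report(before: EventMatrix, after: EventMatrix) -> pd.DataFrame:
    """Per (batch, channel) anchor medians / percentiles before vs after.

    The summary row (batch_id = "_spread_") reports, per channel, the
    cross-batch max-min spread of anchor medians before and after, the
    standard QC readout of how much batch effect the correction removed.
    """
    if list(before.channels) != list(after.channels):
        raise BatchCorrectionError("channel mismatch between before and after")
    anchors_before = split_anchors(before)
    anchors_after = split_anchors(after)
    rows = []
    med_b, med_a = {}, {}
    for batch in sorted(anchors_before):
        mb = np.median(anchors_before[batch].values, axis=0)
        ma = np.median(anchors_after[batch].values, axis=0)
        pb = np.percentile(anchors_before[batch].values, PERCENTILE, axis=0)
        pa = np.percentile(anchors_after[batch].values, PERCENTILE, axis=0)
        med_b[batch], med_a[batch] = mb, ma
        for j, ch in enumerate(before.channels):
            rows.append({"batch_id": batch, "channel": ch,
                         "median_before": mb[j], "median_after": ma[j],
                         "p998_before": pb[j], "p998_after": pa[j]})
    spread_b = np.ptp(np.vstack(list(med_b.values())), axis=0)
    spread_a = np.ptp(np.vstack(list(med_a.values())), axis=0)
    for j, ch in enumerate(before.channels):
        rows.append({"batch_id": "_spread_", "channel": ch,
                     "median_before": spread_b[j], "median_after": spread_a[j],
                     "p998_before": np.nan, "p998_after": np.nan})
    return pd.DataFrame(rows)
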