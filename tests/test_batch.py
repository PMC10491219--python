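"""Anchor-sample batch correction: fit, apply, and QC report."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import cytolineage as cl
from cytolineage.batch import BatchCorrectionError
from conftest import make_events


def anchor(values, batch, sample=None):
    return make_events(np.asarray(values, dtype=float).reshape(-1, 1),
                       channels=["m"],
                       sample_id=sample or f"anchor_{batch}", batch_id=batch,
                       scale="arcsinh", is_anchor=True)


class TestFit:
    def test_shift_is_median_minus_cross_batch_minimum(self):
        # anchors engineered to medians 1.5 / 2.0 / 1.8
        anchors = {
            "A": anchor([1.0, 1.5, 2.0], "A"),
            "B": anchor([1.5, 2.0, 2.5], "B"),
            "C": anchor([1.3, 1.8, 2.3], "C"),
        }
        tf = cl.fit_anchor_transform(anchors)
        assert tf.shift["A"][0] == pytest.approx(0.0)
        assert tf.shift["B"][0] == pytest.approx(0.5)
        assert tf.shift["C"][0] == pytest.approx(0.3)

    def test_single_batch_is_identity(self):
        anchors = {"A": anchor(np.linspace(0, 3, 100), "A")}
        tf = cl.fit_anchor_transform(anchors)
        assert tf.shift["A"][0] == 0.0
        assert tf.observed_p["A"][0] == tf.target_p[0]

    def test_identical_anchors_all_zero_shift(self):
        x = np.linspace(0, 3, 101)
        tf = cl.fit_anchor_transform({b: anchor(x, b) for b in "ABC"})
        for b in "ABC":
            assert tf.shift[b][0] == 0.0

    def test_wrong_scale_rejected(self):
        bad = anchor([1.0, 2.0], "A")
        bad.scale = "raw"
        with pytest.raises(BatchCorrectionError, match="arcsinh"):
            cl.fit_anchor_transform({"A": bad})


class TestSplitAnchors:
    def test_requires_exactly_one_anchor_per_batch(self, small_dataset):
        events, *_ = small_dataset
        arc = cl.arcsinh_transform(events)
        anchors = cl.split_anchors(arc)
        assert set(anchors) == set(events.meta["batch_id"].unique())
        no_anchor = arc.subset_rows((~arc.meta["is_anchor"]).to_numpy())
        with pytest.raises(BatchCorrectionError, match="anchor"):
            cl.split_anchors(no_anchor)


class TestApply:
    def test_pure_shift_when_nothing_resampled(self):
        x = np.linspace(1.0, 3.0, 101)
        anchors = {"A": anchor(x, "A"), "B": anchor(x + 0.5, "B")}
        tf = cl.fit_anchor_transform(anchors)
        events = make_events((x + 0.5)[:, None], channels=["m"], batch_id="B",
                             scale="arcsinh")
        out = cl.apply_anchor_transform(events, tf, seed=0)
        # all values stay >= 0 after the 0.5 shift and P_o == P_t exactly
        np.testing.assert_allclose(out.values[:, 0], x, atol=1e-12)

    def test_resampled_values_follow_half_normal(self):
        # event at 0.2 with shift 0.5 and sigma 0.1 -> |N(0, 0.01)| draw
        tf = cl.AnchorTransform(
            channels=["m"], shift={"B": np.array([0.5])},
            observed_p={"B": np.array([2.0])}, target_p=np.array([2.0]),
            noise_sd={"B": np.array([0.1])})
        events = make_events(np.full((5000, 1), 0.2), channels=["m"],
                             batch_id="B", scale="arcsinh")
        out = cl.apply_anchor_transform(events, tf, seed=1)
        vals = out.values[:, 0]
        assert (vals >= 0).all()
        # half-normal tail bound: P(|N(0, 0.01)| >= 0.5) < 1e-6
        assert np.mean(vals < 0.5) > 0.999
        assert np.mean(vals) == pytest.approx(0.1 * np.sqrt(2 / np.pi), rel=0.05)

    def test_deterministic_under_seed(self, small_dataset):
        events, *_ = small_dataset
        arc = cl.arcsinh_transform(events)
        a, _ = cl.correct_batches(arc, seed=5)
        b, _ = cl.correct_batches(arc, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_unknown_batch_rejected(self):
        anchors = {"A": anchor(np.linspace(0, 3, 50), "A")}
        tf = cl.fit_anchor_transform(anchors)
        events = make_events(np.ones((5, 1)), channels=["m"], batch_id="Z",
                             scale="arcsinh")
        with pytest.raises(BatchCorrectionError, match="Z"):
            cl.apply_anchor_transform(events, tf, seed=0)


@pytest.fixture(scope="module")
def corrected(small_dataset):
    events, truth, lineage, panel = small_dataset
    arc = cl.arcsinh_transform(events)
    out, tf = cl.correct_batches(arc, seed=11)
    return arc, out, tf, truth


class TestCorrectionInvariants:

    def test_post_shift_anchor_medians_identical(self, corrected):
        arc, out, tf, _ = corrected
        anchors = cl.split_anchors(arc)
        medians = np.vstack([
            np.median(anchors[b].values - tf.shift[b][None, :], axis=0)
            for b in tf.batches])
        assert np.max(np.ptp(medians, axis=0)) <= 1e-9

    def test_no_negative_values(self, corrected):
        _, out, _, _ = corrected
        assert (out.values >= 0).all()

    def test_resampled_fraction_equals_negative_fraction(self, corrected):
        arc, out, tf, _ = corrected
        for b in tf.batches:
            mask = (arc.meta["batch_id"] == b).to_numpy()
            shifted = arc.values[mask] - np.asarray(tf.shift[b])[None, :]
            # resampling replaces exactly the post-shift negatives; everything
            # else is an order-preserving affine map of the input
            scale = tf.target_p[None, :] / tf.observed_p[b][None, :]
            expected = shifted * scale
            changed = ~np.isclose(out.values[mask], expected, atol=1e-12)
            assert np.array_equal(changed, shifted < 0)

    def test_percentile_matches_target_within_order_statistic_gap(self, corrected):
        arc, out, tf, _ = corrected
        anchors_after = cl.split_anchors(out)
        for b in tf.batches:
            vals = anchors_after[b].values
            n = vals.shape[0]
            rank = int(round(0.998 * (n - 1)))
            achieved = np.percentile(vals, 99.8, axis=0)
            for j in range(vals.shape[1]):
                col = np.sort(vals[:, j])
                gap = col[min(rank + 1, n - 1)] - col[max(rank - 1, 0)]
                assert abs(achieved[j] - tf.target_p[j]) <= gap + 1e-9, (b, j)

    def test_report_shows_spread_reduction_under_big_gain(self, lineage):
        dyn = cl.build_default_dynamics(lineage)
        markers = dyn.markers
        effects = cl.BatchEffectSpec(
            gains={"A": {}, "B": {m: 2.0 for m in markers}},
            shifts={"A": {}, "B": {}}, floor_sd=0.0, reference_batch="A")
        samples = [cl.SampleDef("anchor_A", "A", "BM", True),
                   cl.SampleDef("anchor_B", "B", "BM", True)]
        events, _ = cl.simulate_dataset(lineage, dyn, effects, 3000, samples,
                                        seed=2)
        arc = cl.arcsinh_transform(events)
        out, _ = cl.correct_batches(arc, seed=2)
        report = cl.correction_report(arc, out)
        spread = report[report["batch_id"] == "_spread_"]
        informative = spread["median_before"] > 0.1
        ratio = (spread.loc[informative, "median_before"]
                 / spread.loc[informative, "median_after"].clip(lower=1e-12))
        assert np.median(ratio) >= 10
        assert (ratio >= 1).all()

    def test_identity_transform_preserves_values(self):
        x = np.linspace(0.1, 3.0, 200)
        anchors = {"A": anchor(x, "A")}
        tf = cl.fit_anchor_transform(anchors)
        events = make_events(x[:, None], channels=["m"], batch_id="A",
                             scale="arcsinh")
        out = cl.apply_anchor_transform(events, tf, seed=0)
        np.testing.assert_allclose(out.values, events.values, atol=1e-12)
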