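"""Shared fixtures: small synthetic data sets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cytolineage as cl


@pytest.fixture(scope="session")
def lineage():
    return cl.build_default_lineage()


@pytest.fixture(scope="session")
def panel():
    return cl.build_default_panel()


@pytest.fixture(scope="session")
def small_dataset():
    """~6k events, 3 batches x (anchor + BM + mPB), default distortions."""
    events, truth, lineage, panel = cl.simulate_default(
        n_events_per_sample=700, n_batches=3, seed=11)
    return events, truth, lineage, panel


@pytest.fixture(scope="session")
def corrected_scaled(small_dataset):
    """The small dataset taken through arcsinh -> correction -> scaling."""
    events, truth, lineage, panel = small_dataset
    arc = cl.arcsinh_transform(events)
    corrected, transform = cl.correct_batches(arc, seed=11)
    scaled = cl.percentile_scale(corrected)
    return scaled, truth, lineage, panel


def make_events(values, channels=None, sample_id="s1", batch_id="b1",
                tissue="BM", scale="raw", **meta_cols):
    """Minimal EventMatrix around a raw array for unit tests."""
    values = np.asarray(values, dtype=float)
    if channels is None:
        channels = [f"ch{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({
        "sample_id": sample_id, "batch_id": batch_id, "tissue": tissue,
        **meta_cols,
    }, index=range(values.shape[0]))
    return cl.EventMatrix(values, channels, meta, scale=scale)
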