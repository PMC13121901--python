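"""Shared fixtures: small synthetic studies and event matrices."""

import numpy as np
import pytest

from cytoconsensus import (
    ChannelPanel,
    EventMatrix,
    generate_study,
    reference_design,
)
from cytoconsensus.io_model import Scale

#: event counts small enough for fast tests but large enough for stable
#: peak detection and binning
SMALL_EVENTS = {"bead": 800, "unlabeled": 2500, "labeled": 2500}
TINY_EVENTS = {"bead": 400, "unlabeled": 1200, "labeled": 1200}


@pytest.fixture(scope="session")
def small_design():
    return reference_design(events_per_sample=SMALL_EVENTS)


@pytest.fixture(scope="session")
def small_study(small_design):
    study = generate_study(small_design, seed=7)
    return study


@pytest.fixture(scope="session")
def overlapping_study():
    design = reference_design(events_per_sample=TINY_EVENTS,
                              separation="overlapping")
    return generate_study(design, seed=11)


@pytest.fixture
def blobs():
    """Two well-separated 5-D Gaussian blobs with truth labels."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, size=(300, 5))
    b = rng.normal(0.0, 1.0, size=(300, 5)) + 10.0
    values = np.vstack([a, b])
    truth = np.r_[np.zeros(300, dtype=int), np.ones(300, dtype=int)]
    panel = ChannelPanel(tuple(f"M{i}" for i in range(5)))
    return EventMatrix(values, panel, Scale.transformed), truth


def pooled_truth(study, meta):
    """Generator-truth labels aligned to an assembled dataset."""
    truth = np.array(["control"] * len(meta), dtype=object)
    for sid, labels in study.truth.items():
        sel = (meta["sample_id"] == sid).to_numpy()
        truth[sel] = labels[meta["source_row"][sel].to_numpy()]
    return truth
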