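"""Shared fixtures: one default synthetic cohort and one trained model per session."""

import numpy as np
import pytest

from thetapet.atlas import default_atlas
from thetapet.classifier import stratified_split, train_ensemble
from thetapet.cohort import RegionSUVRPanel
from thetapet.metaroi import classify_meta_roi
from thetapet.simulate import SimulationConfig, generate_cohort, label_concordance

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass

SESSION_SEED = 7


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def synth_cohort():
    """Default heterogeneous cohort used by classifier/attribution/theta tests."""
    return generate_cohort(SimulationConfig(n=2000, seed=SESSION_SEED))


@pytest.fixture(scope="session")
def meta_results(synth_cohort, atlas):
    return {
        rec.participant_id: classify_meta_roi(panel, atlas)
        for rec, panel in synth_cohort.records
    }


@pytest.fixture(scope="session")
def concordance(synth_cohort, meta_results):
    return {
        pid: lab.label
        for pid, lab in label_concordance(synth_cohort, meta_results).items()
    }


@pytest.fixture(scope="session")
def split(synth_cohort, concordance):
    return stratified_split(synth_cohort, concordance, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def model(synth_cohort, split):
    return train_ensemble(synth_cohort, split, seed=SESSION_SEED)


@pytest.fixture()
def make_panel(atlas):
    """Panel factory: constant value everywhere, with named overrides."""

    def _make(pid="p0", base=1.0, **overrides):
        values = {r: base for r in atlas.region_names}
        values.update(overrides)
        return RegionSUVRPanel(pid, values)

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
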