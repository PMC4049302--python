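import numpy as np
import pytest

from repeatcc.simulate import CCPlantSpec, ProteomeSpec, generate_cc_tracks, generate_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """A 300-protein synthetic proteome with planted repeats + truth."""
    spec = ProteomeSpec(n_proteins=300, seed=1234)
    records, truth = generate_proteome(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def planted_cc(small_proteome):
    """CC tracks planted directly on repeats (full overlap bias)."""
    _, records, truth = small_proteome
    plant = CCPlantSpec(p_cc=0.4, overlap_bias=1.0, seed=99)
    tracks, segments = generate_cc_tracks(records, truth, plant)
    return plant, tracks, segments


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
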