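import numpy as np
import pytest

from pgmap import pipeline, search, simulate


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by integration-level tests."""
    cfg = simulate.SimConfig(genome_length=120_000, n_genes=8, seed=1)
    return simulate.simulate_world(cfg)


@pytest.fixture(scope="session")
def search_cfg():
    return search.SearchConfig()


@pytest.fixture(scope="session")
def three_results(small_world, search_cfg):
    """Protein + transcript + genome search results on the shared world."""
    w = small_world
    return pipeline.run_three_searches(
        w.spectra, w.genome_seqs, w.transcripts, w.proteins, search_cfg
    )


@pytest.fixture(scope="session")
def spectrum_truth(small_world):
    return dict(zip(small_world.truth_spectra.spectrum_id,
                    small_world.truth_spectra.peptide))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
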