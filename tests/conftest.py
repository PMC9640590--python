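import numpy as np
import pytest

from regsig import (BindingTable, RegulatedGeneSets, SimulationConfig,
                    TranscriptomeSignature, simulate_collection)


@pytest.fixture
def toy_signature():
    """Seven genes with mixed-sign scores."""
    return TranscriptomeSignature(
        entity_id="toy", role="drug",
        genes=np.array(["g1", "g2", "g3", "g4", "g5", "g6", "g7"], dtype=object),
        scores=np.array([2.0, -1.0, 0.0, 5.0, -3.0, 0.5, -0.5]))


@pytest.fixture
def toy_binding():
    """Three TFs over five genes with a hand-checkable relation."""
    #            g1     g2     g3     g4     g5
    matrix = np.array([
        [True,  False, True,  False, False],   # tfA
        [False, False, False, False, False],   # tfB binds nothing
        [True,  True,  True,  True,  True],    # tfC binds everything
    ])
    return BindingTable(["tfA", "tfB", "tfC"], ["g1", "g2", "g3", "g4", "g5"], matrix)


@pytest.fixture
def toy_sets():
    return RegulatedGeneSets(up={"g1", "g2"}, down={"g3"}, source_entity="toy")


@pytest.fixture(scope="session")
def small_collection():
    """A small but non-trivial synthetic collection shared across tests."""
    cfg = SimulationConfig(n_genes=300, n_tfs=12, n_drugs=24, n_diseases=6, seed=7)
    return simulate_collection(cfg)
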