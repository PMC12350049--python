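import pytest

from mitochar.io_annotation import load_reference_annotation
from mitochar.synthetic_data import SimulationConfig, make_ancestor


@pytest.fixture(scope="session")
def reference_annotation():
    """The bundled C. repasson gene table (38 features, 16,571 bp)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic synthetic mitogenome on the reference gene order,
    with an implanted 17-bp tandem repeat and the default CSB motifs."""
    cfg = SimulationConfig(seed=11, cr_repeat_motif="ATTGCAGGACTTAAGCT")
    seq, ann, truth = make_ancestor(cfg)
    return seq, ann, truth
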