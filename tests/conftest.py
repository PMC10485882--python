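import pytest

from editscape.annotation import GeneIndex
from editscape.editing import classify_editing
from editscape.expression import normalize
from editscape.synthetic import (
    SimulationConfig,
    generate_annotation,
    generate_expression,
    generate_variants,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """One in-memory fixture shared across the suite: annotation,
    planted variants with ground truth, and normalized count matrices."""
    annotation = generate_annotation(sim_config)
    records, truth = generate_variants(annotation, sim_config)
    matrices = generate_expression(annotation, truth, sim_config)
    for m in matrices.values():
        normalize(m)
    return {
        "annotation": annotation,
        "records": records,
        "truth": truth,
        "matrices": matrices,
        "config": sim_config,
    }


@pytest.fixture(scope="session")
def events(dataset):
    annotation = dataset["annotation"]
    index = GeneIndex(annotation.genes)
    return [classify_editing(v, index) for v in dataset["records"]]
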