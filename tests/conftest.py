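import numpy as np
import pytest

import ionclass as ic


@pytest.fixture(scope="session")
def default_table():
    return ic.load_property_table("default9")


@pytest.fixture(scope="session")
def planted_dataset():
    """Encoded 2-class planted-dipeptide dataset used across selection/classify tests."""
    spec = ic.two_class_spec(n_per_class=30, length=200, seed=7)
    records, labels = ic.generate(spec)
    params = ic.EncoderParams(lam=3, omega=0.2, table=ic.load_property_table())
    matrix = ic.encode_matrix(records, params)
    return ic.LabeledDataset(matrix, np.array(labels)), spec


def random_record(rng: np.random.Generator, length: int, record_id: str = "r"):
    seq = "".join(rng.choice(list(ic.ALPHABET), size=length))
    return ic.ProteinRecord(id=record_id, sequence=seq)
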