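import numpy as np
import pytest

from spidel import ReferenceSeq, load_brain_mutants
from spidel.spectrum import classify_record, group_records

WT0 = ("WT", 0.0, "brain")
WT10 = ("WT", 10.0, "brain")
SCID0 = ("scid", 0.0, "brain")
SCID10 = ("scid", 10.0, "brain")


@pytest.fixture(scope="session")
def brain_records():
    return load_brain_mutants()


@pytest.fixture(scope="session")
def brain_classified(brain_records):
    """Bundled mutant records, classified from their printed notation."""
    return group_records(classify_record(r) for r in brain_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231114)


def make_ref(seq: str, id: str = "ref") -> ReferenceSeq:
    return ReferenceSeq(id=id, sequence=seq)
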