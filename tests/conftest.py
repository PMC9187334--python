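import numpy as np
import pytest

from metsx.core import Cohort, SubjectRecord
from metsx.synthetic import GeneratorSpec, generate_cohort


def make_record(**kwargs):
    """A complete, metabolically unremarkable subject; override freely."""
    base = dict(
        id="r1", sex="female", age=35.0, wc=85.0, height=1.60, weight=64.0,
        sbp=115.0, dbp=75.0, glu=90.0, hdl=55.0, tri=100.0, insulin=8.0,
    )
    base.update(kwargs)
    return SubjectRecord(**base)


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def small_cohort():
    recs = [
        make_record(id="a", glu=80.0),
        make_record(id="b", glu=90.0, sex="male", hdl=45.0),
        make_record(id="c", glu=100.0, tri=180.0),
    ]
    return Cohort(recs, provenance="hand-built")


@pytest.fixture(scope="session")
def synth_cohort():
    """Moderate synthetic cohort shared across tests (read-only)."""
    spec = GeneratorSpec(n={"female": 2000, "male": 2000})
    return generate_cohort(spec, seed=20240612)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
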