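import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


TINY_OBO = """\
format-version: 1.2

[Term]
id: GO:0003824
name: catalytic activity
namespace: molecular_function

[Term]
id: GO:0004375
name: glycine dehydrogenase (decarboxylating) activity
namespace: molecular_function
alt_id: GO:0004374
is_a: GO:0003824

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0000001
name: obsolete example
namespace: biological_process
is_obsolete: true

[Typedef]
id: part_of
name: part of
"""


@pytest.fixture
def tiny_obo() -> str:
    return TINY_OBO


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def small_reference():
    from goforge.simulate import generate_reference

    return generate_reference(n_genes=60, n_terms=30, seed=101,
                              accessions_per_gene=(1, 2))
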