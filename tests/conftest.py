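"""Shared fixtures: small deterministic worlds and an ontology fragment.

Everything is generated programmatically at collection time; no data files.
"""

from __future__ import annotations

import pytest

import goaqc
from goaqc import SynthesisConfig, WorldConfig, build_dictionary, generate_world

# An ontology fragment around "response to calcium ion" used by the
# child/ancestor and synthesis examples:
#   response to stimulus > response to metal ion > response to calcium ion
#   > cellular response to calcium ion; plus "spindle" as an unrelated term.
FRAGMENT_OBO = """format-version: 1.2

[Term]
id: GO:0050896
name: response to stimulus

[Term]
id: GO:0010038
name: response to metal ion
is_a: GO:0050896

[Term]
id: GO:0051592
name: response to calcium ion
is_a: GO:0010038

[Term]
id: GO:0071277
name: cellular response to calcium ion
is_a: GO:0051592

[Term]
id: GO:0005819
name: spindle
"""


@pytest.fixture(scope="session")
def fragment_dag():
    return goaqc.GODag.from_obo(FRAGMENT_OBO)


@pytest.fixture(scope="session")
def std_world():
    """A mid-sized high-signal world shared across detector tests."""
    return generate_world(
        WorldConfig(n_terms=120, n_levels=5, n_genes=40, n_documents=1500, seed=3)
    )


@pytest.fixture(scope="session")
def std_dictionary(std_world):
    return build_dictionary(std_world.dag)


@pytest.fixture(scope="session")
def std_splits(std_world, std_dictionary):
    """(train, dev, test) = (2000, 100, 119+4x24) from the standard world."""
    cfg = SynthesisConfig(
        train_size=2000, dev_size=100, test_consistent=119, test_per_type=24, seed=1
    )
    return goaqc.assemble_datasets(
        std_world.annotations, std_world.dag, std_world.docs, std_dictionary, cfg
    )
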