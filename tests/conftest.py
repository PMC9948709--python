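import dendropy
import pytest

from mehg_guild import default_profiles
from mehg_guild import synthdata as sd


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def planted_four():
    """One MAG per role with decoys everywhere, plus the truth table."""
    spec = sd.PlantingSpec(
        roles=["producer", "degrader", "both", "neither"], decoy_rate=1.0, seed=1
    )
    return sd.generate_proteomes(spec)


def tree_from_nested(nested, taxon_namespace=None):
    """Build a dendropy tree from nested tuples of leaf labels."""

    def render(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(render(c) for c in node) + ")"

    return dendropy.Tree.get(
        data=render(nested) + ";",
        schema="newick",
        preserve_underscores=True,
        taxon_namespace=taxon_namespace or dendropy.TaxonNamespace(),
    )
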