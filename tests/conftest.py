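import numpy as np
import pytest
from hypothesis import settings

from dnaos.parameters import MechanicalParameterSet
from dnaos.sequence import CompositionSpec, GeneSequence, PartComposition, synthesize_gene

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mech():
    return MechanicalParameterSet()


@pytest.fixture(scope="session")
def mech_undamped():
    base = MechanicalParameterSet()
    return MechanicalParameterSet(
        base_params={b: dict(v) for b, v in base.base_params.items()},
        beta={b: 0.0 for b in "ATGC"},
    )


@pytest.fixture(scope="session")
def gene10():
    return GeneSequence(tuple("ACGTAGCTAG"))


@pytest.fixture(scope="session")
def gene60():
    """60-pair synthetic gene with the reference per-part A-T percentages.

    Parts of 20 pairs each with A-T fractions 49.8/57.1/72.2%, i.e. exactly
    10, 11 and 14 A-T pairs after rounding.
    """
    spec = CompositionSpec(
        parts=(
            PartComposition(20, at_fraction=49.8),
            PartComposition(20, at_fraction=57.1),
            PartComposition(20, at_fraction=72.2),
        ),
        seed=20260924,
    )
    return synthesize_gene(spec)
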