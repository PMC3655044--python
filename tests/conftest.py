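import numpy as np
import pytest

from schemarec.alignment import AlignedSequence, ParentPair
from schemarec.structure import contact_map_from_pairs
from schemarec.synthetic import (
    SyntheticFamilySpec,
    make_parent_pair,
    make_random_contact_map,
)


@pytest.fixture
def hand_pair():
    """Six-column gapless pair differing at columns 2 and 4."""
    return ParentPair(AlignedSequence("pa", "ACDEFG"), AlignedSequence("pb", "AYDQFG"))


@pytest.fixture
def hand_cmap():
    return contact_map_from_pairs([(2, 4), (1, 3)])


@pytest.fixture
def small_family():
    return make_parent_pair(
        SyntheticFamilySpec(L=60, n_homologs=4, divergence=0.4, n_gap_events=2,
                            gap_length_range=(1, 3), seed=11)
    )


@pytest.fixture
def small_cmap(small_family):
    return make_random_contact_map(small_family.spec.L, 50, seed=12)


def random_scheme(rng: np.random.Generator, L: int):
    from schemarec.energy import CrossoverScheme

    pattern = rng.choice(["A", "B", "AB", "BA", "ABA", "BAB"])
    n_x = len(pattern) - 1
    if n_x == 0:
        return CrossoverScheme(pattern, ())
    xs = tuple(sorted(int(x) for x in rng.choice(np.arange(1, L), size=n_x, replace=False)))
    return CrossoverScheme(pattern, xs)
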