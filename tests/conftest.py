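"""Shared fixtures: tiny hand-built assemblages and matrices."""

from __future__ import annotations

import numpy as np
import pytest

from ilta.assemblage_io import Assemblage, DamageObservation, LeafSpecimen


def make_leaf(i, site="Sf", **kwargs):
    defaults = dict(
        specimen_id=f"{site}-{i:03d}",
        site=site,
        fossil_species="Carya fragiliformis",
        family="Juglandaceae",
        phenology_modern="deciduous",
        lobation="unlobed",
        margin="toothed",
        primary_venation="pinnate",
        secondary_venation="non-looped",
        tct_combined="F",
        preserved_fraction=0.9,
        area_index=0.9,
    )
    defaults.update(kwargs)
    return LeafSpecimen(**defaults)


@pytest.fixture
def toy_assemblage():
    """Twelve leaves across two sites, three of them damaged."""
    leaves = [make_leaf(i, site="Sf") for i in range(8)]
    leaves += [make_leaf(i, site="SuBe") for i in range(8, 12)]
    leaves[0].damage.append(DamageObservation(2))
    leaves[1].damage.append(DamageObservation(2))
    leaves[1].damage.append(DamageObservation(12))
    leaves[8].damage.append(DamageObservation(214))
    return Assemblage("toy", leaves)


@pytest.fixture
def rarefaction_toy_matrix():
    """Four leaves: DT A on leaves 0 and 1, DT B on leaf 2, leaf 3 clean.

    Exhaustive enumeration gives E[S_2] = 4/3 and Var[S_2] = 2/9.
    """
    return np.array([[1, 0], [1, 0], [0, 1], [0, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20231504)
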