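"""Shared fixtures: hand-built micro-universes and generator presets.

The brute-force oracles used across the suite live in ``oracles.py`` —
they re-derive every quantity from first principles with plain loops,
independently of the library's vectorized implementations.
"""
from __future__ import annotations

import pytest

from toxsource.reference_io import (
    OrganismRecord,
    ReactionRecord,
    ReferenceUniverse,
    ToxinRecord,
)
from toxsource.synthetic_data import GeneratorParams, generate_universe


def make_universe(toxins, reactions, organisms) -> ReferenceUniverse:
    u = ReferenceUniverse(
        toxins={t.toxin_id: t for t in toxins},
        reactions={r.reaction_id: r for r in reactions},
        organisms={o.organism_id: o for o in organisms},
    )
    u.validate()
    return u


def small_params(seed: int, **overrides) -> GeneratorParams:
    """Desk-scale generator preset used throughout the suite."""
    base = dict(
        n_toxins=12,
        n_compounds=40,
        n_reactions=45,
        n_bacteria=15,
        max_strains_per_species=2,
        n_patients=30,
        n_tissues=5,
        n_host_genes=120,
        n_planted_producers=1,
        n_planted_consumers=1,
        producer_toxins=6,
        consumer_toxins=5,
        n_host_free_toxins=2,
    )
    base.update(overrides)
    return GeneratorParams(seed=seed, **base)


@pytest.fixture
def dual_role_universe() -> ReferenceUniverse:
    """A micro-universe where one bacterium is an exclusive producer of one
    toxin and an exclusive consumer of another — the dual-listing case."""
    toxins = [
        ToxinRecord("TA", "homocysteine", {"CA"}),
        ToxinRecord("TB", "creatinine", {"CB"}),
        ToxinRecord("TC", "xanthine", {"CC"}),
    ]
    reactions = [
        ReactionRecord("R1", {"1.1.1.1"}, {"CX"}, {"CA"},
                       dir_primary="forward", topology_tags={"CA": "downstream"}),
        ReactionRecord("R2", {"2.2.2.2"}, {"CB"}, {"CY"},
                       dir_primary="forward", topology_tags={"CB": "upstream"}),
        ReactionRecord("R3", {"3.3.3.3"}, {"CC"}, {"CZ"},
                       dir_primary="unknown", dir_secondary="reversible"),
        ReactionRecord("R4", {"4.4.4.4"}, {"CZ"}, {"CC"},
                       dir_primary="unknown", dir_secondary="unknown"),
    ]
    organisms = [
        OrganismRecord("O1", "Pediococcus", "acidilactici",
                       reaction_ids={"R1", "R2"}),
        OrganismRecord("O2", "Escherichia", "coli", reaction_ids={"R3", "R4"}),
        OrganismRecord("H", "Homo", "sapiens", is_host=True,
                       reaction_ids={"R3"}),
    ]
    return make_universe(toxins, reactions, organisms)


@pytest.fixture(scope="session")
def default_universe_and_truth():
    return generate_universe(small_params(11))


@pytest.fixture(scope="session")
def default_universe(default_universe_and_truth):
    return default_universe_and_truth[0]
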