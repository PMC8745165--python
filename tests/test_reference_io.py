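"""Unit tests for snapshot I/O, EC validation and strain collapsing."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxsource.errors import SchemaError, ValidationError
from toxsource.reference_io import (
    OrganismRecord,
    ReferenceUniverse,
    collapse_strains,
    ec_matches,
    load_reference_bundle,
    validate_ec,
    write_reference_bundle,
)
from toxsource.synthetic_data import generate_universe

from conftest import small_params


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("1.1.1.1", "1.1.1.1"),
        ("4.1.1.-", "4.1.1.-"),
        (" 2.7.7.7 ", "2.7.7.7"),
        ("EC 3.5.1.4", "3.5.1.4"),
        ("6.3", "6.3"),
    ],
)
def test_validate_ec_accepts_canonical_and_partial(raw, expected):
    assert validate_ec(raw) == expected


@pytest.mark.parametrize("raw", ["abc.1", "1.2.3.4.5", "", "1..2", "x"])
def test_validate_ec_rejects_malformed_tokens(raw):
    with pytest.raises(ValidationError):
        validate_ec(raw)


_ec_field = st.one_of(st.integers(1, 999).map(str), st.just("-"))


@settings(derandomize=True, max_examples=50)
@given(st.lists(_ec_field, min_size=1, max_size=4))
def test_validate_ec_accepts_any_well_formed_token(fields):
    token = ".".join(fields)
    assert validate_ec(token) == token
    assert ec_matches(token, token.replace("-", "1"))


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["Escherichia", "Bacteroides", "Roseburia"]),
            st.sampled_from(["coli", "sp.", "ovatus"]),
            st.sets(st.sampled_from([f"R{i}" for i in range(8)])),
        ),
        min_size=1,
        max_size=12,
    )
)
def test_collapse_is_idempotent_for_any_strain_set(rows):
    recs = [
        OrganismRecord(f"O{i:02d}", genus, species, reaction_ids=set(rids))
        for i, (genus, species, rids) in enumerate(rows)
    ]
    once = collapse_strains(recs)
    assert collapse_strains(once) == once
    keys = [r.species_key for r in once]
    assert len(keys) == len(set(keys))


@pytest.mark.parametrize(
    "pattern,ec,expected",
    [
        ("4.1.1.-", "4.1.1.85", True),
        ("4.1.1.-", "4.1.2.85", False),
        ("4.1", "4.1.1.85", True),
        ("4.1.1.85", "4.1.1.85", True),
        ("4.1.1.85", "4.1.1.86", False),
    ],
)
def test_ec_wildcard_matching(pattern, ec, expected):
    assert ec_matches(pattern, ec) is expected


class TestCollapseStrains:
    def test_single_species_record_unchanged(self):
        rec = OrganismRecord("O1", "Escherichia", "coli", reaction_ids={"R1"})
        assert collapse_strains([rec]) == [rec]

    def test_strain_union(self):
        strains = [
            OrganismRecord("O1", "Escherichia", "coli", strain="K-12",
                           reaction_ids={"a"}),
            OrganismRecord("O2", "Escherichia", "coli", strain="O157",
                           reaction_ids={"b"}),
            OrganismRecord("O3", "Escherichia", "coli", strain="B",
                           reaction_ids={"a", "c"}),
        ]
        out = collapse_strains(strains)
        assert len(out) == 1
        assert out[0].reaction_ids == {"a", "b", "c"}
        assert out[0].display_name == "Escherichia coli"

    def test_genus_level_taxa_stay_distinct(self):
        recs = [
            OrganismRecord("O1", "Brevundimonas", "sp.", reaction_ids={"a"}),
            OrganismRecord("O2", "Desulfovibrio", "sp.", reaction_ids={"b"}),
        ]
        assert len(collapse_strains(recs)) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        recs = [
            OrganismRecord(
                f"O{i}", f"G{rng.integers(4)}", f"s{rng.integers(5)}",
                strain=f"st{i}",
                reaction_ids={f"R{j}" for j in rng.integers(0, 20, size=3)},
            )
            for i in range(50)
        ]
        once = collapse_strains(recs)
        assert collapse_strains(once) == once

    def test_union_matches_brute_force(self):
        rng = np.random.default_rng(7)
        recs = [
            OrganismRecord(
                f"O{i:02d}", f"G{rng.integers(4)}", f"s{rng.integers(5)}",
                reaction_ids={f"R{j}" for j in rng.integers(0, 30, size=4)},
            )
            for i in range(50)
        ]
        expected: dict[tuple[str, str], set[str]] = {}
        for r in recs:
            expected.setdefault(r.species_key, set()).update(r.reaction_ids)
        out = collapse_strains(recs)
        assert len(out) == len(expected)
        for rec in out:
            assert rec.reaction_ids == expected[rec.species_key]

    def test_conflicting_host_flags_fatal(self):
        recs = [
            OrganismRecord("O1", "Homo", "sapiens", is_host=True),
            OrganismRecord("O2", "Homo", "sapiens", is_host=False),
        ]
        with pytest.raises(ValidationError, match="is_host"):
            collapse_strains(recs)


class TestBundleRoundTrip:
    def test_round_trip_preserves_all_fields(self, tmp_path):
        universe, _ = generate_universe(small_params(3))
        write_reference_bundle(universe, tmp_path)
        reread = load_reference_bundle(tmp_path, collapse=False)
        assert reread.toxins == universe.toxins
        assert reread.reactions == universe.reactions
        assert reread.organisms == universe.organisms

    def test_empty_tables_give_empty_universe(self, tmp_path):
        write_reference_bundle(ReferenceUniverse(), tmp_path)
        u = load_reference_bundle(tmp_path)
        assert not u.toxins and not u.reactions and not u.organisms

    def test_missing_file_is_fatal_with_path(self, tmp_path):
        with pytest.raises(SchemaError, match="toxins.tsv"):
            load_reference_bundle(tmp_path)

    def test_unknown_column_is_fatal_listing_expected(self, tmp_path):
        write_reference_bundle(ReferenceUniverse(), tmp_path)
        (tmp_path / "toxins.tsv").write_text("bogus\tname\n")
        with pytest.raises(SchemaError, match="toxin_id"):
            load_reference_bundle(tmp_path)

    def test_dangling_reaction_key_is_fatal(self, tmp_path):
        universe, _ = generate_universe(small_params(3))
        next(iter(universe.organisms.values())).reaction_ids.add("R9999")
        write_reference_bundle(universe, tmp_path)
        with pytest.raises(ValidationError, match="R9999"):
            load_reference_bundle(tmp_path)

    def test_load_collapses_strains(self, tmp_path):
        universe, _ = generate_universe(small_params(4))
        write_reference_bundle(universe, tmp_path)
        collapsed = load_reference_bundle(tmp_path, collapse=True)
        keys = [o.species_key for o in collapsed.organisms.values()]
        assert len(keys) == len(set(keys))
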