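"""Direction resolution, capability classes, producer/consumer ranking."""
from __future__ import annotations

import copy

import pytest

from toxsource.capability import (
    classify_capability,
    direction_counts,
    rank_producers_consumers,
    resolve_directions,
)
from toxsource.errors import ToxSourceError, ValidationError
from toxsource.linkage import build_links
from toxsource.reference_io import ReactionRecord
from toxsource.synthetic_data import generate_universe

from conftest import small_params
from oracles import brute_capability


class TestResolveDirections:
    def test_both_unknown_is_unresolved(self):
        rxn = ReactionRecord("R1")
        d = resolve_directions([rxn])["R1"]
        assert (d.resolved, d.provenance) == ("unresolved", "none")

    def test_primary_precedence_over_secondary(self):
        rxn = ReactionRecord("R1", dir_primary="forward", dir_secondary="reversible")
        d = resolve_directions([rxn])["R1"]
        assert (d.resolved, d.provenance) == ("forward", "primary")

    def test_secondary_fills_primary_silence(self):
        rxn = ReactionRecord("R1", dir_secondary="reverse")
        d = resolve_directions([rxn])["R1"]
        assert (d.resolved, d.provenance) == ("reverse", "secondary")

    @pytest.mark.parametrize("seed", [1, 9])
    def test_resolved_count_matches_counting_oracle(self, seed):
        universe, _ = generate_universe(small_params(seed))
        rxns = list(universe.reactions.values())
        counts = direction_counts(resolve_directions(rxns))
        expected = sum(1 for r in rxns if r.dir_primary != "unknown") + sum(
            1
            for r in rxns
            if r.dir_primary == "unknown" and r.dir_secondary != "unknown"
        )
        assert counts["resolved"] == expected

    def test_adding_secondary_annotations_is_monotone(self):
        universe, truth = generate_universe(
            small_params(3, dir_primary_coverage=0.3, dir_secondary_coverage=0.0)
        )
        rxns = list(universe.reactions.values())
        base = resolve_directions(rxns)
        n_base = direction_counts(base)["resolved"]
        richer = copy.deepcopy(rxns)
        for r in richer:
            if r.dir_secondary == "unknown":
                r.dir_secondary = truth.true_directions[r.reaction_id]
        after = resolve_directions(richer)
        assert direction_counts(after)["resolved"] >= n_base
        for rid, d in base.items():
            if d.provenance == "primary":
                assert after[rid].resolved == d.resolved  # never overridden


class TestClassifyCapability:
    def test_forward_product_is_synthesize_only(self, dual_role_universe):
        links = build_links(dual_role_universe)
        directions = resolve_directions(dual_role_universe.reactions.values())
        m = classify_capability(links, directions, dual_role_universe.reactions)
        assert m.get("O1", "TA") == "synthesize_only"

    def test_dual_listing_producer_and_consumer(self, dual_role_universe):
        """One bacterium can exclusively produce one toxin and exclusively
        consume another, and then appears in both ranked lists."""
        links = build_links(dual_role_universe)
        directions = resolve_directions(dual_role_universe.reactions.values())
        m = classify_capability(links, directions, dual_role_universe.reactions)
        assert m.get("O1", "TA") == "synthesize_only"
        assert m.get("O1", "TB") == "decompose_only"
        ranking = rank_producers_consumers(m, 0, 0, exclude={"H"})
        assert ("O1", 1) in ranking.producers
        assert ("O1", 1) in ranking.consumers

    def test_reversible_grants_both_by_default(self, dual_role_universe):
        links = build_links(dual_role_universe)
        directions = resolve_directions(dual_role_universe.reactions.values())
        m = classify_capability(links, directions, dual_role_universe.reactions)
        assert m.get("O2", "TC") == "both"
        m2 = classify_capability(
            links, directions, dual_role_universe.reactions,
            reversible_counts="none",
        )
        assert m2.get("O2", "TC") == "none"

    def test_unresolved_reactions_contribute_nothing(self, dual_role_universe):
        links = [l for l in build_links(dual_role_universe) if l.reaction_id == "R4"]
        directions = resolve_directions(dual_role_universe.reactions.values())
        m = classify_capability(links, directions, dual_role_universe.reactions)
        assert m.get("O2", "TC") == "none"

    @pytest.mark.parametrize("seed", [2, 6, 14])
    def test_classes_match_per_pair_oracle(self, seed):
        universe, _ = generate_universe(small_params(seed))
        links = build_links(universe)
        directions = resolve_directions(universe.reactions.values())
        m = classify_capability(links, directions, universe.reactions)
        assert m.entries == brute_capability(universe)

    def test_partition_every_pair_has_one_class(self, default_universe):
        links = build_links(default_universe)
        directions = resolve_directions(default_universe.reactions.values())
        m = classify_capability(links, directions, default_universe.reactions)
        linked_pairs = {(l.organism_id, l.toxin_id) for l in links}
        assert set(m.entries) == linked_pairs
        assert all(
            c in ("synthesize_only", "decompose_only", "both", "none")
            for c in m.entries.values()
        )

    def test_topology_mode_uses_tags(self, dual_role_universe):
        links = build_links(dual_role_universe)
        directions = resolve_directions(dual_role_universe.reactions.values())
        compounds = {
            t.toxin_id: t.compound_ids for t in dual_role_universe.toxins.values()
        }
        m = classify_capability(
            links, directions, dual_role_universe.reactions, "topology",
            toxin_compounds=compounds,
        )
        assert m.get("O1", "TA") == "synthesize_only"  # downstream tag
        assert m.get("O1", "TB") == "decompose_only"  # upstream tag

    def test_topology_mode_without_tags_is_fatal(self, dual_role_universe):
        universe = copy.deepcopy(dual_role_universe)
        for r in universe.reactions.values():
            r.topology_tags = {}
        links = build_links(universe)
        directions = resolve_directions(universe.reactions.values())
        with pytest.raises(ToxSourceError, match="strict"):
            classify_capability(
                links, directions, universe.reactions, "topology",
                toxin_compounds={},
            )


class TestRanking:
    def test_thresholds_are_strict_inequalities(self, default_universe):
        links = build_links(default_universe)
        directions = resolve_directions(default_universe.reactions.values())
        m = classify_capability(links, directions, default_universe.reactions)
        ranking = rank_producers_consumers(m, 5, 4)
        assert all(n > 5 for _o, n in ranking.producers)
        assert all(n > 4 for _o, n in ranking.consumers)

    def test_empty_matrix_gives_empty_lists(self):
        from toxsource.capability import CapabilityMatrix

        ranking = rank_producers_consumers(CapabilityMatrix(), 5, 4)
        assert ranking.producers == [] and ranking.consumers == []

    def test_negative_threshold_fatal(self):
        from toxsource.capability import CapabilityMatrix

        with pytest.raises(ValidationError):
            rank_producers_consumers(CapabilityMatrix(), -1, 4)

    def test_ordering_by_count_then_name(self):
        from toxsource.capability import CapabilityMatrix

        m = CapabilityMatrix(
            entries={
                ("OB", "T1"): "synthesize_only",
                ("OA", "T1"): "synthesize_only",
                ("OA", "T2"): "synthesize_only",
            }
        )
        ranking = rank_producers_consumers(
            m, 0, 0, names={"OA": "Zeta sp.", "OB": "Alpha sp."}
        )
        assert ranking.producers == [("OA", 2), ("OB", 1)]
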