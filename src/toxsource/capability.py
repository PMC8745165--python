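"""Reaction-direction resolution and producer/consumer classification.

Direction annotations come from two sources: a primary one (module-style
annotations, sparse but authoritative) and a secondary curated source
consulted only where the primary is silent. A reaction whose direction
neither source gives stays unresolved and contributes nothing in strict
mode.

Capability classes per (organism, toxin) pair:

* ``synthesize_only`` — some linked reaction can produce the toxin and no
  linked reaction can consume it;
* ``decompose_only`` — the converse;
* ``both`` — the organism can do either (the toxin is typically a pathway
  intermediate);
* ``none`` — no linked reaction contributes under the mode's rules.

Two modes are supported: *strict* uses resolved reaction directions;
*topology* uses upstream/downstream pathway-position tags instead.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ToxSourceError, ValidationError
from .linkage import Link
from .reference_io import ReactionRecord

CAPABILITY_CLASSES = ("synthesize_only", "decompose_only", "both", "none")


@dataclass(frozen=True)
class DirectionAssignment:
    reaction_id: str
    resolved: str  # forward | reverse | reversible | unresolved
    provenance: str  # primary | secondary | none


def resolve_directions(
    reactions: Iterable[ReactionRecord],
) -> dict[str, DirectionAssignment]:
    """Resolve each reaction's direction with primary-source precedence.

    The secondary source is consulted only when the primary annotation is
    ``unknown``; it can therefore add resolutions but never override one.
    """
    out: dict[str, DirectionAssignment] = {}
    for rxn in reactions:
        if rxn.dir_primary != "unknown":
            out[rxn.reaction_id] = DirectionAssignment(
                rxn.reaction_id, rxn.dir_primary, "primary"
            )
        elif rxn.dir_secondary != "unknown":
            out[rxn.reaction_id] = DirectionAssignment(
                rxn.reaction_id, rxn.dir_secondary, "secondary"
            )
        else:
            out[rxn.reaction_id] = DirectionAssignment(
                rxn.reaction_id, "unresolved", "none"
            )
    return out


def direction_counts(directions: Mapping[str, DirectionAssignment]) -> dict[str, int]:
    counts = {"primary": 0, "secondary": 0, "none": 0}
    for d in directions.values():
        counts[d.provenance] += 1
    counts["resolved"] = counts["primary"] + counts["secondary"]
    counts["total"] = len(directions)
    return counts


@dataclass
class CapabilityMatrix:
    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    mode: str = "strict"

    def get(self, organism_id: str, toxin_id: str) -> str:
        return self.entries.get((organism_id, toxin_id), "none")

    def count_class(self, organism_id: str, cls: str) -> int:
        return sum(
            1
            for (org, _tox), c in self.entries.items()
            if org == organism_id and c == cls
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"organism_id": org, "toxin_id": tox, "class": cls, "mode": self.mode}
            for (org, tox), cls in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["organism_id", "toxin_id", "class", "mode"]
        )


def _strict_abilities(
    role: str, resolved: str, reversible_counts: str
) -> tuple[bool, bool]:
    """(can_synthesize, can_decompose) contributed by one link in strict mode."""
    if resolved == "reversible":
        if reversible_counts == "both":
            return True, True
        return False, False
    if resolved == "forward":
        return role in ("product", "both"), role in ("substrate", "both")
    if resolved == "reverse":
        return role in ("substrate", "both"), role in ("product", "both")
    return False, False  # unresolved


def _link_abilities(
    link: Link,
    directions: Mapping[str, DirectionAssignment],
    reactions: Mapping[str, ReactionRecord],
    mode: str,
    reversible_counts: str,
    toxin_compounds: Mapping[str, set[str]] | None,
) -> tuple[bool, bool]:
    if mode == "strict":
        resolved = directions[link.reaction_id].resolved
        return _strict_abilities(link.role, resolved, reversible_counts)
    tags = reactions[link.reaction_id].topology_tags
    toxin_tags = {
        tags[cid]
        for cid in (toxin_compounds or {}).get(link.toxin_id, set())
        if cid in tags
    }
    return "downstream" in toxin_tags, "upstream" in toxin_tags


def classify_capability(
    links: Iterable[Link],
    directions: Mapping[str, DirectionAssignment],
    reactions: Mapping[str, ReactionRecord],
    mode: str = "strict",
    *,
    reversible_counts: str = "both",
    toxin_compounds: Mapping[str, set[str]] | None = None,
) -> CapabilityMatrix:
    """Classify every linked (organism, toxin) pair.

    In topology mode, ``toxin_compounds`` (toxin_id → compound set) is
    needed to look up which upstream/downstream tags belong to the toxin;
    a universe's ``compound_index`` inverse serves. Raises if topology
    mode is requested but no reaction carries a topology tag.
    """
    if mode not in ("strict", "topology"):
        raise ValidationError(f"unknown capability mode {mode!r}")
    if reversible_counts not in ("both", "none"):
        raise ValidationError(f"reversible_counts must be 'both' or 'none'")

    if mode == "topology":
        if not any(r.topology_tags for r in reactions.values()):
            raise ToxSourceError(
                "topology mode requested but no reaction carries topology tags; "
                "use strict mode"
            )
        if toxin_compounds is None:
            raise ValidationError("topology mode requires toxin_compounds mapping")

    synth: dict[tuple[str, str], bool] = defaultdict(bool)
    decomp: dict[tuple[str, str], bool] = defaultdict(bool)
    pairs: set[tuple[str, str]] = set()

    for l in links:
        key = (l.organism_id, l.toxin_id)
        pairs.add(key)
        s, d = _link_abilities(
            l, directions, reactions, mode, reversible_counts, toxin_compounds
        )
        synth[key] |= s
        decomp[key] |= d

    entries: dict[tuple[str, str], str] = {}
    for key in pairs:
        s, d = synth[key], decomp[key]
        if s and d:
            entries[key] = "both"
        elif s:
            entries[key] = "synthesize_only"
        elif d:
            entries[key] = "decompose_only"
        else:
            entries[key] = "none"
    return CapabilityMatrix(entries=entries, mode=mode)


def exclusive_reaction_counts(
    links: Iterable[Link],
    directions: Mapping[str, DirectionAssignment],
    reactions: Mapping[str, ReactionRecord],
    matrix: CapabilityMatrix,
    *,
    reversible_counts: str = "both",
    toxin_compounds: Mapping[str, set[str]] | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Per organism: reactions backing its exclusive capabilities.

    Counts distinct synthesizing reactions over the organism's
    ``synthesize_only`` toxins, and decomposing reactions over its
    ``decompose_only`` toxins — the reaction-level companion to the
    toxin-level ranking counts, reported alongside since either can be a
    sensible ranking unit.
    """
    synth_rxns: dict[str, set[str]] = defaultdict(set)
    decomp_rxns: dict[str, set[str]] = defaultdict(set)
    for l in links:
        cls = matrix.get(l.organism_id, l.toxin_id)
        if cls not in ("synthesize_only", "decompose_only"):
            continue
        s, d = _link_abilities(
            l, directions, reactions, matrix.mode, reversible_counts,
            toxin_compounds,
        )
        if cls == "synthesize_only" and s:
            synth_rxns[l.organism_id].add(l.reaction_id)
        elif cls == "decompose_only" and d:
            decomp_rxns[l.organism_id].add(l.reaction_id)
    return (
        {o: len(r) for o, r in synth_rxns.items()},
        {o: len(r) for o, r in decomp_rxns.items()},
    )


@dataclass
class ProducerConsumerRanking:
    producers: list[tuple[str, int]]
    consumers: list[tuple[str, int]]
    thresholds: tuple[int, int]
    mode: str


def rank_producers_consumers(
    matrix: CapabilityMatrix,
    min_synth: int = 5,
    min_decomp: int = 4,
    *,
    names: Mapping[str, str] | None = None,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> ProducerConsumerRanking:
    """Rank organisms by exclusive synthesis/decomposition capability.

    Producers are organisms with strictly more than ``min_synth`` toxins in
    class ``synthesize_only``; consumers symmetric with ``decompose_only``
    and ``min_decomp``. An organism may appear in both lists. ``exclude``
    typically holds the host organism id; ``names`` supplies the
    display-name tie-break.
    """
    if min_synth < 0 or min_decomp < 0:
        raise ValidationError("thresholds must be non-negative")
    names = names or {}

    synth_counts: dict[str, int] = defaultdict(int)
    decomp_counts: dict[str, int] = defaultdict(int)
    for (org, _tox), cls in matrix.entries.items():
        if org in exclude:
            continue
        if cls == "synthesize_only":
            synth_counts[org] += 1
        elif cls == "decompose_only":
            decomp_counts[org] += 1

    def ranked(counts: dict[str, int], threshold: int) -> list[tuple[str, int]]:
        kept = [(org, n) for org, n in counts.items() if n > threshold]
        kept.sort(key=lambda item: (-item[1], names.get(item[0], item[0])))
        return kept

    return ProducerConsumerRanking(
        producers=ranked(synth_counts, min_synth),
        consumers=ranked(decomp_counts, min_decomp),
        thresholds=(min_synth, min_decomp),
        mode=matrix.mode,
    )


def directions_frame(directions: Mapping[str, DirectionAssignment]) -> pd.DataFrame:
    rows = [
        {"reaction_id": d.reaction_id, "resolved": d.resolved, "provenance": d.provenance}
        for d in sorted(directions.values(), key=lambda d: d.reaction_id)
    ]
    return pd.DataFrame(rows, columns=["reaction_id", "resolved", "provenance"])


def ranking_frames(
    ranking: ProducerConsumerRanking, names: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    names = names or {}
    prod = pd.DataFrame(
        [
            {"organism_id": o, "name": names.get(o, o), "n_synthesize_only": n}
            for o, n in ranking.producers
        ],
        columns=["organism_id", "name", "n_synthesize_only"],
    )
    cons = pd.DataFrame(
        [
            {"organism_id": o, "name": names.get(o, o), "n_decompose_only": n}
            for o, n in ranking.consumers
        ],
        columns=["organism_id", "name", "n_decompose_only"],
    )
    return prod, cons
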