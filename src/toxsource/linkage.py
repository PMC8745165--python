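"""Toxin–reaction–organism link table and the per-toxin summary.

The link table is the central object of the analysis: one row per
(toxin, reaction, organism) triple in which a compound identifier of the
toxin appears in the reaction and the reaction belongs to the organism's
repertoire. A toxin mapped to several compound identifiers (isomers, salt
forms) still contributes a single link per (reaction, organism); the
``role`` records on which side(s) of the reaction the toxin sits.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .reference_io import ReferenceUniverse

ROLES = ("substrate", "product", "both")


@dataclass(frozen=True)
class Link:
    toxin_id: str
    reaction_id: str
    organism_id: str
    role: str  # substrate | product | both


def toxin_reaction_roles(universe: ReferenceUniverse) -> dict[tuple[str, str], str]:
    """Map (toxin_id, reaction_id) → role for every toxin touching a reaction."""
    compound_index = universe.compound_index
    roles: dict[tuple[str, str], str] = {}
    for rxn in universe.reactions.values():
        sub_toxins: set[str] = set()
        prod_toxins: set[str] = set()
        for cid in rxn.substrates:
            sub_toxins |= compound_index.get(cid, set())
        for cid in rxn.products:
            prod_toxins |= compound_index.get(cid, set())
        for tox in sub_toxins | prod_toxins:
            if tox in sub_toxins and tox in prod_toxins:
                role = "both"
            elif tox in sub_toxins:
                role = "substrate"
            else:
                role = "product"
            roles[(tox, rxn.reaction_id)] = role
    return roles


def build_links(universe: ReferenceUniverse) -> list[Link]:
    """Build the full link table for a validated universe."""
    roles = toxin_reaction_roles(universe)
    by_reaction: dict[str, list[tuple[str, str]]] = {}
    for (tox, rid), role in roles.items():
        by_reaction.setdefault(rid, []).append((tox, role))

    links: list[Link] = []
    for org in universe.organisms.values():
        for rid in org.reaction_ids:
            for tox, role in by_reaction.get(rid, ()):
                links.append(Link(tox, rid, org.organism_id, role))
    links.sort(key=lambda l: (l.toxin_id, l.reaction_id, l.organism_id))
    return links


def links_frame(links: list[Link]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.toxin_id, l.reaction_id, l.organism_id, l.role) for l in links],
        columns=["toxin_id", "reaction_id", "organism_id", "role"],
    )


def summarize_toxins(
    links: list[Link], universe: ReferenceUniverse
) -> pd.DataFrame:
    """Per-toxin summary: bacteria, reactions, and host enzymes linked.

    ``n_bacteria`` counts distinct non-host organisms linked to the toxin;
    ``n_reactions`` counts distinct linked reactions over any organism;
    ``n_host_enzymes`` counts distinct EC tokens on host-repertoire
    reactions linked to the toxin (partial ECs count as distinct tokens).
    Rows are sorted by (n_host_enzymes asc, n_bacteria desc, name) for
    report stability.
    """
    host = universe.host
    host_id = host.organism_id if host else None

    bacteria: dict[str, set[str]] = {t: set() for t in universe.toxins}
    reactions: dict[str, set[str]] = {t: set() for t in universe.toxins}
    host_ecs: dict[str, set[str]] = {t: set() for t in universe.toxins}
    for l in links:
        reactions[l.toxin_id].add(l.reaction_id)
        if l.organism_id == host_id:
            host_ecs[l.toxin_id] |= universe.reactions[l.reaction_id].ec_numbers
        else:
            bacteria[l.toxin_id].add(l.organism_id)

    rows = [
        {
            "toxin_id": t.toxin_id,
            "name": t.name,
            "n_bacteria": len(bacteria[t.toxin_id]),
            "n_reactions": len(reactions[t.toxin_id]),
            "n_host_enzymes": len(host_ecs[t.toxin_id]),
        }
        for t in universe.toxins.values()
    ]
    df = pd.DataFrame(
        rows, columns=["toxin_id", "name", "n_bacteria", "n_reactions", "n_host_enzymes"]
    )
    return df.sort_values(
        ["n_host_enzymes", "n_bacteria", "name"],
        ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)


def list_toxins_without_host_enzymes(summary: pd.DataFrame) -> set[str]:
    """Toxins with bacterial links but no host enzyme — candidate
    microbiome-exclusive solutes."""
    mask = (summary["n_host_enzymes"] == 0) & (summary["n_bacteria"] > 0)
    return set(summary.loc[mask, "toxin_id"])
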