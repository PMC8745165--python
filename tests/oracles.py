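"""Independent brute-force re-derivations used as test oracles.

Everything here is plain-loop, first-principles code kept deliberately
separate from the library's implementations: set unions for strain
collapsing, a triple loop for the link table, per-pair capability
re-derivation, and per-patient scans for cohort percentages.
"""
from __future__ import annotations

from toxsource.reference_io import ReferenceUniverse


def brute_links(universe: ReferenceUniverse) -> set[tuple[str, str, str, str]]:
    """Triple loop over (toxin, reaction, organism)."""
    out = set()
    for tox in universe.toxins.values():
        for rxn in universe.reactions.values():
            in_sub = bool(tox.compound_ids & rxn.substrates)
            in_prod = bool(tox.compound_ids & rxn.products)
            if not (in_sub or in_prod):
                continue
            role = "both" if (in_sub and in_prod) else (
                "substrate" if in_sub else "product"
            )
            for org in universe.organisms.values():
                if rxn.reaction_id in org.reaction_ids:
                    out.add((tox.toxin_id, rxn.reaction_id, org.organism_id, role))
    return out


def brute_summary(universe: ReferenceUniverse) -> dict[str, tuple[int, int, int]]:
    """Per-toxin (n_bacteria, n_reactions, n_host_enzymes) by set cardinality."""
    links = brute_links(universe)
    host_ids = {o.organism_id for o in universe.organisms.values() if o.is_host}
    out = {}
    for tid in universe.toxins:
        rows = [l for l in links if l[0] == tid]
        bacteria = {l[2] for l in rows if l[2] not in host_ids}
        reactions = {l[1] for l in rows}
        host_ecs = set()
        for l in rows:
            if l[2] in host_ids:
                host_ecs |= universe.reactions[l[1]].ec_numbers
        out[tid] = (len(bacteria), len(reactions), len(host_ecs))
    return out


def brute_capability(
    universe: ReferenceUniverse, reversible_counts: str = "both"
) -> dict[tuple[str, str], str]:
    """Strict-mode class per linked (organism, toxin) pair, from scratch."""
    out = {}
    for org in universe.organisms.values():
        for tox in universe.toxins.values():
            synth = decomp = False
            linked = False
            for rid in org.reaction_ids:
                rxn = universe.reactions[rid]
                in_sub = bool(tox.compound_ids & rxn.substrates)
                in_prod = bool(tox.compound_ids & rxn.products)
                if not (in_sub or in_prod):
                    continue
                linked = True
                if rxn.dir_primary != "unknown":
                    d = rxn.dir_primary
                elif rxn.dir_secondary != "unknown":
                    d = rxn.dir_secondary
                else:
                    continue
                if d == "reversible":
                    if reversible_counts == "both":
                        synth = decomp = True
                elif d == "forward":
                    synth |= in_prod
                    decomp |= in_sub
                elif d == "reverse":
                    synth |= in_sub
                    decomp |= in_prod
            if not linked:
                continue
            if synth and decomp:
                cls = "both"
            elif synth:
                cls = "synthesize_only"
            elif decomp:
                cls = "decompose_only"
            else:
                cls = "none"
            out[(org.organism_id, tox.toxin_id)] = cls
    return out


def brute_enzyme_pct(cohort) -> dict[str, tuple[float, float]]:
    """(pct_mrna, pct_protein) per enzyme by per-patient scans."""
    patients = list(cohort.enzyme_mrna.index)
    out = {}
    for enz in cohort.enzyme_mrna.columns:
        n_m = sum(1 for p in patients if cohort.enzyme_mrna.loc[p, enz] > 0)
        n_p = sum(1 for p in patients if bool(cohort.enzyme_protein.loc[p, enz]))
        out[enz] = (100.0 * n_m / len(patients), 100.0 * n_p / len(patients))
    return out


def brute_union_pct(cohort, toxin_to_enzymes) -> dict[str, float]:
    """Per-toxin any-enzyme prevalence by per-patient any() scan."""
    patients = list(cohort.enzyme_mrna.index)
    out = {}
    for tox, enzymes in toxin_to_enzymes.items():
        hits = 0
        for p in patients:
            if any(cohort.enzyme_mrna.loc[p, e] > 0 for e in enzymes):
                hits += 1
        out[tox] = 100.0 * hits / len(patients)
    return out


def brute_quartiles(counts: list[float]) -> list[str | None]:
    """Quartile labels for one patient's enzyme counts (None = undetected)."""
    import math

    nonzero = sorted(c for c in counts if c > 0)
    n = len(nonzero)
    labels: list[str | None] = []
    for c in counts:
        if c <= 0:
            labels.append(None)
            continue
        rank = 1 + sum(1 for v in nonzero if v < c)  # minimum rank under ties
        labels.append(f"Q{math.ceil(4 * rank / n)}")
    return labels
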