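"""Synthetic reference universes, cohorts and expression data.

Every pipeline stage in this package is exercised against generated data
with *planted* structure the generator records as ground truth:

* planted producer species get dedicated forward reactions producing their
  planted toxins (and nothing that consumes them), so under full direction
  coverage they are recoverable as exclusive producers; planted consumers
  are the mirror image;
* background toxin reactions are reversible, which classifies every
  background (organism, toxin) pair as ``both`` — background noise can
  therefore never masquerade as an exclusive producer or consumer;
* a configurable set of toxins is kept out of the host repertoire, planting
  the "no host enzyme" candidate set;
* the host expression matrix is drawn from a two-component log-normal
  mixture, emulating the bimodal whole-organism transcript distribution;
* cohort detection follows presence → detection → count → protein
  conditional sampling with known probabilities, so prevalence moments are
  checkable analytically.

One integer seed governs everything; per-artifact substreams are derived
deterministically from it, so equal (params, seed) gives byte-identical
output bundles.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .linkage import toxin_reaction_roles
from .reference_io import (
    OrganismRecord,
    ReactionRecord,
    ReferenceUniverse,
    ToxinRecord,
    collapse_strains,
)
from .cohort_prevalence import CohortDetection
from .host_abundance import TissueExpression

# Display-name pools: real uremic retention solutes and common gut genera,
# purely cosmetic — identifiers are synthetic.
_TOXIN_NAMES = [
    "mannitol", "phenol", "trimethylamine", "oxalate", "creatinine",
    "trimethylamine-N-oxide", "pseudouridine", "3-(3-hydroxyphenyl)propanoate",
    "S-adenosylhomocysteine", "homocysteine", "argininic acid", "putrescine",
    "methylglyoxal", "hypoxanthine", "urea", "xanthine", "nicotinamide",
    "cytidine", "uridine", "anthranilic acid", "inosine", "indole-3-acetic acid",
    "3-hydroxyanthranilic acid", "myoinositol", "phenylacetic acid", "sorbitol",
    "dimethylamine", "orotic acid", "xanthosine", "orotidine", "quinolinic acid",
    "creatine", "gentisic acid", "hippuric acid", "taurocyamine", "melatonin",
    "uric acid", "kynurenine", "p-cresyl sulfate", "indoxyl sulfate",
]
_GENERA = [
    "Bacteroides", "Clostridium", "Lactobacillus", "Escherichia", "Klebsiella",
    "Ruminococcus", "Eubacterium", "Faecalibacterium", "Roseburia",
    "Bifidobacterium", "Desulfovibrio", "Enterococcus", "Prevotella",
    "Campylobacter", "Helicobacter", "Parabacteroides",
]
_EPITHETS = [
    "sp.", "coli", "longum", "rectale", "uniformis", "ovatus", "vulgatus",
    "torques", "prausnitzii", "intestinalis", "faecalis", "piger", "oxytoca",
    "pylori", "acidilactici", "innocua", "ruminis", "merdae", "plautii",
    "hominis", "caccae", "obeum", "bolteae", "copri",
]
# Approximate adult organ masses in grams for the tissue-weight table.
_TISSUE_WEIGHTS = [
    ("liver", 1500.0), ("brain", 1400.0), ("muscle", 2500.0), ("kidney", 300.0),
    ("lung", 1000.0), ("heart", 310.0), ("colon", 370.0), ("small_intestine", 640.0),
    ("skin", 2600.0), ("pancreas", 100.0), ("spleen", 150.0), ("stomach", 140.0),
    ("thyroid", 20.0), ("adrenal", 12.0), ("testis", 25.0), ("bladder", 45.0),
]


@dataclass
class GeneratorParams:
    """Study-condition knobs for the synthetic universe and cohort."""

    seed: int
    n_toxins: int = 30
    n_compounds: int = 90
    n_reactions: int = 120
    n_bacteria: int = 50  # species
    max_strains_per_species: int = 3
    n_patients: int = 200
    n_tissues: int = 12
    n_host_genes: int = 800
    dir_primary_coverage: float = 0.35
    dir_secondary_coverage: float = 0.45
    n_planted_producers: int = 3
    n_planted_consumers: int = 3
    producer_toxins: int = 6  # exclusive-synthesis toxins per planted producer
    consumer_toxins: int = 5  # exclusive-decomposition toxins per planted consumer
    n_host_free_toxins: int = 4
    n_toxin_blocks: int = 0  # 2 = disjoint producer blocks for clustering tests
    presence_prob: float | tuple[float, float] = (0.05, 0.95)
    detect_prob_given_presence: float = 0.7
    protein_prob_given_mrna: float = 0.3
    mrna_log_mean: float = 2.0
    mrna_log_sd: float = 1.0
    expression_mixture: tuple[tuple[float, float, float], ...] = (
        (0.45, 0.3, 0.35),  # (weight, log10 mean, log10 sd): poorly expressed
        (0.55, 2.6, 0.4),  # well expressed
    )
    expression_noise_sd: float = 0.25
    concentration_mode: str = "null"  # null | linked
    concentration_noise_sd: float = 0.1

    def validate(self) -> None:
        probs = [
            self.dir_primary_coverage, self.dir_secondary_coverage,
            self.detect_prob_given_presence, self.protein_prob_given_mrna,
        ]
        pp = self.presence_prob
        probs.extend(pp if isinstance(pp, tuple) else (pp,))
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        for name in ("n_toxins", "n_compounds", "n_reactions", "n_patients",
                     "n_tissues", "n_host_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if abs(sum(w for w, _, _ in self.expression_mixture) - 1.0) > 1e-9:
            raise ValidationError("expression mixture weights must sum to 1")


@dataclass
class GroundTruth:
    """Generator-known structure used as the recovery target in tests."""

    producers: dict[str, set[str]] = field(default_factory=dict)
    consumers: dict[str, set[str]] = field(default_factory=dict)
    true_directions: dict[str, str] = field(default_factory=dict)
    host_enzyme_free: set[str] = field(default_factory=set)
    toxin_blocks: dict[str, int] = field(default_factory=dict)
    concentration_rule: str = "none"


def _substream(seed: int, channel: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), channel])


def _make_organisms(
    params: GeneratorParams, rng: np.random.Generator
) -> tuple[list[OrganismRecord], dict[int, list[str]]]:
    """Strain-level bacterial records plus the host; species index → strain ids."""
    pairs = [(g, e) for g in _GENERA for e in _EPITHETS]
    if params.n_bacteria > len(pairs):
        raise ValidationError(
            f"cannot name {params.n_bacteria} species from the pools"
        )
    chosen = rng.choice(len(pairs), size=params.n_bacteria, replace=False)
    organisms: list[OrganismRecord] = []
    species_strains: dict[int, list[str]] = {}
    for si, pi in enumerate(chosen):
        genus, epithet = pairs[int(pi)]
        n_strains = int(rng.integers(1, params.max_strains_per_species + 1))
        ids = []
        for k in range(n_strains):
            oid = f"B{si:03d}S{k + 1}"
            organisms.append(
                OrganismRecord(
                    organism_id=oid,
                    genus=genus,
                    species=epithet,
                    strain=f"strain-{k + 1}" if n_strains > 1 else None,
                    is_host=False,
                )
            )
            ids.append(oid)
        species_strains[si] = ids
    organisms.append(
        OrganismRecord(
            organism_id="HOST", genus="Homo", species="sapiens", is_host=True
        )
    )
    return organisms, species_strains


def generate_universe(
    params: GeneratorParams,
) -> tuple[ReferenceUniverse, GroundTruth]:
    """Generate a strain-level universe with planted capability structure.

    The returned universe passes ``load_reference_bundle`` validation
    unmodified; planted producer/consumer toxin sets reference the
    *collapsed* (species-level) organism identifiers, since capability
    analysis runs on collapsed repertoires.
    """
    params.validate()
    rng = _substream(params.seed, 0)
    truth = GroundTruth()

    # --- toxins and compounds -------------------------------------------
    n_named = len(_TOXIN_NAMES)
    toxins: dict[str, ToxinRecord] = {}
    toxin_compound: dict[str, str] = {}
    for i in range(params.n_toxins):
        tid = f"T{i + 1:03d}"
        name = _TOXIN_NAMES[i] if i < n_named else f"solute-{i + 1}"
        cid = f"C{i + 1:04d}"
        toxins[tid] = ToxinRecord(toxin_id=tid, name=name, compound_ids={cid})
        toxin_compound[tid] = cid
    n_extra = params.n_compounds - params.n_toxins
    if n_extra < 5:
        raise ValidationError("n_compounds must exceed n_toxins by at least 5")
    background_compounds = [
        f"C{params.n_toxins + j + 1:04d}" for j in range(n_extra)
    ]
    # a quarter of toxins get a synonym compound identifier
    synonym_pool = list(background_compounds)
    for tid in list(toxins)[:: 4]:
        toxins[tid].compound_ids.add(synonym_pool.pop())
    free_compounds = synonym_pool

    # --- organisms ------------------------------------------------------
    organisms, species_strains = _make_organisms(params, rng)
    collapsed = collapse_strains(organisms)
    species_key_to_id = {o.species_key: o.organism_id for o in collapsed}

    def collapsed_id(si: int) -> str:
        first = species_strains[si][0]
        rec = next(o for o in organisms if o.organism_id == first)
        return species_key_to_id[rec.species_key]

    # --- toxin role partition -------------------------------------------
    n_pool = max(params.producer_toxins, params.consumer_toxins)
    planted_needed = n_pool if (params.n_planted_producers or params.n_planted_consumers) else 0
    if planted_needed + params.n_host_free_toxins + 2 > params.n_toxins:
        raise ValidationError(
            "infeasible plant: more planted/host-free toxins than toxins available"
        )
    all_tids = list(toxins)
    planted_tids = all_tids[:planted_needed]
    background_tids = all_tids[planted_needed:]
    host_free = set(rng.choice(background_tids, size=params.n_host_free_toxins,
                               replace=False)) if params.n_host_free_toxins else set()
    truth.host_enzyme_free = {str(t) for t in host_free}

    n_species = params.n_bacteria
    n_planted_orgs = params.n_planted_producers + params.n_planted_consumers
    if n_planted_orgs > n_species:
        raise ValidationError("infeasible plant: more planted organisms than species")
    planted_species = list(rng.choice(n_species, size=n_planted_orgs, replace=False))
    producer_species = planted_species[: params.n_planted_producers]
    consumer_species = planted_species[params.n_planted_producers:]
    background_species = [s for s in range(n_species) if s not in planted_species]

    # --- reactions ------------------------------------------------------
    reactions: dict[str, ReactionRecord] = {}
    repertoire: dict[str, set[str]] = {o.organism_id: set() for o in organisms}
    used_ecs: set[str] = set()
    planted_rids: set[str] = set()
    toxin_rids: dict[str, list[str]] = {tid: [] for tid in toxins}

    def fresh_ec() -> str:
        while True:
            ec = (
                f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 21))}."
                f"{int(rng.integers(1, 21))}.{int(rng.integers(1, 100))}"
            )
            if ec not in used_ecs:
                used_ecs.add(ec)
                return ec

    def next_rid() -> str:
        return f"R{len(reactions) + 1:04d}"

    def pick_background(n: int) -> set[str]:
        return {str(c) for c in rng.choice(free_compounds, size=n, replace=False)}

    def add_reaction(**kw) -> ReactionRecord:
        rid = next_rid()
        rec = ReactionRecord(reaction_id=rid, **kw)
        reactions[rid] = rec
        return rec

    # planted producers: dedicated forward reactions producing their toxins
    for si in producer_species:
        tox_set = set(rng.choice(planted_tids, size=params.producer_toxins,
                                 replace=False)) if planted_tids else set()
        truth.producers[collapsed_id(si)] = {str(t) for t in tox_set}
        for tid in sorted(tox_set):
            cid = toxin_compound[str(tid)]
            rec = add_reaction(
                ec_numbers={fresh_ec()},
                substrates=pick_background(int(rng.integers(1, 3))),
                products={cid},
                pathway_ids={f"P{int(rng.integers(1, 13)):02d}"},
                topology_tags={cid: "downstream"},
                dir_primary="forward",
                dir_secondary="forward",
            )
            truth.true_directions[rec.reaction_id] = "forward"
            planted_rids.add(rec.reaction_id)
            toxin_rids[str(tid)].append(rec.reaction_id)
            for oid in species_strains[si]:
                repertoire[oid].add(rec.reaction_id)

    # planted consumers: dedicated forward reactions consuming their toxins
    for si in consumer_species:
        tox_set = set(rng.choice(planted_tids, size=params.consumer_toxins,
                                 replace=False)) if planted_tids else set()
        truth.consumers[collapsed_id(si)] = {str(t) for t in tox_set}
        for tid in sorted(tox_set):
            cid = toxin_compound[str(tid)]
            rec = add_reaction(
                ec_numbers={fresh_ec()},
                substrates={cid},
                products=pick_background(int(rng.integers(1, 3))),
                pathway_ids={f"P{int(rng.integers(1, 13)):02d}"},
                topology_tags={cid: "upstream"},
                dir_primary="forward",
                dir_secondary="forward",
            )
            truth.true_directions[rec.reaction_id] = "forward"
            planted_rids.add(rec.reaction_id)
            toxin_rids[str(tid)].append(rec.reaction_id)
            for oid in species_strains[si]:
                repertoire[oid].add(rec.reaction_id)

    # block structure for clustering fixtures
    blocks = params.n_toxin_blocks
    if blocks:
        if not background_species or len(background_species) < blocks:
            raise ValidationError("not enough background species for blocks")
        block_species = {
            b: background_species[b::blocks] for b in range(blocks)
        }
        for j, tid in enumerate(background_tids):
            truth.toxin_blocks[tid] = j % blocks

    # background toxin reactions: reversible, so they grant 'both' only
    for tid in background_tids:
        k = int(rng.integers(1, 4))
        for _ in range(k):
            cid = toxin_compound[tid]
            degenerate = rng.random() < 0.08
            if degenerate:
                substrates = {cid} | pick_background(1)
                products = {cid} | pick_background(1)
            elif rng.random() < 0.5:
                substrates, products = {cid}, pick_background(int(rng.integers(1, 3)))
            else:
                substrates, products = pick_background(int(rng.integers(1, 3))), {cid}
            reuse = used_ecs and rng.random() < 0.1
            ec = sorted(used_ecs)[int(rng.integers(0, len(used_ecs)))] if reuse else fresh_ec()
            rec = add_reaction(
                ec_numbers={ec},
                substrates=substrates,
                products=products,
                pathway_ids={f"P{int(rng.integers(1, 13)):02d}"},
                topology_tags={cid: str(rng.choice(["upstream", "downstream"]))},
                dir_primary="reversible",
                dir_secondary="reversible",
                degenerate=degenerate,
            )
            truth.true_directions[rec.reaction_id] = "reversible"
            toxin_rids[tid].append(rec.reaction_id)
            if blocks:
                pool = block_species[truth.toxin_blocks[tid]]
                members = [s for s in pool if rng.random() < 0.4]
                members.append(pool[0])  # block core species carries everything
            else:
                members = [s for s in range(n_species) if rng.random() < 0.25]
                if not members:
                    members = [int(rng.integers(0, n_species))]
            for si in set(members):
                for oid in species_strains[si]:
                    repertoire[oid].add(rec.reaction_id)
            if tid not in host_free and not blocks and rng.random() < 0.5:
                repertoire["HOST"].add(rec.reaction_id)

    # host coverage: every toxin outside the planted host-free set shares
    # at least one of its reactions with the host repertoire, so the
    # "no host enzyme" candidate set is exactly the planted one
    for tid, rids in toxin_rids.items():
        if tid in truth.host_enzyme_free or not rids:
            continue
        if not any(r in repertoire["HOST"] for r in rids):
            repertoire["HOST"].add(rids[0])

    if len(reactions) > params.n_reactions:
        raise ValidationError(
            f"infeasible plant: {len(reactions)} structural reactions exceed "
            f"n_reactions={params.n_reactions}"
        )

    # pure background reactions over non-toxin compounds (no links)
    while len(reactions) < params.n_reactions:
        substrates = pick_background(int(rng.integers(1, 3)))
        products = pick_background(int(rng.integers(1, 3))) - substrates
        if not products:
            continue
        true_dir = str(rng.choice(["forward", "reverse", "reversible"]))
        rec = add_reaction(
            ec_numbers={fresh_ec()},
            substrates=substrates,
            products=products,
            pathway_ids={f"P{int(rng.integers(1, 13)):02d}"},
            dir_primary=true_dir,
            dir_secondary=true_dir,
        )
        truth.true_directions[rec.reaction_id] = true_dir
        for si in range(n_species):
            if rng.random() < 0.2:
                for oid in species_strains[si]:
                    repertoire[oid].add(rec.reaction_id)
        if rng.random() < 0.3:
            repertoire["HOST"].add(rec.reaction_id)

    # every organism carries at least one reaction
    rid_list = sorted(reactions)
    for oid, reps in repertoire.items():
        if not reps:
            reps.add(rid_list[int(rng.integers(0, len(rid_list)))])

    # --- direction annotation coverage ----------------------------------
    # Coverage masks come from a dedicated substream so that, for a fixed
    # seed, raising a coverage fraction only ever adds annotations
    # (nested masks — the monotonicity tests rely on this). Planted
    # reactions keep their curated annotations regardless.
    cov_rng = _substream(params.seed, 7)
    for rid in sorted(reactions):
        u_p, u_s = cov_rng.random(2)
        if rid in planted_rids:
            continue
        rec = reactions[rid]
        true_dir = truth.true_directions[rid]
        rec.dir_primary = true_dir if u_p < params.dir_primary_coverage else "unknown"
        rec.dir_secondary = true_dir if u_s < params.dir_secondary_coverage else "unknown"

    for org in organisms:
        org.reaction_ids = repertoire[org.organism_id]

    universe = ReferenceUniverse(
        toxins=toxins,
        reactions=reactions,
        organisms={o.organism_id: o for o in organisms},
    )
    universe.validate()
    return universe, truth


def generate_cohort(
    universe: ReferenceUniverse, params: GeneratorParams
) -> CohortDetection:
    """Simulate patient-level detection for the universe's toxin enzymes.

    Enzymes are the EC numbers of toxin-linked bacterial reactions. Per
    patient and organism, presence is Bernoulli; an enzyme's mRNA is
    detected iff at least one carrier species is present and detection
    fires; counts are ceil-log-normal; protein detection is conditional
    on detected mRNA.
    """
    params.validate()
    rng = _substream(params.seed, 1)
    species = collapse_strains(list(universe.organisms.values()))
    bacteria = [o for o in species if not o.is_host]

    roles = toxin_reaction_roles(universe)
    toxin_rids = {rid for (_t, rid) in roles}
    enzymes = sorted(
        {
            ec
            for rid in toxin_rids
            for ec in universe.reactions[rid].ec_numbers
        }
    )
    enzyme_to_organisms: dict[str, set[str]] = {e: set() for e in enzymes}
    for org in bacteria:
        org_ecs = {
            ec
            for rid in org.reaction_ids
            if rid in toxin_rids
            for ec in universe.reactions[rid].ec_numbers
        }
        for ec in org_ecs:
            if ec in enzyme_to_organisms:
                enzyme_to_organisms[ec].add(org.organism_id)

    n_pat, n_org, n_enz = params.n_patients, len(bacteria), len(enzymes)
    patients = [f"P{i + 1:04d}" for i in range(n_pat)]
    org_ids = [o.organism_id for o in bacteria]

    pp = params.presence_prob
    if isinstance(pp, tuple):
        org_probs = rng.uniform(pp[0], pp[1], size=n_org)
    else:
        org_probs = np.full(n_org, float(pp))
    presence = rng.random((n_pat, n_org)) < org_probs[None, :]

    carrier = np.zeros((n_org, n_enz), dtype=bool)
    enz_index = {e: j for j, e in enumerate(enzymes)}
    for j, enz in enumerate(enzymes):
        for org in enzyme_to_organisms[enz]:
            carrier[org_ids.index(org), j] = True

    present_any = presence.astype(int) @ carrier.astype(int) > 0
    detected = present_any & (
        rng.random((n_pat, n_enz)) < params.detect_prob_given_presence
    )
    raw = np.ceil(
        rng.lognormal(params.mrna_log_mean, params.mrna_log_sd, size=(n_pat, n_enz))
    ).astype(int)
    counts = np.where(detected, raw, 0)
    protein = detected & (
        rng.random((n_pat, n_enz)) < params.protein_prob_given_mrna
    )

    return CohortDetection(
        enzyme_mrna=pd.DataFrame(counts, index=patients, columns=enzymes),
        enzyme_protein=pd.DataFrame(protein, index=patients, columns=enzymes),
        organism_presence=pd.DataFrame(presence, index=patients, columns=org_ids),
        enzyme_to_organisms=enzyme_to_organisms,
    )


def generate_host_expression(
    universe: ReferenceUniverse, params: GeneratorParams
) -> TissueExpression:
    """Gene × tissue expression from a two-component log-normal mixture.

    Host enzyme genes (one per EC in the host repertoire) come first, then
    background genes up to ``n_host_genes``; tissue weights follow typical
    adult organ masses.
    """
    params.validate()
    rng = _substream(params.seed, 2)

    host = universe.host
    host_ecs = sorted(
        {
            ec
            for rid in (host.reaction_ids if host else set())
            for ec in universe.reactions[rid].ec_numbers
        }
    )
    genes = [f"HG{i + 1:04d}" for i in range(max(params.n_host_genes, len(host_ecs)))]
    gene_ecs = {genes[i]: {ec} for i, ec in enumerate(host_ecs)}

    if params.n_tissues <= len(_TISSUE_WEIGHTS):
        tissue_items = _TISSUE_WEIGHTS[: params.n_tissues]
    else:
        extra = [
            (f"tissue_{j}", float(rng.uniform(20, 1500)))
            for j in range(params.n_tissues - len(_TISSUE_WEIGHTS))
        ]
        tissue_items = _TISSUE_WEIGHTS + extra
    tissues = [t for t, _ in tissue_items]
    weights = pd.Series({t: w for t, w in tissue_items}, name="grams")[tissues]

    comp_weights = np.array([w for w, _, _ in params.expression_mixture])
    comp_means = np.array([m for _, m, _ in params.expression_mixture])
    comp_sds = np.array([s for _, _, s in params.expression_mixture])
    comp = rng.choice(len(comp_weights), size=len(genes), p=comp_weights)
    base_log10 = rng.normal(comp_means[comp], comp_sds[comp])
    noise = rng.normal(0.0, params.expression_noise_sd, size=(len(genes), len(tissues)))
    matrix = np.power(10.0, base_log10[:, None] + noise)

    expr = TissueExpression(
        expression=pd.DataFrame(matrix, index=genes, columns=tissues),
        tissue_weights=weights,
        gene_ecs=gene_ecs,
    )
    expr.validate()
    return expr


def generate_concentrations(
    universe: ReferenceUniverse,
    summary: pd.DataFrame,
    params: GeneratorParams,
) -> dict[str, ToxinRecord]:
    """Plasma concentrations per toxin, null or linked to producer counts.

    ``null`` mode draws concentrations independent of ``n_bacteria``;
    ``linked`` mode makes the uremic concentration monotone in
    ``n_bacteria`` up to multiplicative log-normal noise.
    """
    params.validate()
    rng = _substream(params.seed, 3)
    n_bact = dict(zip(summary["toxin_id"], summary["n_bacteria"]))

    if params.concentration_mode == "linked":
        values = [n_bact.get(t, 0) for t in universe.toxins]
        if len(set(values)) <= 1:
            raise ValidationError(
                "linked mode needs variation in n_bacteria; all counts equal"
            )

    out: dict[str, ToxinRecord] = {}
    for tid, tox in universe.toxins.items():
        if params.concentration_mode == "null":
            uremic = float(rng.lognormal(1.0, 1.0))
        elif params.concentration_mode == "linked":
            noise = float(rng.normal(0.0, params.concentration_noise_sd))
            uremic = float((n_bact.get(tid, 0) + 1.0) * np.exp(noise))
        else:
            raise ValidationError(
                f"unknown concentration_mode {params.concentration_mode!r}"
            )
        normal = uremic * float(rng.uniform(0.05, 0.5))
        out[tid] = replace(tox, conc_normal=normal, conc_uremic=uremic)
    return out


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Flat ground-truth table for writing alongside a generated bundle."""
    rows: list[dict[str, str]] = []
    for org, toxs in sorted(truth.producers.items()):
        rows.append({"kind": "producer", "key": org, "value": "|".join(sorted(toxs))})
    for org, toxs in sorted(truth.consumers.items()):
        rows.append({"kind": "consumer", "key": org, "value": "|".join(sorted(toxs))})
    for rid, d in sorted(truth.true_directions.items()):
        rows.append({"kind": "direction", "key": rid, "value": d})
    for tid in sorted(truth.host_enzyme_free):
        rows.append({"kind": "host_enzyme_free", "key": tid, "value": ""})
    for tid, b in sorted(truth.toxin_blocks.items()):
        rows.append({"kind": "toxin_block", "key": tid, "value": str(b)})
    rows.append({"kind": "concentration_rule", "key": "mode", "value": truth.concentration_rule})
    return pd.DataFrame(rows, columns=["kind", "key", "value"])


def params_dict(params: GeneratorParams) -> dict:
    return dataclasses.asdict(params)
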