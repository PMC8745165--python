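"""End-to-end orchestration: load or generate inputs, run every analysis
stage in dependency order, emit the report tables and a run manifest.

Stage order: load/generate → link → directions → capability → host
abundance → cohort prevalence → association. Every output is TSV; the
manifest is JSON carrying the seed, a config hash, and per-file row counts
so headline stage numbers are auditable against the emitted files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    concentration_correlation,
    merges_frame,
    synthesis_profile,
    toxin_cluster,
)
from .capability import (
    classify_capability,
    direction_counts,
    directions_frame,
    exclusive_reaction_counts,
    rank_producers_consumers,
    ranking_frames,
    resolve_directions,
)
from .cohort_prevalence import (
    CohortDetection,
    enzyme_prevalence,
    load_cohort,
    organism_repertoire_summary,
    toxin_union_prevalence,
    write_cohort,
)
from .errors import StageError, ValidationError
from .host_abundance import (
    abundance_distribution,
    load_expression,
    organism_abundance,
    rank_toxin_enzymes,
    write_expression,
)
from .linkage import (
    build_links,
    links_frame,
    list_toxins_without_host_enzymes,
    summarize_toxins,
    toxin_reaction_roles,
)
from .reference_io import (
    ReferenceUniverse,
    ec_matches,
    load_reference_bundle,
    write_reference_bundle,
)
from .synthetic_data import (
    GeneratorParams,
    generate_cohort,
    generate_concentrations,
    generate_host_expression,
    generate_universe,
    ground_truth_frame,
)

log = logging.getLogger("toxsource")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one input source."""

    out_dir: str
    input_dir: str | None = None
    generator: GeneratorParams | None = None
    mode: str = "strict"  # strict | topology
    min_synth: int = 5
    min_decomp: int = 4
    reversible_counts: str = "both"
    correlation_method: str = "spearman"
    cluster_distance: str = "jaccard"
    cluster_linkage: str = "average"
    flag_k: int = 5  # bottom-/top-k flags in the host enzyme ranking

    def validate(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ValidationError(
                "exactly one of input_dir or generator params must be supplied"
            )
        if self.min_synth < 0 or self.min_decomp < 0:
            raise ValidationError("thresholds must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            if seed is not None:
                gen["seed"] = seed
            gen = GeneratorParams(**gen)
        cfg = cls(out_dir=out_dir, generator=gen, **raw)
        cfg.validate()
        return cfg


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict
    frames: dict[str, pd.DataFrame] = field(default_factory=dict)


def map_toxins_to_cohort_enzymes(
    universe: ReferenceUniverse, cohort_enzymes: list[str]
) -> dict[str, list[str]]:
    """Map each toxin to the cohort enzymes of its linked reactions.

    The EC join honors dash wildcards in either direction, since
    metatranscriptome annotations are often partial.
    """
    roles = toxin_reaction_roles(universe)
    toxin_ecs: dict[str, set[str]] = {}
    for (tox, rid) in roles:
        toxin_ecs.setdefault(tox, set()).update(universe.reactions[rid].ec_numbers)
    out: dict[str, list[str]] = {}
    for tox, ecs in sorted(toxin_ecs.items()):
        matched = [
            enz
            for enz in cohort_enzymes
            if any(ec_matches(enz, ec) or ec_matches(ec, enz) for ec in ecs)
        ]
        out[tox] = matched
    return out


def host_enzyme_gene_map(
    universe: ReferenceUniverse,
    summary: pd.DataFrame,
    gene_ecs: dict[str, set[str]],
    max_enzymes: int = 3,
) -> dict[str, set[str]]:
    """Toxin → host gene set, restricted to toxins with 1..max host enzymes.

    These are the solutes for which the host has only a handful of
    synthesizing enzymes, so whole-organism abundance of those few genes
    is informative about the host's contribution.
    """
    host = universe.host
    if host is None:
        return {}
    ec_to_gene: dict[str, str] = {}
    for gene, ecs in gene_ecs.items():
        for ec in ecs:
            ec_to_gene.setdefault(ec, gene)

    roles = toxin_reaction_roles(universe)
    out: dict[str, set[str]] = {}
    eligible = set(
        summary.loc[
            (summary["n_host_enzymes"] >= 1)
            & (summary["n_host_enzymes"] <= max_enzymes),
            "toxin_id",
        ]
    )
    for (tox, rid) in roles:
        if tox not in eligible or rid not in host.reaction_ids:
            continue
        for ec in universe.reactions[rid].ec_numbers:
            gene = ec_to_gene.get(ec)
            if gene:
                out.setdefault(tox, set()).add(gene)
    return out


def _write(df: pd.DataFrame, path: Path, manifest_counts: dict, *, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest_counts[path.name] = int(len(df))
    log.info("wrote %s (%d rows)", path.name, len(df))


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    frames: dict[str, pd.DataFrame] = {}

    # --- stage: load / generate ----------------------------------------
    try:
        if config.generator is not None:
            universe_raw, truth = generate_universe(config.generator)
            cohort = generate_cohort(universe_raw, config.generator)
            expr = generate_host_expression(universe_raw, config.generator)
            write_reference_bundle(universe_raw, out / "inputs")
            write_cohort(cohort, out / "inputs")
            write_expression(expr, out / "inputs")
            truth_df = ground_truth_frame(truth)
            _write(truth_df, out / "inputs" / "ground_truth.tsv", counts)
            universe = load_reference_bundle(out / "inputs")
        else:
            universe = load_reference_bundle(config.input_dir)
            cohort = load_cohort(config.input_dir)
            expr = load_expression(config.input_dir)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise StageError("load", str(exc)) from exc
    log.info(
        "universe: %d toxins, %d reactions, %d organisms (collapsed)",
        len(universe.toxins), len(universe.reactions), len(universe.organisms),
    )

    host = universe.host
    host_id = host.organism_id if host else None
    names = {o.organism_id: o.display_name for o in universe.organisms.values()}

    # --- stage: link ----------------------------------------------------
    try:
        links = build_links(universe)
        summary = summarize_toxins(links, universe)
        no_host = list_toxins_without_host_enzymes(summary)
    except Exception as exc:
        raise StageError("link", str(exc)) from exc
    log.info("link table: %d links; %d toxins without host enzymes",
             len(links), len(no_host))
    frames["links"] = links_frame(links)
    _write(frames["links"], out / "links.tsv", counts)
    frames["toxin_summary"] = summary
    _write(summary, out / "toxin_summary.tsv", counts)

    # --- stage: directions + capability ---------------------------------
    try:
        directions = resolve_directions(universe.reactions.values())
        dcounts = direction_counts(directions)
        matrix = classify_capability(
            links,
            directions,
            universe.reactions,
            config.mode,
            reversible_counts=config.reversible_counts,
            toxin_compounds={t.toxin_id: t.compound_ids for t in universe.toxins.values()},
        )
        ranking = rank_producers_consumers(
            matrix,
            config.min_synth,
            config.min_decomp,
            names=names,
            exclude={host_id} if host_id else frozenset(),
        )
    except Exception as exc:
        raise StageError("capability", str(exc)) from exc
    log.info("directions resolved: %d of %d (primary %d, secondary %d)",
             dcounts["resolved"], dcounts["total"], dcounts["primary"],
             dcounts["secondary"])
    frames["directions"] = directions_frame(directions)
    _write(frames["directions"], out / "directions.tsv", counts)
    frames["capability_matrix"] = matrix.to_frame()
    _write(frames["capability_matrix"], out / "capability_matrix.tsv", counts)
    prod_df, cons_df = ranking_frames(ranking, names)
    toxin_compounds = {t.toxin_id: t.compound_ids for t in universe.toxins.values()}
    synth_rxn, decomp_rxn = exclusive_reaction_counts(
        links, directions, universe.reactions, matrix,
        reversible_counts=config.reversible_counts,
        toxin_compounds=toxin_compounds,
    )
    prod_df["n_synthesis_reactions"] = [
        synth_rxn.get(o, 0) for o in prod_df["organism_id"]
    ]
    cons_df["n_decomposition_reactions"] = [
        decomp_rxn.get(o, 0) for o in cons_df["organism_id"]
    ]
    frames["producers"], frames["consumers"] = prod_df, cons_df
    _write(prod_df, out / "producers.tsv", counts)
    _write(cons_df, out / "consumers.tsv", counts)

    # --- stage: host abundance ------------------------------------------
    try:
        abundance = organism_abundance(expr)
        gene_map = host_enzyme_gene_map(universe, summary, expr.gene_ecs)
        highlight = {g for gs in gene_map.values() for g in gs}
        ranks = (
            rank_toxin_enzymes(abundance, gene_map, k=config.flag_k)
            if gene_map
            else pd.DataFrame(
                columns=["toxin_id", "gene", "abundance", "rank",
                         "flag_bottom", "flag_top"]
            )
        )
        hist, highlights = abundance_distribution(abundance, highlight)
    except Exception as exc:
        raise StageError("host_abundance", str(exc)) from exc
    frames["organism_abundance"] = abundance.reset_index()
    _write(frames["organism_abundance"], out / "organism_abundance.tsv", counts)
    frames["toxin_enzyme_ranks"] = ranks
    _write(ranks, out / "toxin_enzyme_ranks.tsv", counts)
    frames["abundance_histogram"] = hist
    _write(hist, out / "abundance_histogram.tsv", counts)
    _write(highlights, out / "abundance_highlights.tsv", counts)

    # --- stage: cohort prevalence ---------------------------------------
    try:
        toxin_enz = map_toxins_to_cohort_enzymes(universe, cohort.enzymes)
        enz_prev = enzyme_prevalence(cohort)
        tox_prev = toxin_union_prevalence(cohort, toxin_enz)
        org_summary = organism_repertoire_summary(
            cohort, toxin_enz, known_organisms=set(universe.organisms)
        )
    except Exception as exc:
        raise StageError("cohort", str(exc)) from exc
    log.info("cohort: %d patients, %d enzymes, %d detected toxins",
             len(cohort.patients), len(cohort.enzymes),
             int((tox_prev["pct_any_enzyme"] > 0).sum()))
    frames["enzyme_prevalence"] = enz_prev
    _write(enz_prev, out / "enzyme_prevalence.tsv", counts)
    frames["toxin_prevalence"] = tox_prev
    _write(tox_prev, out / "toxin_prevalence.tsv", counts)
    frames["organism_summary"] = org_summary
    _write(org_summary, out / "organism_summary.tsv", counts)

    # --- stage: association ---------------------------------------------
    try:
        if config.generator is not None:
            universe.toxins = generate_concentrations(
                universe, summary, config.generator
            )
        corr_rows = []
        for condition in ("normal", "uremic"):
            res = concentration_correlation(
                summary, universe.toxins, condition, config.correlation_method
            )
            corr_rows.append(
                {
                    "condition": res.condition,
                    "coefficient": "" if res.coefficient is None else res.coefficient,
                    "p_value": "" if res.p_value is None else res.p_value,
                    "n": res.n,
                    "status": res.status,
                }
            )
        corr_df = pd.DataFrame(
            corr_rows, columns=["condition", "coefficient", "p_value", "n", "status"]
        )

        profile = synthesis_profile(links, matrix)
        if host_id and host_id in profile.columns:
            profile = profile.drop(columns=[host_id])
        nonzero = profile.loc[profile.sum(axis=1) > 0] if not profile.empty else profile
        if len(nonzero) >= 2:
            cluster = toxin_cluster(
                profile, config.cluster_distance, config.cluster_linkage
            )
            dend = merges_frame(cluster)
            heat = cluster.ordered_matrix.reset_index()
        else:
            cluster = None
            dend = pd.DataFrame(columns=["left", "right", "height", "size"])
            heat = pd.DataFrame(columns=["toxin_id"])
    except Exception as exc:
        raise StageError("association", str(exc)) from exc
    frames["correlation"] = corr_df
    _write(corr_df, out / "correlation.tsv", counts)
    frames["dendrogram"] = dend
    _write(dend, out / "dendrogram.tsv", counts)
    frames["heatmap_matrix"] = heat
    _write(heat, out / "heatmap_matrix.tsv", counts)

    # --- manifest --------------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # hash covers the analysis, not the destination
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.generator.seed if config.generator else None,
        "config_hash": cfg_hash,
        "stage_counts": {
            "toxins": len(universe.toxins),
            "reactions": len(universe.reactions),
            "organisms": len(universe.organisms),
            "links": len(links),
            "toxins_linked": int((summary["n_bacteria"] + summary["n_reactions"] > 0).sum()),
            "toxins_without_host_enzymes": len(no_host),
            "directions_resolved": dcounts["resolved"],
            "directions_primary": dcounts["primary"],
            "directions_secondary": dcounts["secondary"],
            "cohort_patients": len(cohort.patients),
            "cohort_enzymes": len(cohort.enzymes),
        },
        "file_rows": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ReportBundle(out_dir=out, manifest=manifest, frames=frames)
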