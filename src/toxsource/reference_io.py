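"""Reading, validation and normalization of the tabular reference snapshot.

The reference universe is a joined snapshot of four flat tables:

* ``toxins.tsv`` — uremic retention solutes with their compound identifiers
  and optional normal/uremic plasma concentrations;
* ``reactions.tsv`` — an enzymatic-reaction catalog with EC numbers,
  substrate/product compound sets, pathway membership, optional pathway
  topology tags (is a compound upstream or downstream in the pathway), and
  direction annotations from a primary (module-style) and a secondary
  (curated-pathway-style) source;
* ``organisms.tsv`` — bacterial strains/species plus exactly one host
  organism, each with its reaction repertoire;
* ``compound_map.tsv`` — a derived compound → toxin index, re-emitted for
  convenience and ignored on load (the toxin table is authoritative).

All files are UTF-8 TSV with a single header row; set-valued cells are
pipe-delimited; an empty cell means missing.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

DIRECTION_CODES = ("forward", "reverse", "reversible", "unknown")
TOPOLOGY_CODES = ("upstream", "downstream")

_SET_SEP = "|"
_TAG_SEP = ":"

_EC_RE = re.compile(r"^(\d+|-)(\.(\d+|-)){0,3}$")


def validate_ec(raw: str) -> str:
    """Normalize an EC number token to canonical dotted form.

    Partial EC numbers with dash segments (``4.1.1.-``) are accepted and
    preserved. An optional ``EC``/``ec`` prefix is stripped.
    """
    token = str(raw).strip()
    if token.lower().startswith("ec"):
        token = token[2:].lstrip(" :").strip()
    if not _EC_RE.match(token):
        raise ValidationError(f"malformed EC number token: {raw!r}")
    return token


def ec_matches(pattern: str, ec: str) -> bool:
    """True if ``ec`` is covered by ``pattern``, honoring dash wildcards.

    ``4.1.1.-`` matches ``4.1.1.85``; a shorter pattern matches any
    completion of its given fields. Exact tokens match only themselves.
    """
    p_fields = pattern.split(".")
    e_fields = ec.split(".")
    if len(p_fields) > len(e_fields):
        return False
    return all(p == "-" or p == e for p, e in zip(p_fields, e_fields))


@dataclass
class ToxinRecord:
    toxin_id: str
    name: str
    compound_ids: set[str] = field(default_factory=set)
    conc_normal: float | None = None
    conc_uremic: float | None = None


@dataclass
class ReactionRecord:
    reaction_id: str
    ec_numbers: set[str] = field(default_factory=set)
    substrates: set[str] = field(default_factory=set)
    products: set[str] = field(default_factory=set)
    pathway_ids: set[str] = field(default_factory=set)
    topology_tags: dict[str, str] = field(default_factory=dict)
    dir_primary: str = "unknown"
    dir_secondary: str = "unknown"
    degenerate: bool = False


@dataclass
class OrganismRecord:
    organism_id: str
    genus: str
    species: str
    strain: str | None = None
    is_host: bool = False
    reaction_ids: set[str] = field(default_factory=set)

    @property
    def species_key(self) -> tuple[str, str]:
        """Case-insensitive (genus, species) token pair.

        ``sp.`` is an ordinary species token, so genus-level taxa such as
        "Brevundimonas sp." stay distinct records.
        """
        return (self.genus.strip().lower(), self.species.strip().lower())

    @property
    def display_name(self) -> str:
        return f"{self.genus} {self.species}"


@dataclass
class ReferenceUniverse:
    toxins: dict[str, ToxinRecord] = field(default_factory=dict)
    reactions: dict[str, ReactionRecord] = field(default_factory=dict)
    organisms: dict[str, OrganismRecord] = field(default_factory=dict)

    @property
    def compound_index(self) -> dict[str, set[str]]:
        """Map compound_id → set of toxin_ids carrying it."""
        index: dict[str, set[str]] = {}
        for tox in self.toxins.values():
            for cid in tox.compound_ids:
                index.setdefault(cid, set()).add(tox.toxin_id)
        return index

    @property
    def host(self) -> OrganismRecord | None:
        hosts = [o for o in self.organisms.values() if o.is_host]
        return hosts[0] if hosts else None

    def validate(self) -> None:
        hosts = [o for o in self.organisms.values() if o.is_host]
        if len(hosts) > 1:
            raise ValidationError(
                f"expected at most one host organism, found {len(hosts)}: "
                + ", ".join(o.organism_id for o in hosts)
            )
        for tox in self.toxins.values():
            for conc in (tox.conc_normal, tox.conc_uremic):
                if conc is not None and conc < 0:
                    raise ValidationError(
                        f"negative concentration on toxin {tox.toxin_id}"
                    )
        for rxn in self.reactions.values():
            for ec in rxn.ec_numbers:
                validate_ec(ec)
            if rxn.dir_primary not in DIRECTION_CODES:
                raise ValidationError(
                    f"reaction {rxn.reaction_id}: bad dir_primary {rxn.dir_primary!r}"
                )
            if rxn.dir_secondary not in DIRECTION_CODES:
                raise ValidationError(
                    f"reaction {rxn.reaction_id}: bad dir_secondary {rxn.dir_secondary!r}"
                )
            overlap = rxn.substrates & rxn.products
            if overlap and not rxn.degenerate:
                raise ValidationError(
                    f"reaction {rxn.reaction_id}: compounds {sorted(overlap)} on "
                    "both sides but not flagged degenerate"
                )
            for cid, tag in rxn.topology_tags.items():
                if tag not in TOPOLOGY_CODES:
                    raise ValidationError(
                        f"reaction {rxn.reaction_id}: bad topology tag {tag!r} for {cid}"
                    )
        dangling_rows = []
        for org in self.organisms.values():
            missing = org.reaction_ids - self.reactions.keys()
            if missing:
                dangling_rows.append((org.organism_id, sorted(missing)))
        if dangling_rows:
            detail = "; ".join(f"{oid}: {m}" for oid, m in dangling_rows)
            raise ValidationError(f"dangling reaction keys in organism records: {detail}")


def collapse_strains(
    organisms: Iterable[OrganismRecord],
) -> list[OrganismRecord]:
    """Collapse strain-level records into one record per (genus, species).

    The collapsed repertoire is the union over the strains; the collapsed
    organism_id is the lexicographically smallest member id so the
    operation is deterministic and idempotent. The host record is passed
    through unchanged.
    """
    groups: dict[tuple[str, str], list[OrganismRecord]] = {}
    order: list[tuple[str, str]] = []
    for org in organisms:
        if not org.genus.strip() or not org.species.strip():
            raise ValidationError(
                f"organism {org.organism_id}: genus and species must be non-empty"
            )
        key = org.species_key
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(org)

    collapsed: list[OrganismRecord] = []
    for key in order:
        members = groups[key]
        host_flags = {m.is_host for m in members}
        if len(host_flags) > 1:
            raise ValidationError(
                f"conflicting is_host flags within species group {key}"
            )
        if len(members) == 1:
            collapsed.append(members[0])
            continue
        rep = min(members, key=lambda m: m.organism_id)
        union: set[str] = set()
        for m in members:
            union |= m.reaction_ids
        collapsed.append(
            replace(rep, strain=None, reaction_ids=union)
        )
    return collapsed


# ---------------------------------------------------------------------------
# TSV serialization

TOXIN_COLS = ["toxin_id", "name", "compound_ids", "conc_normal", "conc_uremic"]
REACTION_COLS = [
    "reaction_id", "ec_numbers", "substrates", "products", "pathway_ids",
    "topology_tags", "dir_primary", "dir_secondary", "degenerate",
]
ORGANISM_COLS = ["organism_id", "genus", "species", "strain", "is_host", "reaction_ids"]
COMPOUND_MAP_COLS = ["compound_id", "toxin_ids"]

FILE_SCHEMAS = {
    "toxins.tsv": TOXIN_COLS,
    "reactions.tsv": REACTION_COLS,
    "organisms.tsv": ORGANISM_COLS,
}


def _join_set(values: Iterable[str]) -> str:
    return _SET_SEP.join(sorted(values))


def _split_set(cell: str) -> set[str]:
    cell = cell.strip()
    if not cell:
        return set()
    return {tok for tok in cell.split(_SET_SEP) if tok}


def _join_tags(tags: Mapping[str, str]) -> str:
    return _SET_SEP.join(f"{cid}{_TAG_SEP}{tag}" for cid, tag in sorted(tags.items()))


def _split_tags(cell: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for tok in _split_set(cell):
        if _TAG_SEP not in tok:
            raise ValidationError(f"malformed topology tag cell entry: {tok!r}")
        cid, tag = tok.split(_TAG_SEP, 1)
        out[cid] = tag
    return out


def _read_table(path: Path, expected_cols: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != expected_cols:
        raise SchemaError(
            f"{path}: unexpected header {list(df.columns)}; expected {expected_cols}"
        )
    return df


def load_reference_bundle(
    directory: str | Path,
    *,
    collapse: bool = True,
) -> ReferenceUniverse:
    """Load and validate a reference bundle from ``directory``.

    With ``collapse=True`` (default), strain-level organism records are
    merged to species level on the way in.
    """
    directory = Path(directory)
    tox_df = _read_table(directory / "toxins.tsv", TOXIN_COLS)
    rxn_df = _read_table(directory / "reactions.tsv", REACTION_COLS)
    org_df = _read_table(directory / "organisms.tsv", ORGANISM_COLS)

    toxins: dict[str, ToxinRecord] = {}
    for row in tox_df.itertuples(index=False):
        if row.toxin_id in toxins:
            raise ValidationError(f"duplicate toxin_id {row.toxin_id}")
        toxins[row.toxin_id] = ToxinRecord(
            toxin_id=row.toxin_id,
            name=row.name,
            compound_ids=_split_set(row.compound_ids),
            conc_normal=float(row.conc_normal) if row.conc_normal else None,
            conc_uremic=float(row.conc_uremic) if row.conc_uremic else None,
        )

    reactions: dict[str, ReactionRecord] = {}
    for row in rxn_df.itertuples(index=False):
        if row.reaction_id in reactions:
            raise ValidationError(f"duplicate reaction_id {row.reaction_id}")
        reactions[row.reaction_id] = ReactionRecord(
            reaction_id=row.reaction_id,
            ec_numbers={validate_ec(e) for e in _split_set(row.ec_numbers)},
            substrates=_split_set(row.substrates),
            products=_split_set(row.products),
            pathway_ids=_split_set(row.pathway_ids),
            topology_tags=_split_tags(row.topology_tags),
            dir_primary=row.dir_primary or "unknown",
            dir_secondary=row.dir_secondary or "unknown",
            degenerate=row.degenerate.strip().lower() in ("1", "true", "yes"),
        )

    organisms_list: list[OrganismRecord] = []
    for row in org_df.itertuples(index=False):
        organisms_list.append(
            OrganismRecord(
                organism_id=row.organism_id,
                genus=row.genus,
                species=row.species,
                strain=row.strain or None,
                is_host=row.is_host.strip().lower() in ("1", "true", "yes"),
                reaction_ids=_split_set(row.reaction_ids),
            )
        )
    ids = [o.organism_id for o in organisms_list]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate organism_id in organisms.tsv")
    if collapse:
        organisms_list = collapse_strains(organisms_list)

    universe = ReferenceUniverse(
        toxins=toxins,
        reactions=reactions,
        organisms={o.organism_id: o for o in organisms_list},
    )
    universe.validate()
    return universe


def _fmt_opt(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_reference_bundle(universe: ReferenceUniverse, directory: str | Path) -> None:
    """Re-emit a universe as the four-bundle TSV schema, deterministically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    tox_rows = [
        {
            "toxin_id": t.toxin_id,
            "name": t.name,
            "compound_ids": _join_set(t.compound_ids),
            "conc_normal": _fmt_opt(t.conc_normal),
            "conc_uremic": _fmt_opt(t.conc_uremic),
        }
        for t in sorted(universe.toxins.values(), key=lambda t: t.toxin_id)
    ]
    pd.DataFrame(tox_rows, columns=TOXIN_COLS).to_csv(
        directory / "toxins.tsv", sep="\t", index=False
    )

    rxn_rows = [
        {
            "reaction_id": r.reaction_id,
            "ec_numbers": _join_set(r.ec_numbers),
            "substrates": _join_set(r.substrates),
            "products": _join_set(r.products),
            "pathway_ids": _join_set(r.pathway_ids),
            "topology_tags": _join_tags(r.topology_tags),
            "dir_primary": r.dir_primary,
            "dir_secondary": r.dir_secondary,
            "degenerate": "true" if r.degenerate else "false",
        }
        for r in sorted(universe.reactions.values(), key=lambda r: r.reaction_id)
    ]
    pd.DataFrame(rxn_rows, columns=REACTION_COLS).to_csv(
        directory / "reactions.tsv", sep="\t", index=False
    )

    org_rows = [
        {
            "organism_id": o.organism_id,
            "genus": o.genus,
            "species": o.species,
            "strain": o.strain or "",
            "is_host": "true" if o.is_host else "false",
            "reaction_ids": _join_set(o.reaction_ids),
        }
        for o in sorted(universe.organisms.values(), key=lambda o: o.organism_id)
    ]
    pd.DataFrame(org_rows, columns=ORGANISM_COLS).to_csv(
        directory / "organisms.tsv", sep="\t", index=False
    )

    map_rows = [
        {"compound_id": cid, "toxin_ids": _join_set(tids)}
        for cid, tids in sorted(universe.compound_index.items())
    ]
    pd.DataFrame(map_rows, columns=COMPOUND_MAP_COLS).to_csv(
        directory / "compound_map.tsv", sep="\t", index=False
    )
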