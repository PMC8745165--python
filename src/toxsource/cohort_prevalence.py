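"""Patient-level prevalence of enzymes, toxins and bacteria.

Works on a metatranscriptome/proteome detection cohort: per-patient mRNA
counts per enzyme (0 = undetected), boolean protein detection, and boolean
organism presence. Detection is presence/absence (count > 0) with no
abundance cutoff; within-patient mRNA abundance enters only through
quartile ranks, so sequencing depth never needs normalizing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class CohortDetection:
    """Patient × enzyme and patient × organism detection matrices."""

    enzyme_mrna: pd.DataFrame  # patients × enzymes, non-negative counts
    enzyme_protein: pd.DataFrame  # patients × enzymes, bool
    organism_presence: pd.DataFrame  # patients × organisms, bool
    enzyme_to_organisms: dict[str, set[str]] = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return list(self.enzyme_mrna.index)

    @property
    def enzymes(self) -> list[str]:
        return list(self.enzyme_mrna.columns)

    def validate(self) -> None:
        if list(self.enzyme_protein.index) != list(self.enzyme_mrna.index):
            raise ValidationError("protein and mRNA matrices disagree on patients")
        if list(self.enzyme_protein.columns) != list(self.enzyme_mrna.columns):
            raise ValidationError("protein and mRNA matrices disagree on enzymes")
        if list(self.organism_presence.index) != list(self.enzyme_mrna.index):
            raise ValidationError("organism matrix disagrees on patients")
        if (self.enzyme_mrna.to_numpy() < 0).any():
            raise ValidationError("negative mRNA count in cohort")
        unknown = set(self.enzyme_to_organisms) - set(self.enzymes)
        if unknown:
            raise ValidationError(
                f"enzyme_to_organisms keys absent from matrices: {sorted(unknown)}"
            )


def write_cohort(cohort: CohortDetection, directory) -> None:
    """Write a cohort as dense long-form TSVs (one row per cell)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mrna = cohort.enzyme_mrna.stack().rename("count").reset_index()
    mrna.columns = ["patient", "enzyme", "count"]
    mrna.to_csv(directory / "cohort_mrna.tsv", sep="\t", index=False)
    prot = cohort.enzyme_protein.astype(bool).stack().rename("detected").reset_index()
    prot.columns = ["patient", "enzyme", "detected"]
    prot.to_csv(directory / "cohort_protein.tsv", sep="\t", index=False)
    orgs = cohort.organism_presence.astype(bool).stack().rename("present").reset_index()
    orgs.columns = ["patient", "organism", "present"]
    orgs.to_csv(directory / "cohort_organisms.tsv", sep="\t", index=False)
    emap = pd.DataFrame(
        [
            {"enzyme": e, "organism_ids": "|".join(sorted(o))}
            for e, o in sorted(cohort.enzyme_to_organisms.items())
        ],
        columns=["enzyme", "organism_ids"],
    )
    emap.to_csv(directory / "cohort_enzyme_map.tsv", sep="\t", index=False)


def load_cohort(directory) -> CohortDetection:
    """Load a cohort from the dense long-form TSVs written by ``write_cohort``."""
    from pathlib import Path

    from .errors import SchemaError

    directory = Path(directory)
    frames = {}
    schemas = {
        "cohort_mrna.tsv": ["patient", "enzyme", "count"],
        "cohort_protein.tsv": ["patient", "enzyme", "detected"],
        "cohort_organisms.tsv": ["patient", "organism", "present"],
        "cohort_enzyme_map.tsv": ["enzyme", "organism_ids"],
    }
    for fname, cols in schemas.items():
        path = directory / fname
        if not path.exists():
            raise SchemaError(f"missing input file: {path}")
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if list(df.columns) != cols:
            raise SchemaError(
                f"{path}: unexpected header {list(df.columns)}; expected {cols}"
            )
        frames[fname] = df

    def pivot(df, value_col, caster):
        wide = df.pivot(index=df.columns[0], columns=df.columns[1], values=value_col)
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        wide.index.name = None
        wide.columns.name = None
        return wide.map(caster)

    as_bool = lambda v: str(v).strip().lower() in ("1", "true", "yes")
    mrna = pivot(frames["cohort_mrna.tsv"], "count", lambda v: int(float(v)))
    prot = pivot(frames["cohort_protein.tsv"], "detected", as_bool)
    orgs = pivot(frames["cohort_organisms.tsv"], "present", as_bool)
    prot = prot.reindex(index=mrna.index, columns=mrna.columns, fill_value=False)
    orgs = orgs.reindex(index=mrna.index)
    emap = {
        row.enzyme: set(t for t in row.organism_ids.split("|") if t)
        for row in frames["cohort_enzyme_map.tsv"].itertuples(index=False)
    }
    cohort = CohortDetection(
        enzyme_mrna=mrna, enzyme_protein=prot, organism_presence=orgs,
        enzyme_to_organisms=emap,
    )
    cohort.validate()
    return cohort


def assign_quartiles(
    cohort: CohortDetection,
) -> tuple[pd.DataFrame, pd.Series]:
    """Within-patient abundance quartiles of detected enzyme mRNAs.

    For each patient, the nonzero counts of all enzymes are ranked
    (ties get the minimum rank) and cut into four classes:
    Q = ceil(4 · rank / n_detected), so Q1 is the lowest-abundance quarter
    and Q4 the highest. Zero counts get NA. The per-enzyme summary class is
    the modal quartile across patients where the enzyme was detected, ties
    resolved toward the lower quartile.

    Returns ``(per_patient, summary)``: a patient × enzyme frame of labels
    (``pd.NA`` where undetected) and an enzyme-indexed Series of summary
    labels (``pd.NA`` for enzymes never detected).
    """
    cohort.validate()
    counts = cohort.enzyme_mrna.to_numpy(dtype=float)
    labels = np.full(counts.shape, None, dtype=object)

    for i in range(counts.shape[0]):
        row = counts[i]
        nz = row > 0
        n = int(nz.sum())
        if n == 0:
            continue
        ranks = rankdata(row[nz], method="min")
        q = np.ceil(4.0 * ranks / n).astype(int)
        labels[i, nz] = [QUARTILE_LABELS[v - 1] for v in q]

    per_patient = pd.DataFrame(
        labels, index=cohort.enzyme_mrna.index, columns=cohort.enzyme_mrna.columns
    )

    summary = {}
    for enz in cohort.enzymes:
        col = per_patient[enz]
        detected = col[col.notna()]
        if detected.empty:
            summary[enz] = pd.NA
            continue
        tally = detected.value_counts()
        best = max(
            QUARTILE_LABELS,
            key=lambda lab: (tally.get(lab, 0), -QUARTILE_LABELS.index(lab)),
        )
        summary[enz] = best
    return per_patient, pd.Series(summary, name="quartile_class")


def enzyme_prevalence(cohort: CohortDetection) -> pd.DataFrame:
    """Per-enzyme cohort prevalence: mRNA %, protein %, carrier bacteria,
    and the summary abundance quartile."""
    cohort.validate()
    n_pat = len(cohort.patients)
    if n_pat == 0:
        raise ValidationError("cohort has no patients")
    _, summary_q = assign_quartiles(cohort)

    pct_mrna = (cohort.enzyme_mrna > 0).mean(axis=0) * 100.0
    pct_protein = cohort.enzyme_protein.astype(bool).mean(axis=0) * 100.0

    rows = []
    for enz in cohort.enzymes:
        rows.append(
            {
                "enzyme": enz,
                "pct_mrna": float(pct_mrna[enz]),
                "pct_protein": float(pct_protein[enz]),
                "n_bacteria": len(cohort.enzyme_to_organisms.get(enz, set())),
                "quartile_class": summary_q[enz] if pct_mrna[enz] > 0 else pd.NA,
            }
        )
    df = pd.DataFrame(
        rows, columns=["enzyme", "pct_mrna", "pct_protein", "n_bacteria", "quartile_class"]
    )
    return df.sort_values(
        ["pct_mrna", "enzyme"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def toxin_union_prevalence(
    cohort: CohortDetection,
    toxin_to_enzymes: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-toxin union prevalence: % of patients with any synthesizing
    enzyme's mRNA detected, plus the count of its enzymes ever detected."""
    cohort.validate()
    detected = cohort.enzyme_mrna > 0
    n_pat = len(cohort.patients)

    rows = []
    for toxin, enzymes in toxin_to_enzymes.items():
        enzymes = [e for e in enzymes]
        unknown = [e for e in enzymes if e not in detected.columns]
        if unknown:
            raise ValidationError(
                f"toxin {toxin}: enzymes absent from cohort: {unknown}"
            )
        if not enzymes:
            warnings.warn(f"toxin {toxin} has an empty enzyme set", stacklevel=2)
            rows.append(
                {"toxin_id": toxin, "n_enzymes_detected": 0, "pct_any_enzyme": 0.0}
            )
            continue
        sub = detected[enzymes]
        rows.append(
            {
                "toxin_id": toxin,
                "n_enzymes_detected": int((sub.any(axis=0)).sum()),
                "pct_any_enzyme": float(sub.any(axis=1).sum()) / n_pat * 100.0,
            }
        )
    df = pd.DataFrame(rows, columns=["toxin_id", "n_enzymes_detected", "pct_any_enzyme"])
    return df.sort_values(
        ["pct_any_enzyme", "toxin_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def organism_repertoire_summary(
    cohort: CohortDetection,
    toxin_to_enzymes: Mapping[str, Iterable[str]],
    known_organisms: set[str] | None = None,
) -> pd.DataFrame:
    """Per-organism cohort summary: occurrence, toxins and enzymes covered.

    For each organism in the cohort: the percentage of patients where it is
    present; the number of distinct toxins for which at least one of the
    organism's enzymes was detected in at least one patient; the number of
    the organism's distinct enzymes ever detected; and the toxin list.
    Sorted by occurrence, descending.
    """
    cohort.validate()
    if known_organisms is not None:
        unknown = set(cohort.organism_presence.columns) - known_organisms
        if unknown:
            raise ValidationError(
                f"cohort organisms absent from universe: {sorted(unknown)}"
            )

    org_enzymes: dict[str, set[str]] = {
        org: set() for org in cohort.organism_presence.columns
    }
    for enz, orgs in cohort.enzyme_to_organisms.items():
        for org in orgs:
            if org in org_enzymes:
                org_enzymes[org].add(enz)

    ever_detected = set(
        cohort.enzyme_mrna.columns[(cohort.enzyme_mrna > 0).any(axis=0)]
    )
    pct_present = cohort.organism_presence.astype(bool).mean(axis=0) * 100.0

    rows = []
    for org in cohort.organism_presence.columns:
        detected_enzymes = org_enzymes[org] & ever_detected
        toxins = sorted(
            t
            for t, enzymes in toxin_to_enzymes.items()
            if detected_enzymes & set(enzymes)
        )
        rows.append(
            {
                "organism_id": org,
                "pct_patients": float(pct_present[org]),
                "n_toxins": len(toxins),
                "n_enzymes": len(detected_enzymes),
                "toxins": "|".join(toxins),
            }
        )
    df = pd.DataFrame(
        rows, columns=["organism_id", "pct_patients", "n_toxins", "n_enzymes", "toxins"]
    )
    return df.sort_values(
        ["pct_patients", "organism_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
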