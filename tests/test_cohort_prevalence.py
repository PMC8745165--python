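"""Cohort prevalence, quartile assignment, and organism summaries."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from toxsource.cohort_prevalence import (
    CohortDetection,
    assign_quartiles,
    enzyme_prevalence,
    load_cohort,
    organism_repertoire_summary,
    toxin_union_prevalence,
    write_cohort,
)
from toxsource.errors import ValidationError
from toxsource.synthetic_data import generate_cohort, generate_universe

from conftest import small_params
from oracles import brute_enzyme_pct, brute_quartiles, brute_union_pct


def make_cohort(mrna, protein=None, presence=None, e2o=None) -> CohortDetection:
    mrna = pd.DataFrame(mrna).rename(
        index=lambda i: f"P{i}", columns=lambda j: f"E{j}"
    )
    if protein is None:
        protein = mrna > 0
    else:
        protein = pd.DataFrame(protein).rename(
            index=lambda i: f"P{i}", columns=lambda j: f"E{j}"
        ).astype(bool)
    if presence is None:
        presence = pd.DataFrame(
            True, index=mrna.index, columns=["O1"]
        )
    return CohortDetection(
        enzyme_mrna=mrna.astype(int),
        enzyme_protein=protein,
        organism_presence=presence,
        enzyme_to_organisms=e2o or {},
    )


@pytest.fixture(scope="module")
def generated_cohort():
    universe, _ = generate_universe(small_params(17))
    return generate_cohort(universe, small_params(17))


class TestQuartiles:
    def test_four_distinct_counts_map_to_q1_through_q4(self):
        cohort = make_cohort([[1, 2, 3, 4]])
        per_patient, _ = assign_quartiles(cohort)
        assert list(per_patient.iloc[0]) == ["Q1", "Q2", "Q3", "Q4"]

    def test_undetected_enzyme_is_na(self):
        cohort = make_cohort([[0, 5]])
        per_patient, summary = assign_quartiles(cohort)
        assert pd.isna(per_patient.iloc[0, 0])
        assert pd.isna(summary["E0"])

    def test_balance_within_one_for_distinct_counts(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            counts = rng.choice(np.arange(1, 500), size=n, replace=False)
            cohort = make_cohort([list(counts)])
            per_patient, _ = assign_quartiles(cohort)
            occ = per_patient.iloc[0].value_counts()
            filled = [occ.get(q, 0) for q in ("Q1", "Q2", "Q3", "Q4")]
            assert max(filled) - min(filled) <= 1

    def test_matches_rank_cut_oracle(self, generated_cohort):
        per_patient, _ = assign_quartiles(generated_cohort)
        for pid in list(generated_cohort.enzyme_mrna.index)[:10]:
            counts = list(generated_cohort.enzyme_mrna.loc[pid])
            expected = brute_quartiles(counts)
            got = [
                None if pd.isna(v) else v for v in per_patient.loc[pid]
            ]
            assert got == expected

    def test_modal_summary_ties_resolve_low(self):
        # two detected mRNAs split into Q2/Q4; E0 is once each → tie → Q2
        cohort = make_cohort([[1, 2], [2, 1]])
        per_patient, summary = assign_quartiles(cohort)
        assert list(per_patient.iloc[0]) == ["Q2", "Q4"]
        assert summary["E0"] == "Q2"


class TestEnzymePrevalence:
    def test_undetected_enzyme_zero_pct_na_quartile(self):
        cohort = make_cohort([[0, 3], [0, 1]])
        rows = enzyme_prevalence(cohort).set_index("enzyme")
        assert rows.loc["E0", "pct_mrna"] == 0.0
        assert pd.isna(rows.loc["E0", "quartile_class"])

    def test_percentages_match_column_scan_oracle(self, generated_cohort):
        rows = enzyme_prevalence(generated_cohort).set_index("enzyme")
        expected = brute_enzyme_pct(generated_cohort)
        for enz, (pm, pp) in expected.items():
            assert rows.loc[enz, "pct_mrna"] == pytest.approx(pm)
            assert rows.loc[enz, "pct_protein"] == pytest.approx(pp)

    def test_invariant_to_patient_and_enzyme_ordering(self, generated_cohort):
        c = generated_cohort
        rows = enzyme_prevalence(c).set_index("enzyme")
        shuffled = CohortDetection(
            enzyme_mrna=c.enzyme_mrna.iloc[::-1, ::-1],
            enzyme_protein=c.enzyme_protein.iloc[::-1, ::-1],
            organism_presence=c.organism_presence.iloc[::-1],
            enzyme_to_organisms=c.enzyme_to_organisms,
        )
        rows2 = enzyme_prevalence(shuffled).set_index("enzyme")
        pd.testing.assert_frame_equal(rows.sort_index(), rows2.sort_index())


class TestUnionPrevalence:
    def test_single_enzyme_two_of_four_patients(self):
        cohort = make_cohort([[1], [0], [2], [0]])
        row = toxin_union_prevalence(cohort, {"T1": ["E0"]}).iloc[0]
        assert row.pct_any_enzyme == pytest.approx(50.0)

    def test_disjoint_halves_union_to_hundred(self):
        mrna = [[1, 0]] * 5 + [[0, 1]] * 5
        cohort = make_cohort(mrna)
        row = toxin_union_prevalence(cohort, {"T1": ["E0", "E1"]}).iloc[0]
        assert row.pct_any_enzyme == pytest.approx(100.0)
        assert row.n_enzymes_detected == 2

    def test_empty_enzyme_set_warns_with_zero(self):
        cohort = make_cohort([[1]])
        with pytest.warns(UserWarning, match="empty enzyme set"):
            row = toxin_union_prevalence(cohort, {"T1": []}).iloc[0]
        assert row.pct_any_enzyme == 0.0

    def test_union_dominance_and_any_scan_oracle(self, generated_cohort):
        enzymes = list(generated_cohort.enzymes)
        rng = np.random.default_rng(0)
        mapping = {
            f"T{k}": list(rng.choice(enzymes, size=3, replace=False))
            for k in range(8)
        }
        rows = toxin_union_prevalence(generated_cohort, mapping).set_index("toxin_id")
        expected = brute_union_pct(generated_cohort, mapping)
        marginals = (generated_cohort.enzyme_mrna > 0).mean(axis=0) * 100
        for tox, enz in mapping.items():
            pct = rows.loc[tox, "pct_any_enzyme"]
            assert pct == pytest.approx(expected[tox])
            assert pct >= max(marginals[e] for e in enz) - 1e-9
            assert pct <= min(100.0, sum(marginals[e] for e in enz)) + 1e-9


class TestOrganismSummary:
    def test_absent_organism_all_zero(self):
        cohort = make_cohort(
            [[1]], presence=pd.DataFrame({"O1": [False]}, index=["P0"]),
            e2o={"E0": {"O1"}},
        )
        row = organism_repertoire_summary(cohort, {"T1": ["E0"]}).iloc[0]
        assert row.pct_patients == 0.0
        # the enzyme is detected cohort-wide, so repertoire counts remain
        assert row.n_enzymes == 1

    def test_unknown_cohort_organism_fatal(self):
        cohort = make_cohort([[1]], e2o={"E0": {"O1"}})
        with pytest.raises(ValidationError, match="O1"):
            organism_repertoire_summary(cohort, {}, known_organisms={"OX"})

    def test_join_counts_match_brute_force(self, generated_cohort):
        c = generated_cohort
        mapping = {
            f"T{k}": [e] for k, e in enumerate(list(c.enzymes)[:10])
        }
        rows = organism_repertoire_summary(c, mapping).set_index("organism_id")
        ever = {e for e in c.enzymes if (c.enzyme_mrna[e] > 0).any()}
        for org in c.organism_presence.columns:
            org_enz = {e for e, orgs in c.enzyme_to_organisms.items() if org in orgs}
            detected = org_enz & ever
            toxins = {t for t, es in mapping.items() if set(es) & detected}
            pct = 100.0 * c.organism_presence[org].sum() / len(c.patients)
            assert rows.loc[org, "pct_patients"] == pytest.approx(pct)
            assert rows.loc[org, "n_enzymes"] == len(detected)
            assert rows.loc[org, "n_toxins"] == len(toxins)


def test_cohort_round_trip(tmp_path, generated_cohort):
    write_cohort(generated_cohort, tmp_path)
    reread = load_cohort(tmp_path)
    pd.testing.assert_frame_equal(
        reread.enzyme_mrna, generated_cohort.enzyme_mrna.sort_index(axis=1)
    )
    pd.testing.assert_frame_equal(
        reread.organism_presence.astype(bool),
        generated_cohort.organism_presence.sort_index(axis=1).astype(bool),
    )
    assert reread.enzyme_to_organisms == generated_cohort.enzyme_to_organisms
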