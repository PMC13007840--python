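import numpy as np
import pytest

from seegwm.cohort import (
    SCOPE_WM_ONLY,
    cohort_means_from_totals,
    shares_from_counts,
    summarize_cohort,
    summarize_patient,
    tract_share_table,
)
from seegwm.crossing import CrossingRecord
from seegwm.electrodes import Contact, PlacedElectrode
from seegwm.tissue import CSF, GM, WM, TissueClassification


def electrode(pid, name, xs, z=0.0):
    contacts = tuple(
        Contact(f"{name}{i}", i, (float(x), 0.0, z)) for i, x in enumerate(xs, start=1)
    )
    return PlacedElectrode(pid, name, "spencer6", contacts)


@pytest.fixture()
def patient_inputs():
    """One patient, two electrodes (one per hemisphere), mixed tissue and tracts."""
    e_left = electrode("P1", "L", [-30, -25, -20])
    e_right = electrode("P1", "R", [30, 25, 20])
    cls = [
        TissueClassification("L1", WM),
        TissueClassification("L2", WM),
        TissueClassification("L3", GM),
        TissueClassification("R1", WM),
        TissueClassification("R2", GM),
        TissueClassification("R3", CSF),
    ]
    records = [
        CrossingRecord("L1", "cc", 0.9, True),
        CrossingRecord("L2", "cc", 0.8, True),
        CrossingRecord("L2", "ifof", 0.7, True),
        CrossingRecord("R1", "cc", 0.6, True),
        CrossingRecord("R1", "ifof", 0.4, False),
    ]
    return [e_left, e_right], cls, records


class TestSummarizePatient:
    def test_counts_and_distinct_tracts(self, patient_inputs):
        electrodes, cls, records = patient_inputs
        s = summarize_patient(electrodes, cls, records)
        assert s.patient_id == "P1"
        assert s.implant_side == "bilateral"
        assert s.n_electrodes == 2 and s.n_contacts == 6
        assert s.tissue_counts[WM] == 3 and s.tissue_counts[CSF] == 1
        assert s.tract_contacts["cc"]["overall"] == 3
        assert s.tract_contacts["cc"]["left"] == 2
        assert s.tract_contacts["cc"]["right"] == 1
        assert s.tract_contacts["ifof"]["overall"] == 1
        assert s.n_distinct_tracts == 2

    def test_hemisphere_counts_split_the_overall_count(self, patient_inputs):
        electrodes, cls, records = patient_inputs
        s = summarize_patient(electrodes, cls, records)
        for t, row in s.tract_contacts.items():
            assert row["left"] + row["right"] + row["midline"] == row["overall"]

    def test_single_side_implant(self):
        s = summarize_patient(
            [electrode("P1", "L", [-30, -25])],
            [TissueClassification("L1", WM), TissueClassification("L2", WM)],
            [],
        )
        assert s.implant_side == "left"
        assert s.n_distinct_tracts == 0

    def test_scope_restriction_drops_out_of_scope_records(self, patient_inputs):
        electrodes, cls, records = patient_inputs
        wm_only = [c for c in cls if c.tissue_class == WM]
        s = summarize_patient(electrodes, wm_only, records)
        # L3 is GM, so the ifof crossing on L2 stays but GM contacts vanish
        assert s.hemisphere_contacts["left"] == 2
        assert s.hemisphere_contacts["right"] == 1
        assert s.tract_contacts["cc"]["overall"] == 3

    def test_mixed_patients_rejected(self):
        with pytest.raises(ValueError, match="mixed patient_ids"):
            summarize_patient(
                [electrode("P1", "A", [-10]), electrode("P2", "B", [10])], [], []
            )

    def test_unknown_classified_contact_rejected(self, patient_inputs):
        electrodes, _, _ = patient_inputs
        with pytest.raises(ValueError, match="not on any electrode"):
            summarize_patient(electrodes, [TissueClassification("ZZ9", WM)], [])


def make_cohort():
    """Three patients: left-only, right-only, bilateral, with known tract counts."""
    patients = []
    specs = [
        ("P1", [("L", [-30, -25, -20])], {"cc": ["L1", "L2"], "ifof": ["L1"]}),
        ("P2", [("R", [30, 25, 20])], {"cc": ["R1"]}),
        ("P3", [("L", [-15, -10]), ("R", [15, 10])], {"ifof": ["R1", "R2"]}),
    ]
    for pid, els, crossed in specs:
        electrodes = [electrode(pid, n, xs) for n, xs in els]
        cls = [
            TissueClassification(c.contact_id, WM)
            for e in electrodes
            for c in e.contacts
        ]
        records = [
            CrossingRecord(cid, tract, 0.8, True)
            for tract, ids in crossed.items()
            for cid in ids
        ]
        patients.append(summarize_patient(electrodes, cls, records))
    return patients


class TestSummarizeCohort:
    def test_global_means(self):
        cohort = summarize_cohort(make_cohort())
        assert cohort.n_patients == 3
        assert cohort.mean_electrodes_per_patient == pytest.approx(4 / 3)
        assert cohort.mean_contacts_per_patient == pytest.approx(10 / 3)
        assert cohort.mean_contacts_per_electrode == pytest.approx(10 / 4)
        assert cohort.sd_electrodes_per_patient == pytest.approx(np.std([1, 1, 2], ddof=1))

    def test_tract_probabilities_and_strata(self):
        cohort = summarize_cohort(make_cohort())
        table = cohort.tract_table.set_index("tract")
        # cc: involved in P1 and P2 of 3 patients
        assert table.loc["cc", "overall_pct"] == pytest.approx(66.67)
        # left stratum: P1 and P3 have left contacts; only P1 crosses cc on the left
        assert table.loc["cc", "left_pct"] == pytest.approx(50.0)
        # right stratum: P2 and P3; only P2 crosses cc on the right
        assert table.loc["cc", "right_pct"] == pytest.approx(50.0)
        # ifof on the right: only P3 of {P2, P3}
        assert table.loc["ifof", "right_pct"] == pytest.approx(50.0)
        # mean contacts over involved patients: cc -> (2 + 1) / 2
        assert table.loc["cc", "mean"] == pytest.approx(1.5)

    def test_commissural_tracts_have_no_hemispheric_split(self):
        cohort = summarize_cohort(make_cohort(), commissural_tracts={"cc"})
        table = cohort.tract_table.set_index("tract")
        assert np.isnan(table.loc["cc", "left_pct"])
        assert not np.isnan(table.loc["ifof", "left_pct"])

    def test_probability_monotone_in_added_contacts(self):
        base = make_cohort()
        cohort = summarize_cohort(base)
        # give P2 an ifof contact as well: its probability may only rise
        electrodes = [electrode("P2", "R", [30, 25, 20])]
        cls = [TissueClassification(c.contact_id, WM)
               for e in electrodes for c in e.contacts]
        richer = summarize_patient(
            electrodes, cls,
            [CrossingRecord("R1", "cc", 0.8, True), CrossingRecord("R2", "ifof", 0.8, True)],
        )
        cohort2 = summarize_cohort([base[0], richer, base[2]])
        t1 = cohort.tract_table.set_index("tract")
        t2 = cohort2.tract_table.set_index("tract")
        for tract in ("cc", "ifof"):
            assert t2.loc[tract, "overall_pct"] >= t1.loc[tract, "overall_pct"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            summarize_cohort([])

    def test_published_style_totals(self):
        means = cohort_means_from_totals(n_patients=86, n_electrodes=860, n_contacts=6372)
        assert means["mean_electrodes_per_patient"] == 10.0
        assert means["mean_contacts_per_electrode"] == 7.41
        assert means["mean_contacts_per_patient"] == 74.09


class TestTractShareTable:
    def records(self):
        return [
            CrossingRecord("a", "cc", 0.9, True),
            CrossingRecord("a", "ifof", 0.6, True),
            CrossingRecord("b", "cc", 0.8, True),
            CrossingRecord("c", "cc", 0.2, False),
            CrossingRecord("d", "ifof", 0.7, True),
        ]

    def hemis(self):
        return {"a": "left", "b": "right", "c": "left", "d": "right"}

    def test_all_crossing_scope(self):
        table = tract_share_table(self.records(), self.hemis()).set_index("tract")
        # denominator: contacts a, b, d cross something
        assert table.loc["cc", "n"] == 2
        assert table.loc["cc", "pct"] == pytest.approx(66.67)
        assert table.loc["ifof", "n_left"] == 1
        assert table.loc["ifof", "n_right"] == 1

    def test_wm_only_scope(self):
        cls = [
            TissueClassification("a", WM),
            TissueClassification("b", GM),
            TissueClassification("c", WM),
            TissueClassification("d", WM),
        ]
        table = tract_share_table(
            self.records(), self.hemis(), scope=SCOPE_WM_ONLY, classifications=cls
        ).set_index("tract")
        # denominator = 3 WM contacts; b's cc crossing falls outside the scope
        assert table.loc["cc", "n"] == 1
        assert table.loc["cc", "pct"] == pytest.approx(33.33)

    def test_wm_scope_requires_classifications(self):
        with pytest.raises(ValueError, match="requires classifications"):
            tract_share_table(self.records(), self.hemis(), scope=SCOPE_WM_ONLY)

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="unknown denominator scope"):
            tract_share_table(self.records(), self.hemis(), scope="bogus")

    def test_published_style_share_arithmetic(self):
        table = shares_from_counts(
            {"corpus_callosum": 3254, "ifof": 756, "slf3_right": 477, "slf3_left": 264},
            denominator=4381,
        ).set_index("tract")
        assert table.loc["corpus_callosum", "pct"] == 74.28
        assert table.loc["ifof", "pct"] == 17.26
        assert table.loc["slf3_right", "pct"] == 10.89
        assert table.loc["slf3_left", "pct"] == 6.03
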