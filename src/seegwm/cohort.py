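"""Per-patient and cohort aggregation of tissue and tract-crossing results.

The reporting conventions mirror the printed arithmetic of the source tables:

* tissue-class shares are taken over intraparenchymal contacts, the
  intraparenchymal share over all contacts;
* per-tract contact shares are taken over a scoped denominator - either all
  contacts crossing at least one tract, or white-matter-class contacts only;
* the cohort-level probability of a tract being sampled is the percentage of
  patients with at least one contact crossing it; hemispheric probabilities
  are computed only over patients who actually have in-scope contacts in that
  hemisphere;
* per-tract mean +/- SD contacts per patient are computed over the patients
  involved in the tract (sample SD, n-1);
* commissural tracts span both hemispheres and are reported once, without a
  hemispheric split.

Percentages are rounded half-up at 2 decimals (integer precision for
prose-style shares).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from seegwm._rounding import percentage, round_half_up
from seegwm.crossing import CrossingRecord
from seegwm.electrodes import LEFT, MIDLINE, RIGHT, PlacedElectrode
from seegwm.tissue import TISSUE_CLASSES, WM, TissueClassification

HEMIS = (LEFT, RIGHT, MIDLINE)


@dataclass(frozen=True)
class PatientSummary:
    """One patient's implantation, tissue and tract-sampling counts.

    ``tract_contacts`` maps tract name to per-hemisphere contact counts (keys
    ``overall``/``left``/``right``/``midline``); ``hemisphere_contacts``
    counts the in-scope contacts per hemisphere and defines which hemispheric
    strata the patient belongs to.
    """

    patient_id: str
    implant_side: str  # left | right | bilateral
    n_electrodes: int
    n_contacts: int
    electrode_contact_counts: tuple[int, ...]
    tissue_counts: Mapping[str, int]
    tract_contacts: Mapping[str, Mapping[str, int]]
    hemisphere_contacts: Mapping[str, int]

    @property
    def n_distinct_tracts(self) -> int:
        return sum(1 for v in self.tract_contacts.values() if v["overall"] >= 1)


def _implant_side(electrodes: Sequence[PlacedElectrode]) -> str:
    sides = {e.hemisphere for e in electrodes} - {MIDLINE}
    if sides == {LEFT}:
        return LEFT
    if sides == {RIGHT}:
        return RIGHT
    if sides == {LEFT, RIGHT}:
        return "bilateral"
    return MIDLINE


def summarize_patient(
    electrodes: Sequence[PlacedElectrode],
    classifications: Sequence[TissueClassification],
    records: Sequence[CrossingRecord],
) -> PatientSummary:
    """Aggregate one patient's classifications and crossing records.

    ``classifications`` defines the in-scope contact set (pass the full list
    for an all-contacts summary, or only WM-class contacts for a
    white-matter-focused one); ``records`` are restricted to that set.  All
    electrodes must belong to a single patient.
    """
    if not electrodes:
        raise ValueError("no electrodes supplied")
    patient_ids = {e.patient_id for e in electrodes}
    if len(patient_ids) != 1:
        raise ValueError(f"mixed patient_ids in one summary: {sorted(patient_ids)}")
    (patient_id,) = patient_ids

    hemi_by_contact = {
        c.contact_id: c.hemisphere for e in electrodes for c in e.contacts
    }
    scope = {cl.contact_id for cl in classifications}
    unknown = scope - set(hemi_by_contact)
    if unknown:
        raise ValueError(f"classified contacts not on any electrode: {sorted(unknown)[:5]}")

    tissue_counts = {cls: 0 for cls in TISSUE_CLASSES}
    for cl in classifications:
        tissue_counts[cl.tissue_class] += 1

    hemisphere_contacts = {h: 0 for h in HEMIS}
    for cid in scope:
        hemisphere_contacts[hemi_by_contact[cid]] += 1

    tract_contacts: dict[str, dict[str, int]] = {}
    for r in records:
        if r.contact_id not in scope:
            continue
        row = tract_contacts.setdefault(
            r.tract_name, {"overall": 0, LEFT: 0, RIGHT: 0, MIDLINE: 0}
        )
        if r.crossed:
            row["overall"] += 1
            row[hemi_by_contact[r.contact_id]] += 1

    return PatientSummary(
        patient_id=patient_id,
        implant_side=_implant_side(electrodes),
        n_electrodes=len(electrodes),
        n_contacts=sum(e.n_contacts for e in electrodes),
        electrode_contact_counts=tuple(e.n_contacts for e in electrodes),
        tissue_counts=tissue_counts,
        tract_contacts=tract_contacts,
        hemisphere_contacts=hemisphere_contacts,
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level sampling statistics over patient summaries."""

    n_patients: int
    mean_electrodes_per_patient: float
    sd_electrodes_per_patient: float
    mean_contacts_per_patient: float
    sd_contacts_per_patient: float
    mean_contacts_per_electrode: float
    sd_contacts_per_electrode: float
    mean_distinct_tracts_per_patient: float
    tract_table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.tract_table.copy()


def summarize_cohort(
    patients: Sequence[PatientSummary],
    commissural_tracts: Iterable[str] = (),
    ndigits: int = 2,
) -> CohortSummary:
    """Aggregate patient summaries into cohort sampling statistics.

    The per-tract table carries: mean +/- SD contacts per involved patient
    (overall and per hemisphere), and the percentage of patients with at least
    one contact in the tract - overall over the whole cohort, per hemisphere
    over the patients with in-scope contacts in that hemisphere.  Commissural
    tracts get no hemispheric split.
    """
    if not patients:
        raise ValueError("empty cohort")
    commissural = set(commissural_tracts)
    n = len(patients)

    mean_el, sd_el = _mean_sd([p.n_electrodes for p in patients])
    mean_ct, sd_ct = _mean_sd([p.n_contacts for p in patients])
    per_electrode = [c for p in patients for c in p.electrode_contact_counts]
    mean_cpe, sd_cpe = _mean_sd(per_electrode)
    mean_tracts, _ = _mean_sd([p.n_distinct_tracts for p in patients])

    hemi_denoms = {
        h: [p for p in patients if p.hemisphere_contacts.get(h, 0) >= 1]
        for h in (LEFT, RIGHT)
    }

    tracts = sorted({t for p in patients for t in p.tract_contacts})
    rows = []
    for t in tracts:
        counts = [p.tract_contacts.get(t, {}).get("overall", 0) for p in patients]
        involved = [c for c in counts if c >= 1]
        mean_t, sd_t = _mean_sd(involved)
        row = {
            "tract": t,
            "commissural": t in commissural,
            "mean": round_half_up(mean_t, ndigits) if involved else float("nan"),
            "sd": round_half_up(sd_t, ndigits) if len(involved) > 1 else float("nan"),
            "overall_pct": percentage(len(involved), n, ndigits),
        }
        for h in (LEFT, RIGHT):
            mk, sk, pk = f"{h}_mean", f"{h}_sd", f"{h}_pct"
            if t in commissural:
                row[mk] = row[sk] = row[pk] = float("nan")
                continue
            denom = hemi_denoms[h]
            h_counts = [p.tract_contacts.get(t, {}).get(h, 0) for p in denom]
            h_involved = [c for c in h_counts if c >= 1]
            row[mk] = round_half_up(_mean_sd(h_involved)[0], ndigits) if h_involved else float("nan")
            row[sk] = round_half_up(_mean_sd(h_involved)[1], ndigits) if len(h_involved) > 1 else float("nan")
            row[pk] = percentage(len(h_involved), len(denom), ndigits) if denom else float("nan")
        rows.append(row)

    table = pd.DataFrame(
        rows,
        columns=[
            "tract", "commissural", "mean", "sd", "overall_pct",
            "left_mean", "left_sd", "left_pct",
            "right_mean", "right_sd", "right_pct",
        ],
    )
    return CohortSummary(
        n_patients=n,
        mean_electrodes_per_patient=mean_el,
        sd_electrodes_per_patient=sd_el,
        mean_contacts_per_patient=mean_ct,
        sd_contacts_per_patient=sd_ct,
        mean_contacts_per_electrode=mean_cpe,
        sd_contacts_per_electrode=sd_cpe,
        mean_distinct_tracts_per_patient=mean_tracts,
        tract_table=table,
    )


def cohort_means_from_totals(
    n_patients: int, n_electrodes: int, n_contacts: int, ndigits: int = 2
) -> dict[str, float]:
    """Cohort mean arithmetic from grand totals (e.g. published counts)."""
    if n_patients < 1 or n_electrodes < 1:
        raise ValueError("need at least one patient and one electrode")
    return {
        "mean_electrodes_per_patient": round_half_up(n_electrodes / n_patients, ndigits),
        "mean_contacts_per_patient": round_half_up(n_contacts / n_patients, ndigits),
        "mean_contacts_per_electrode": round_half_up(n_contacts / n_electrodes, ndigits),
    }


# ---------------------------------------------------------------------------
# per-tract contact share tables
# ---------------------------------------------------------------------------

SCOPE_ALL_CROSSING = "all_crossing_contacts"
SCOPE_WM_ONLY = "wm_only_contacts"


def tract_share_table(
    records: Sequence[CrossingRecord],
    hemispheres: Mapping[str, str],
    scope: str = SCOPE_ALL_CROSSING,
    classifications: Sequence[TissueClassification] | None = None,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Per-tract contact counts and shares over a scoped denominator.

    ``scope`` selects the denominator: contacts crossing >= 1 tract
    (``all_crossing_contacts``) or white-matter-class contacts
    (``wm_only_contacts``, requires ``classifications``).  ``hemispheres``
    maps contact ids to hemispheres for the left/right split.
    """
    if scope == SCOPE_ALL_CROSSING:
        denominator = {r.contact_id for r in records if r.crossed}
    elif scope == SCOPE_WM_ONLY:
        if classifications is None:
            raise ValueError("wm_only_contacts scope requires classifications")
        denominator = {c.contact_id for c in classifications if c.tissue_class == WM}
    else:
        raise ValueError(f"unknown denominator scope {scope!r}")

    tracts = sorted({r.tract_name for r in records})
    rows = []
    denom_n = len(denominator)
    for t in tracts:
        ids = {r.contact_id for r in records
               if r.crossed and r.tract_name == t and r.contact_id in denominator}
        n_left = sum(1 for c in ids if hemispheres.get(c) == LEFT)
        n_right = sum(1 for c in ids if hemispheres.get(c) == RIGHT)
        rows.append(
            {
                "tract": t,
                "n": len(ids),
                "pct": percentage(len(ids), denom_n, ndigits) if denom_n else float("nan"),
                "n_left": n_left,
                "pct_left": percentage(n_left, denom_n, ndigits) if denom_n else float("nan"),
                "n_right": n_right,
                "pct_right": percentage(n_right, denom_n, ndigits) if denom_n else float("nan"),
            }
        )
    return pd.DataFrame(
        rows, columns=["tract", "n", "pct", "n_left", "pct_left", "n_right", "pct_right"]
    )


def shares_from_counts(
    counts: Mapping[str, int], denominator: int, ndigits: int = 2
) -> pd.DataFrame:
    """Share table directly from per-tract counts and a denominator."""
    if denominator < 1:
        raise ValueError("denominator must be positive")
    rows = [
        {"tract": t, "n": n, "pct": percentage(n, denominator, ndigits)}
        for t, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["tract", "n", "pct"])
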