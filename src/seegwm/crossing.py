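"""Probabilistic tract-atlas scoring, crossing decisions and stimulation planning.

Each probabilistic tract atlas stores, per voxel, the fraction of a reference
cohort whose tract occupies that voxel.  A contact's probability of crossing a
tract is the maximum atlas value over its 2x2x1 window - the disconnectome
convention of reporting the highest tract probability a mask touches (a mean
aggregation is available as an option).  A tract counts as crossed when that
probability reaches chance level: probability >= 0.5 under the default
inclusive rule (a strict > comparison is available).

Stimulation planning selects, for a target tract, the contacts overlapping the
tract (probability at or above threshold) plus their same-electrode index
neighbours, and reports each contact's Euclidean distance in mm to the nearest
supra-threshold voxel center.  Planning is an output artifact only - no
current-spread modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from seegwm._rounding import percentage
from seegwm.electrodes import Contact
from seegwm.volumes import ContactMask, Volume, mask_values, require_same_grid

COMMISSURAL = "commissural"
TRACT_HEMISPHERES = ("left", "right", COMMISSURAL)


@dataclass(frozen=True)
class TractAtlas:
    """One probabilistic tract volume with hemisphere metadata.

    Voxel values must already be fractions in [0, 1]; anything outside is a
    hard validation error (catching percent-vs-fraction unit mistakes).
    """

    tract_name: str
    hemisphere: str
    volume: Volume

    def __post_init__(self):
        if self.hemisphere not in TRACT_HEMISPHERES:
            raise ValueError(
                f"tract {self.tract_name!r}: hemisphere must be one of "
                f"{TRACT_HEMISPHERES}, got {self.hemisphere!r}"
            )
        data = self.volume.data
        lo, hi = float(np.min(data)), float(np.max(data))
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"tract {self.tract_name!r}: voxel values must be fractions in "
                f"[0, 1] (found range [{lo:g}, {hi:g}]); convert percent maps first"
            )

    @property
    def is_commissural(self) -> bool:
        return self.hemisphere == COMMISSURAL


@dataclass(frozen=True)
class CrossingRecord:
    contact_id: str
    tract_name: str
    probability: float
    crossed: bool

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("crossing probability must lie in [0, 1]")


def contact_tract_probability(
    atlas: TractAtlas, mask: ContactMask, aggregation: str = "max"
) -> float:
    """Tract probability of one contact window; an empty mask scores 0."""
    if aggregation not in ("max", "mean"):
        raise ValueError("aggregation must be 'max' or 'mean'")
    if mask.source is not None:
        require_same_grid(mask.source, atlas.volume)
    values = mask_values(atlas.volume, mask)
    if values.size == 0:
        return 0.0
    return float(np.max(values) if aggregation == "max" else np.mean(values))


def decide_crossings(
    atlases: Sequence[TractAtlas],
    masks: Sequence[ContactMask],
    threshold: float = 0.5,
    inclusive: bool = True,
    aggregation: str = "max",
) -> list[CrossingRecord]:
    """Score every (contact, tract) pair and apply the crossing threshold.

    All pairs are retained (sub-threshold ones with ``crossed=False``) so the
    output is filterable; ordering is deterministic by contact id then tract
    name.
    """
    if not atlases:
        raise ValueError("no tract atlases supplied")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    records = []
    for mask in masks:
        for atlas in sorted(atlases, key=lambda a: a.tract_name):
            p = contact_tract_probability(atlas, mask, aggregation)
            crossed = p >= threshold if inclusive else p > threshold
            records.append(
                CrossingRecord(
                    contact_id=mask.contact_id,
                    tract_name=atlas.tract_name,
                    probability=p,
                    crossed=crossed,
                )
            )
    records.sort(key=lambda r: (r.contact_id, r.tract_name))
    return records


@dataclass(frozen=True)
class OverlapCensus:
    """How many contacts carry >= 2 and >= 3 crossed tracts."""

    n_contacts: int
    n_ge2: int
    n_ge3: int
    commissural_excluded: bool

    @property
    def pct_ge2(self) -> int:
        return int(percentage(self.n_ge2, self.n_contacts, 0)) if self.n_contacts else 0

    @property
    def pct_ge3(self) -> int:
        return int(percentage(self.n_ge3, self.n_contacts, 0)) if self.n_contacts else 0


def overlap_census(
    records: Sequence[CrossingRecord],
    exclude_commissural: bool = False,
    commissural_tracts: Iterable[str] = (),
    contact_ids: Iterable[str] | None = None,
) -> OverlapCensus:
    """Count multi-tract overlap among a contact subset.

    The denominator is ``contact_ids`` when given, else every contact
    appearing in ``records`` (crossed or not).  With ``exclude_commissural``,
    records belonging to ``commissural_tracts`` are dropped before counting.
    """
    commissural = set(commissural_tracts)
    if contact_ids is None:
        denominator = {r.contact_id for r in records}
    else:
        denominator = set(contact_ids)
    per_contact: dict[str, int] = {}
    for r in records:
        if not r.crossed or r.contact_id not in denominator:
            continue
        if exclude_commissural and r.tract_name in commissural:
            continue
        per_contact[r.contact_id] = per_contact.get(r.contact_id, 0) + 1
    n_ge2 = sum(1 for n in per_contact.values() if n >= 2)
    n_ge3 = sum(1 for n in per_contact.values() if n >= 3)
    return OverlapCensus(
        n_contacts=len(denominator),
        n_ge2=n_ge2,
        n_ge3=n_ge3,
        commissural_excluded=exclude_commissural,
    )


@dataclass(frozen=True)
class StimulationPlan:
    """Stimulation candidates for one target tract.

    ``targets`` are contacts overlapping the tract; ``adjacent`` their
    same-electrode index neighbours that do not overlap.  ``distance_mm`` maps
    every supplied contact to its distance from the nearest supra-threshold
    voxel center (0 for contacts whose center coincides with one).
    """

    tract_name: str
    targets: tuple[str, ...]
    adjacent: tuple[str, ...]
    distance_mm: Mapping[str, float]
    status: str = "ok"

    def to_rows(self) -> list[dict]:
        rows = [
            {"tract": self.tract_name, "contact": c, "role": role,
             "distance_mm": self.distance_mm.get(c, float("nan"))}
            for role, ids in (("target", self.targets), ("adjacent", self.adjacent))
            for c in ids
        ]
        return rows


def plan_stimulation(
    tract: TractAtlas,
    electrodes: Mapping[str, Sequence[Contact]],
    masks: Mapping[str, ContactMask],
    threshold: float = 0.5,
    inclusive: bool = True,
    aggregation: str = "max",
) -> StimulationPlan:
    """Select overlapping and adjacent contacts for stimulating one tract."""
    if not electrodes:
        raise ValueError("at least one electrode is required")
    supra = np.argwhere(np.asarray(tract.volume.data) >= threshold)
    if supra.size == 0:
        return StimulationPlan(
            tract_name=tract.tract_name,
            targets=(),
            adjacent=(),
            distance_mm={},
            status="no_suprathreshold_voxels",
        )
    supra_mm = tract.volume.voxel_to_world(supra)

    targets: list[str] = []
    adjacent: list[str] = []
    distances: dict[str, float] = {}
    for ename in sorted(electrodes):
        contacts = sorted(electrodes[ename], key=lambda c: c.index)
        probs = {}
        for c in contacts:
            mask = masks[c.contact_id]
            p = contact_tract_probability(tract, mask, aggregation)
            probs[c.index] = p
            d = np.linalg.norm(supra_mm - np.asarray(c.center, dtype=float), axis=1)
            distances[c.contact_id] = float(np.min(d))
        hit = {
            i for i, p in probs.items()
            if (p >= threshold if inclusive else p > threshold)
        }
        for c in contacts:
            if c.index in hit:
                targets.append(c.contact_id)
            elif (c.index - 1) in hit or (c.index + 1) in hit:
                adjacent.append(c.contact_id)
    return StimulationPlan(
        tract_name=tract.tract_name,
        targets=tuple(targets),
        adjacent=tuple(adjacent),
        distance_mm=distances,
        status="ok",
    )
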