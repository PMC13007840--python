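"""Depth-electrode geometry: manufacturer models, trajectories, contact placement.

A depth electrode is described by its manufacturer geometry (number of
cylindrical contacts, contact length/diameter, and the ordered center-to-center
spacings between consecutive contacts) and an implantation trajectory: the
center of the deepest contact (the surgical target) plus the unit direction
pointing from the target back toward the entry point.  Contact centers follow
by accumulating the spacing list along the trajectory.

Two builtin models are provided: the 6-contact Spencer Probe (2.41 mm contacts,
1.12 mm diameter, dense distal block at 5 mm pitch, sparse proximal block at
10 mm) and the parametric "reduced diameter" electrode (6-10 equally spaced
2.29 mm contacts, 0.82 mm diameter, uniform pitch of 5-8 mm).

"Contact spacing" is interpreted throughout as center-to-center distance, the
usual depth-electrode datasheet convention.  Contact 1 is the deepest contact
(SEEG numbering); hemispheres are assigned from the sign of the x coordinate
(x < 0 left, x > 0 right, x == 0 midline) under an RAS+ analysis space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LEFT = "left"
RIGHT = "right"
MIDLINE = "midline"

_DIRECTION_TOL = 1e-6


def hemisphere_of(x: float) -> str:
    """Hemisphere from the analysis-space x coordinate (RAS+: +x is right)."""
    if x < 0:
        return LEFT
    if x > 0:
        return RIGHT
    return MIDLINE


@dataclass(frozen=True)
class ElectrodeModel:
    """Manufacturer geometry of a multi-contact depth electrode.

    ``gaps`` holds the n_contacts - 1 center-to-center distances (mm), ordered
    from the deepest pair outward.
    """

    model_id: str
    n_contacts: int
    contact_length: float
    contact_diameter: float
    gaps: tuple[float, ...]

    def __post_init__(self):
        if self.n_contacts < 2:
            raise ValueError("an electrode needs at least 2 contacts")
        if self.contact_length <= 0 or self.contact_diameter <= 0:
            raise ValueError("contact dimensions must be positive")
        if len(self.gaps) != self.n_contacts - 1:
            raise ValueError(
                f"model {self.model_id!r}: expected {self.n_contacts - 1} gaps, "
                f"got {len(self.gaps)}"
            )
        if any(g <= 0 for g in self.gaps):
            raise ValueError("all contact spacings must be positive")

    @property
    def span(self) -> float:
        """Distance (mm) from the deepest to the most superficial contact center."""
        return float(sum(self.gaps))


def spencer_probe(transition_gap: float = 10.0) -> ElectrodeModel:
    """The 6-contact Spencer Probe.

    Contacts 1-3 sit at 5 mm pitch, contacts 4-6 at 10 mm.  The spacing between
    contacts 3 and 4 is not part of the datasheet shorthand; it defaults to the
    sparser block's 10 mm, giving the conventional distal-dense layout.
    """
    if transition_gap <= 0:
        raise ValueError("transition gap must be positive")
    return ElectrodeModel(
        model_id="spencer6",
        n_contacts=6,
        contact_length=2.41,
        contact_diameter=1.12,
        gaps=(5.0, 5.0, float(transition_gap), 10.0, 10.0),
    )


def reduced_diameter(n_contacts: int = 8, gap: float = 5.0) -> ElectrodeModel:
    """The equally spaced reduced-diameter electrode (6-10 contacts, 5-8 mm pitch)."""
    if not 6 <= int(n_contacts) <= 10:
        raise ValueError(
            f"reduced-diameter electrodes carry 6-10 contacts, got {n_contacts}"
        )
    if not 5.0 <= float(gap) <= 8.0:
        raise ValueError(f"reduced-diameter pitch must lie in [5, 8] mm, got {gap}")
    return ElectrodeModel(
        model_id="reduced",
        n_contacts=int(n_contacts),
        contact_length=2.29,
        contact_diameter=0.82,
        gaps=(float(gap),) * (int(n_contacts) - 1),
    )


def builtin_models(reduced_n: int = 8, reduced_gap: float = 5.0) -> list[ElectrodeModel]:
    """The two builtin electrode models used across the cohort."""
    return [spencer_probe(), reduced_diameter(reduced_n, reduced_gap)]


def get_model(model_id: str, n_contacts: int | None = None, gap: float | None = None) -> ElectrodeModel:
    """Resolve a model id (``spencer6`` or ``reduced``) to a concrete geometry."""
    if model_id == "spencer6":
        return spencer_probe()
    if model_id == "reduced":
        return reduced_diameter(
            8 if n_contacts is None else n_contacts,
            5.0 if gap is None else gap,
        )
    raise ValueError(f"unknown electrode model {model_id!r}")


@dataclass(frozen=True)
class Trajectory:
    """Implanted-electrode trajectory in analysis-space mm.

    ``target_point`` is the center of the deepest contact; ``unit_direction``
    points from the target toward the entry point (unit norm to 1e-6).
    """

    patient_id: str
    electrode_name: str
    target_point: tuple[float, float, float]
    unit_direction: tuple[float, float, float]
    model: ElectrodeModel

    def __post_init__(self):
        d = np.asarray(self.unit_direction, dtype=float)
        if abs(float(np.linalg.norm(d)) - 1.0) > _DIRECTION_TOL:
            raise ValueError(
                f"trajectory {self.electrode_name!r}: direction must be unit "
                f"norm (|d| = {np.linalg.norm(d):.8f})"
            )


@dataclass(frozen=True)
class Contact:
    """One physical electrode contact with its analysis-space center."""

    contact_id: str
    index: int  # 1-based, 1 = deepest
    center: tuple[float, float, float]
    hemisphere: str = field(default="")

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("contact index is 1-based")
        if not self.hemisphere:
            object.__setattr__(self, "hemisphere", hemisphere_of(self.center[0]))


@dataclass(frozen=True)
class PlacedElectrode:
    """An electrode with its reconstructed (or directly supplied) contacts."""

    patient_id: str
    electrode_name: str
    model_id: str
    contacts: tuple[Contact, ...]

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def hemisphere(self) -> str:
        """Electrode laterality: hemisphere of the deepest contact."""
        return self.contacts[0].hemisphere


def place_contacts(traj: Trajectory) -> list[Contact]:
    """Reconstruct contact centers along a trajectory.

    Contact k (1-based) sits at ``target + direction * sum(gaps[:k-1])``; the
    first contact is exactly at the target point.
    """
    target = np.asarray(traj.target_point, dtype=float)
    direction = np.asarray(traj.unit_direction, dtype=float)
    offsets = np.concatenate([[0.0], np.cumsum(traj.model.gaps)])
    contacts = []
    for k, off in enumerate(offsets, start=1):
        center = target + direction * off
        contacts.append(
            Contact(
                contact_id=f"{traj.electrode_name}{k}",
                index=k,
                center=(float(center[0]), float(center[1]), float(center[2])),
            )
        )
    return contacts


def place_electrode(traj: Trajectory) -> PlacedElectrode:
    return PlacedElectrode(
        patient_id=traj.patient_id,
        electrode_name=traj.electrode_name,
        model_id=traj.model.model_id,
        contacts=tuple(place_contacts(traj)),
    )


# ---------------------------------------------------------------------------
# external interfaces: tab-separated electrode files
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = [
    "patient_id", "electrode_name", "model_id", "n_contacts", "gap_mm",
    "target_x", "target_y", "target_z", "dir_x", "dir_y", "dir_z",
]
CONTACT_COLUMNS = ["patient_id", "electrode_name", "index", "x", "y", "z"]


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read a tab-separated trajectory file (one row per electrode).

    Columns: patient_id, electrode_name, model_id, n_contacts, gap_mm,
    target_x/y/z, dir_x/y/z (mm, analysis space).  '#' starts a comment line.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str, "electrode_name": str})
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file {path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        model = get_model(str(row.model_id), int(row.n_contacts), float(row.gap_mm))
        out.append(
            Trajectory(
                patient_id=str(row.patient_id),
                electrode_name=str(row.electrode_name),
                target_point=(float(row.target_x), float(row.target_y), float(row.target_z)),
                unit_direction=(float(row.dir_x), float(row.dir_y), float(row.dir_z)),
                model=model,
            )
        )
    return out


def write_trajectories(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    rows = []
    for t in trajectories:
        gap = t.model.gaps[0]
        rows.append(
            dict(
                patient_id=t.patient_id,
                electrode_name=t.electrode_name,
                model_id=t.model.model_id,
                n_contacts=t.model.n_contacts,
                gap_mm=gap,
                target_x=t.target_point[0], target_y=t.target_point[1], target_z=t.target_point[2],
                dir_x=t.unit_direction[0], dir_y=t.unit_direction[1], dir_z=t.unit_direction[2],
            )
        )
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f", lineterminator="\n"
    )


def read_contact_table(path: str | Path) -> list[PlacedElectrode]:
    """Read a per-contact coordinate file, bypassing trajectory reconstruction.

    Columns: patient_id, electrode_name, index, x, y, z.  Contacts are grouped
    into electrodes (model unknown, recorded as ``explicit``), ordered by index.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str, "electrode_name": str})
    missing = set(CONTACT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contact file {path}: missing columns {sorted(missing)}")
    electrodes = []
    for (pid, ename), grp in df.groupby(["patient_id", "electrode_name"], sort=True):
        grp = grp.sort_values("index")
        contacts = tuple(
            Contact(
                contact_id=f"{ename}{int(idx)}",
                index=int(idx),
                center=(float(x), float(y), float(z)),
            )
            for idx, x, y, z in grp[["index", "x", "y", "z"]].to_numpy()
        )
        electrodes.append(PlacedElectrode(str(pid), str(ename), "explicit", contacts))
    return electrodes


def is_contact_table(path: str | Path) -> bool:
    """Sniff whether a tab-separated electrode file is per-contact or per-trajectory."""
    header = pd.read_csv(path, sep="\t", comment="#", nrows=0)
    return {"index", "x", "y", "z"}.issubset(header.columns)
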