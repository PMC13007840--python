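"""Simulated multi-electrode implantations on a phantom, with ground truth.

The simulator emulates the scale of a typical SEEG cohort: about 10 +/- 2
electrodes per patient, a 50/50 mix of Spencer-6 and reduced-diameter
electrodes (6-10 contacts at 5 mm pitch, about 7.4 contacts per electrode on
average), and an implantation-side mix of roughly 35% left, 46% right and 19%
bilateral patients.  Each electrode's deepest-contact target is drawn
uniformly from the phantom parenchyma on the patient's implanted side
(outside the ventricle) and its direction points toward a random entry point
on the brain surface of the same side, so trajectories run from deep tissue
out through the gray-matter shell - proximal contacts may land in CSF, as
they do clinically.

All randomness flows through one seeded generator; with a fixed seed the
emitted files are byte-identical across runs (volumes are written as
uncompressed NIfTI for this reason).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from seegwm.electrodes import (
    PlacedElectrode,
    Trajectory,
    place_electrode,
    reduced_diameter,
    spencer_probe,
    write_trajectories,
)
from seegwm.phantom import Phantom, PhantomSpec, spec_to_dict
from seegwm.tissue import write_label_config

_MAX_ATTEMPTS = 1000
_SIDE_PROBS = {"left": 30 / 86, "right": 40 / 86, "bilateral": 16 / 86}


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated implantation cohort plus its analytic ground truth."""

    phantom: Phantom
    seed: int
    trajectories: tuple[Trajectory, ...]
    electrodes: tuple[PlacedElectrode, ...]
    gt_tissue: pd.DataFrame  # patient_id, electrode, contact, x/y/z, true_tissue, ambiguous
    gt_crossing: pd.DataFrame  # patient_id, contact, tract, true_crossed, ambiguous

    @property
    def n_patients(self) -> int:
        return len({t.patient_id for t in self.trajectories})

    @property
    def n_contacts(self) -> int:
        return sum(e.n_contacts for e in self.electrodes)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all standard pipeline inputs plus ground truth to a directory.

        Emits the tissue atlas and per-tract NIfTI volumes, the electrode
        trajectory TSV, the tract manifest, the GM/WM label config, both
        ground-truth tables and a ready-to-run pipeline config (run.yaml).
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["tissue_atlas"] = out / "tissue_atlas.nii"
        self.phantom.tissue_atlas.volume.to_nifti(paths["tissue_atlas"])
        manifest_rows = []
        for atlas in self.phantom.tract_atlases:
            p = out / f"tract_{atlas.tract_name}.nii"
            atlas.volume.to_nifti(p)
            paths[f"tract_{atlas.tract_name}"] = p
            manifest_rows.append(
                {
                    "tract_name": atlas.tract_name,
                    "file": p.name,
                    "hemisphere": atlas.hemisphere,
                    "is_commissural": atlas.is_commissural,
                }
            )
        paths["tract_manifest"] = out / "tracts.tsv"
        pd.DataFrame(
            manifest_rows, columns=["tract_name", "file", "hemisphere", "is_commissural"]
        ).to_csv(paths["tract_manifest"], sep="\t", index=False, lineterminator="\n")

        paths["labels"] = out / "labels.yaml"
        write_label_config(
            paths["labels"],
            gm={self.phantom.spec.gm_label: "gm_shell"},
            wm={self.phantom.spec.wm_label: "wm_core"},
        )

        paths["electrodes"] = out / "electrodes.tsv"
        write_trajectories(self.trajectories, paths["electrodes"])

        paths["gt_tissue"] = out / "ground_truth_tissue.csv"
        self.gt_tissue.to_csv(
            paths["gt_tissue"], index=False, float_format="%.6f", lineterminator="\n"
        )
        paths["gt_crossing"] = out / "ground_truth.csv"
        self.gt_crossing.to_csv(
            paths["gt_crossing"], index=False, float_format="%.6f", lineterminator="\n"
        )

        paths["phantom_spec"] = out / "phantom.yaml"
        with open(paths["phantom_spec"], "w") as fh:
            yaml.safe_dump(spec_to_dict(self.phantom.spec), fh, sort_keys=True)

        paths["run_config"] = out / "run.yaml"
        with open(paths["run_config"], "w") as fh:
            yaml.safe_dump(
                {
                    "electrode_file": "electrodes.tsv",
                    "tissue_atlas": "tissue_atlas.nii",
                    "labels": "labels.yaml",
                    "tract_manifest": "tracts.tsv",
                    "out_dir": "results",
                    "threshold": 0.5,
                    "threshold_mode": "inclusive",
                    "aggregation": "max",
                    "singleton_axis": 2,
                    "precision": 2,
                    "seed": self.seed,
                },
                fh,
                sort_keys=False,
            )
        return paths


def _sample_target(
    rng: np.random.Generator, spec: PhantomSpec, sign: float
) -> np.ndarray:
    """Uniform point in the parenchyma on one side, outside the ventricle."""
    center = np.asarray(spec.brain_center)
    rmax = spec.brain_radius - 3.0
    for _ in range(_MAX_ATTEMPTS):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = rmax * rng.random() ** (1.0 / 3.0)
        p = center + r * u
        p[0] = center[0] + sign * abs(p[0] - center[0])
        if abs(p[0] - center[0]) < 1.0:
            continue
        if spec.ventricle is not None and spec.ventricle.level(p[None, :])[0] <= 1.2:
            continue
        return p
    raise RuntimeError(
        "target sampling failed: could not place a target inside the "
        "parenchyma outside the ventricle within the attempt budget"
    )


def _sample_direction(
    rng: np.random.Generator, spec: PhantomSpec, target: np.ndarray, sign: float
) -> np.ndarray:
    """Unit direction from target toward a same-side entry point on the surface."""
    center = np.asarray(spec.brain_center)
    for _ in range(_MAX_ATTEMPTS):
        v = rng.normal(size=3)
        v[0] = sign * abs(v[0])
        v /= np.linalg.norm(v)
        entry = center + spec.brain_radius * v
        d = entry - target
        dist = np.linalg.norm(d)
        if dist < 25.0:
            continue
        return d / dist
    raise RuntimeError(
        "direction sampling failed: no entry point at least 25 mm from the target"
    )


def simulate_cohort(
    phantom: Phantom,
    n_patients: int = 20,
    mean_electrodes: float = 10.0,
    sd_electrodes: float = 2.0,
    reduced_fraction: float = 0.5,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate an implantation cohort on a phantom.

    Reproducible given ``seed``; raises if the geometry cannot be satisfied
    within a bounded number of rejection-sampling attempts.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    spec = phantom.spec
    sides = list(_SIDE_PROBS)
    probs = np.asarray(list(_SIDE_PROBS.values()))

    trajectories: list[Trajectory] = []
    electrodes: list[PlacedElectrode] = []
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        side = str(rng.choice(sides, p=probs))
        n_el = max(3, int(round(rng.normal(mean_electrodes, sd_electrodes))))
        for j in range(n_el):
            if side == "bilateral":
                el_side = "left" if j % 2 == 0 else "right"
            else:
                el_side = side
            sign = -1.0 if el_side == "left" else 1.0
            if rng.random() < reduced_fraction:
                model = reduced_diameter(int(rng.integers(6, 11)), 5.0)
            else:
                model = spencer_probe()
            target = _sample_target(rng, spec, sign)
            direction = _sample_direction(rng, spec, target, sign)
            traj = Trajectory(
                patient_id=pid,
                electrode_name=f"{pid}E{j + 1}",
                target_point=tuple(float(v) for v in target),
                unit_direction=tuple(float(v) for v in direction),
                model=model,
            )
            trajectories.append(traj)
            electrodes.append(place_electrode(traj))

    # analytic ground truth for every contact
    tissue_rows = []
    ids: list[str] = []
    pts: list[tuple[float, float, float]] = []
    for e in electrodes:
        for c in e.contacts:
            ids.append(c.contact_id)
            pts.append(c.center)
            tissue_rows.append(
                {
                    "patient_id": e.patient_id,
                    "electrode": e.electrode_name,
                    "contact": c.contact_id,
                    "x": c.center[0],
                    "y": c.center[1],
                    "z": c.center[2],
                }
            )
    points = np.asarray(pts)
    classes, ambiguous = phantom.true_tissue(points)
    gt_tissue = pd.DataFrame(tissue_rows)
    gt_tissue["true_tissue"] = classes
    gt_tissue["ambiguous"] = ambiguous

    gt_crossing = phantom.true_crossings(ids, points)
    contact_patient = {
        c.contact_id: e.patient_id for e in electrodes for c in e.contacts
    }
    gt_crossing.insert(0, "patient_id", gt_crossing["contact"].map(contact_patient))

    return SimulatedCohort(
        phantom=phantom,
        seed=seed,
        trajectories=tuple(trajectories),
        electrodes=tuple(electrodes),
        gt_tissue=gt_tissue,
        gt_crossing=gt_crossing,
    )
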