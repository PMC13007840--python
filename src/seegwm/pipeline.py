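"""End-to-end pipeline: load -> place -> mask -> classify -> cross -> summarize.

The pipeline consumes an electrode file (trajectories or explicit per-contact
coordinates, already in the common analysis space), a labelled tissue atlas, a
probabilistic tract-atlas manifest, and a config.  It emits six artifacts into
the output directory:

* ``contacts.csv`` - one row per contact with coordinates, hemisphere, window
  bounds status and tissue class;
* ``tissue_census.csv`` - per-class counts and shares;
* ``crossings.csv`` - one row per (contact, tract) with probability and the
  crossing decision;
* ``cohort_tract_table.csv`` - per-tract cohort involvement table, in both
  contact scopes (all contacts / white-matter contacts only);
* ``overlap.csv`` - multi-tract overlap census over white-matter contacts,
  with and without commissural tracts;
* ``manifest.json`` - config, input hashes, stage counters, versions.

Any stage failure raises :class:`PipelineError` naming the stage, and partial
outputs are removed.  Reruns of an identical config produce byte-identical
CSVs (timestamps are confined to the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from seegwm._version import __version__ as _version
from seegwm.cohort import (
    CohortSummary,
    PatientSummary,
    summarize_cohort,
    summarize_patient,
)
from seegwm.crossing import (
    CrossingRecord,
    TractAtlas,
    decide_crossings,
    overlap_census,
    plan_stimulation,
)
from seegwm.electrodes import (
    PlacedElectrode,
    is_contact_table,
    place_electrode,
    read_contact_table,
    read_trajectories,
)
from seegwm.tissue import (
    WM,
    TissueAtlas,
    TissueClassification,
    classify_contacts,
    load_label_config,
    tissue_census,
)
from seegwm.volumes import ContactMask, Volume, contact_mask

log = logging.getLogger("seegwm")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    electrode_file: Path
    tissue_atlas: Path
    labels: Path
    tract_manifest: Path
    out_dir: Path
    threshold: float = 0.5
    threshold_mode: str = "inclusive"  # inclusive (>=) | strict (>)
    aggregation: str = "max"  # max | mean
    singleton_axis: int = 2
    precision: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in (0, 1], got {self.threshold}")
        if self.threshold_mode not in ("inclusive", "strict"):
            raise ValueError("threshold_mode must be 'inclusive' or 'strict'")
        if self.aggregation not in ("max", "mean"):
            raise ValueError("aggregation must be 'max' or 'mean'")
        if self.singleton_axis not in (0, 1, 2):
            raise ValueError("singleton_axis must be 0, 1 or 2")
        for name in ("electrode_file", "tissue_atlas", "labels", "tract_manifest"):
            p = Path(getattr(self, name))
            object.__setattr__(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        object.__setattr__(self, "out_dir", Path(self.out_dir))

    @property
    def inclusive(self) -> bool:
        return self.threshold_mode == "inclusive"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; relative paths resolve against its directory."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = path.parent
        kwargs = {}
        for name in ("electrode_file", "tissue_atlas", "labels", "tract_manifest", "out_dir"):
            if name not in raw:
                raise ValueError(f"config {path}: missing {name!r}")
            p = Path(raw[name])
            kwargs[name] = p if p.is_absolute() else base / p
        for name in ("threshold", "threshold_mode", "aggregation",
                     "singleton_axis", "precision", "seed"):
            if name in raw:
                kwargs[name] = raw[name]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {
            "electrode_file": str(self.electrode_file),
            "tissue_atlas": str(self.tissue_atlas),
            "labels": str(self.labels),
            "tract_manifest": str(self.tract_manifest),
            "out_dir": str(self.out_dir),
            "threshold": self.threshold,
            "threshold_mode": self.threshold_mode,
            "aggregation": self.aggregation,
            "singleton_axis": self.singleton_axis,
            "precision": self.precision,
            "seed": self.seed,
        }
        return d


def read_tract_manifest(path: str | Path) -> list[TractAtlas]:
    """Load tract atlases from a tab-separated manifest.

    Columns: tract_name, file (relative to the manifest), hemisphere,
    is_commissural.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"tract_name", "file", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tract manifest {path}: missing columns {sorted(missing)}")
    atlases = []
    for row in df.itertuples(index=False):
        f = Path(str(row.file))
        if not f.is_absolute():
            f = path.parent / f
        atlases.append(
            TractAtlas(
                tract_name=str(row.tract_name),
                hemisphere=str(row.hemisphere),
                volume=Volume.from_nifti(f),
            )
        )
    return atlases


@dataclass
class RunResult:
    """In-memory results of one pipeline run."""

    config: RunConfig
    electrodes: list[PlacedElectrode]
    masks: dict[str, ContactMask]
    classifications: list[TissueClassification]
    records: list[CrossingRecord]
    contacts_df: pd.DataFrame
    census_df: pd.DataFrame
    crossings_df: pd.DataFrame
    cohort_df: pd.DataFrame
    overlap_df: pd.DataFrame
    cohort_all: CohortSummary
    cohort_wm: CohortSummary
    manifest: dict
    output_paths: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_electrodes(config: RunConfig) -> list[PlacedElectrode]:
    if is_contact_table(config.electrode_file):
        return read_contact_table(config.electrode_file)
    return [place_electrode(t) for t in read_trajectories(config.electrode_file)]


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full pipeline; optionally write the six output artifacts."""
    t0 = time.time()
    stage = "load"
    try:
        electrodes = _load_electrodes(config)
        gm_labels, wm_labels = load_label_config(config.labels)
        atlas = TissueAtlas(
            volume=Volume.from_nifti(config.tissue_atlas),
            gm_labels=gm_labels,
            wm_labels=wm_labels,
        )
        tracts = read_tract_manifest(config.tract_manifest)
        if not electrodes:
            raise ValueError("electrode file contains no electrodes")
        log.info("load: %d electrodes, %d tracts", len(electrodes), len(tracts))

        stage = "mask"
        masks: dict[str, ContactMask] = {}
        for e in electrodes:
            for c in e.contacts:
                if c.contact_id in masks:
                    raise ValueError(f"duplicate contact id {c.contact_id!r}")
                masks[c.contact_id] = contact_mask(
                    atlas.volume, c, singleton_axis=config.singleton_axis
                )
        log.info("mask: %d contact windows", len(masks))

        stage = "classify"
        ordered_masks = [masks[c.contact_id] for e in electrodes for c in e.contacts]
        classifications = classify_contacts(atlas, ordered_masks)
        census = tissue_census(classifications, ndigits=config.precision)
        log.info("classify: %d intraparenchymal of %d",
                 census.n_intraparenchymal, census.total)

        stage = "cross"
        records = decide_crossings(
            tracts,
            ordered_masks,
            threshold=config.threshold,
            inclusive=config.inclusive,
            aggregation=config.aggregation,
        )
        n_crossed = sum(r.crossed for r in records)
        log.info("cross: %d crossed of %d (contact, tract) pairs",
                 n_crossed, len(records))

        stage = "summarize"
        commissural = {t.tract_name for t in tracts if t.is_commissural}
        cls_by_id = {c.contact_id: c for c in classifications}
        hemi_by_id = {c.contact_id: c.hemisphere for e in electrodes for c in e.contacts}

        by_patient: dict[str, list[PlacedElectrode]] = {}
        for e in electrodes:
            by_patient.setdefault(e.patient_id, []).append(e)

        summaries_all: list[PatientSummary] = []
        summaries_wm: list[PatientSummary] = []
        for pid in sorted(by_patient):
            els = by_patient[pid]
            own = {c.contact_id for e in els for c in e.contacts}
            cls = [cls_by_id[cid] for e in els for c in e.contacts
                   for cid in (c.contact_id,)]
            recs = [r for r in records if r.contact_id in own]
            summaries_all.append(summarize_patient(els, cls, recs))
            wm_cls = [c for c in cls if c.tissue_class == WM]
            summaries_wm.append(summarize_patient(els, wm_cls, recs))
        cohort_all = summarize_cohort(summaries_all, commissural, config.precision)
        cohort_wm = summarize_cohort(summaries_wm, commissural, config.precision)

        wm_ids = {c.contact_id for c in classifications if c.tissue_class == WM}
        overlap_rows = []
        for excl in (False, True):
            oc = overlap_census(
                records,
                exclude_commissural=excl,
                commissural_tracts=commissural,
                contact_ids=wm_ids,
            )
            overlap_rows.append(
                {
                    "scope": "wm_contacts",
                    "commissural_excluded": excl,
                    "n_contacts": oc.n_contacts,
                    "n_ge2": oc.n_ge2,
                    "pct_ge2": oc.pct_ge2,
                    "n_ge3": oc.n_ge3,
                    "pct_ge3": oc.pct_ge3,
                }
            )

        stage = "report"
        contact_rows = []
        for e in electrodes:
            for c in e.contacts:
                contact_rows.append(
                    {
                        "patient_id": e.patient_id,
                        "electrode": e.electrode_name,
                        "contact": c.contact_id,
                        "index": c.index,
                        "x": c.center[0],
                        "y": c.center[1],
                        "z": c.center[2],
                        "hemisphere": c.hemisphere,
                        "in_bounds": masks[c.contact_id].in_bounds,
                        "tissue_class": cls_by_id[c.contact_id].tissue_class,
                    }
                )
        contacts_df = pd.DataFrame(contact_rows)

        patient_by_id = {c.contact_id: e.patient_id
                         for e in electrodes for c in e.contacts}
        electrode_by_id = {c.contact_id: e.electrode_name
                           for e in electrodes for c in e.contacts}
        crossings_df = pd.DataFrame(
            [
                {
                    "patient_id": patient_by_id[r.contact_id],
                    "electrode": electrode_by_id[r.contact_id],
                    "contact": r.contact_id,
                    "tract": r.tract_name,
                    "is_commissural": r.tract_name in commissural,
                    "probability": r.probability,
                    "crossed": r.crossed,
                }
                for r in records
            ]
        )
        census_df = census.to_frame()

        cohort_df = pd.concat(
            [
                cohort_all.tract_table.assign(scope="all_contacts"),
                cohort_wm.tract_table.assign(scope="wm_contacts"),
            ],
            ignore_index=True,
        )
        cohort_df = cohort_df[
            ["scope"] + [c for c in cohort_df.columns if c != "scope"]
        ]
        overlap_df = pd.DataFrame(overlap_rows)

        manifest = {
            "package_version": _version,
            "config": config.to_dict(),
            "inputs_sha256": {
                "electrode_file": _sha256(config.electrode_file),
                "tissue_atlas": _sha256(config.tissue_atlas),
                "labels": _sha256(config.labels),
                "tract_manifest": _sha256(config.tract_manifest),
            },
            "counts": {
                "patients": len(by_patient),
                "electrodes": len(electrodes),
                "contacts": len(masks),
                "intraparenchymal": census.n_intraparenchymal,
                "crossed_pairs": n_crossed,
            },
            "runtime_s": None,  # filled at write time
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    result = RunResult(
        config=config,
        electrodes=electrodes,
        masks=masks,
        classifications=classifications,
        records=records,
        contacts_df=contacts_df,
        census_df=census_df,
        crossings_df=crossings_df,
        cohort_df=cohort_df,
        overlap_df=overlap_df,
        cohort_all=cohort_all,
        cohort_wm=cohort_wm,
        manifest=manifest,
    )
    if write:
        _write_outputs(result, elapsed=time.time() - t0)
    return result


def _write_outputs(result: RunResult, elapsed: float) -> None:
    out = result.config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        tables = {
            "contacts.csv": result.contacts_df,
            "tissue_census.csv": result.census_df,
            "crossings.csv": result.crossings_df,
            "cohort_tract_table.csv": result.cohort_df,
            "overlap.csv": result.overlap_df,
        }
        for name, df in tables.items():
            p = out / name
            df.to_csv(p, index=False, float_format="%.6f", lineterminator="\n")
            written.append(p)
            result.output_paths[name] = p
        result.manifest["runtime_s"] = round(elapsed, 3)
        result.manifest["written_utc"] = time.strftime(
            "%Y-%m-%dT%H:%M:%SZ", time.gmtime()
        )
        p = out / "manifest.json"
        with open(p, "w") as fh:
            json.dump(result.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
        result.output_paths["manifest.json"] = p
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("write", str(exc)) from exc
    log.info("report: wrote %d artifacts to %s", len(written), out)


def plan_stimulation_run(config: RunConfig, tract_name: str):
    """Stimulation planning for one tract under a pipeline config."""
    tracts = read_tract_manifest(config.tract_manifest)
    by_name = {t.tract_name: t for t in tracts}
    if tract_name not in by_name:
        raise PipelineError(
            "plan", f"tract {tract_name!r} not in manifest "
                    f"({sorted(by_name)})"
        )
    atlas_vol = Volume.from_nifti(config.tissue_atlas)
    electrodes = _load_electrodes(config)
    masks = {
        c.contact_id: contact_mask(atlas_vol, c, singleton_axis=config.singleton_axis)
        for e in electrodes for c in e.contacts
    }
    contacts = {e.electrode_name: list(e.contacts) for e in electrodes}
    return plan_stimulation(
        by_name[tract_name],
        contacts,
        masks,
        threshold=config.threshold,
        inclusive=config.inclusive,
        aggregation=config.aggregation,
    )
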