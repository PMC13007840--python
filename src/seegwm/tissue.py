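"""Tissue-compartment classification of contacts against a labelled atlas.

A Harvard-Oxford-like integer atlas partitions labels into gray-matter and
white-matter sets; label 0 and anything in neither set is CSF/extra-
parenchymal.  A contact is classified from its full 2x2x1 window: gray matter
if the window touches only GM labels, white matter if only WM labels,
gray-white boundary if both, CSF if neither (including an empty, out-of-volume
window).  "Boundary" is thus defined operationally - the window overlaps both
compartments - which is the only definition expressible from a binary
parcellation and a voxel window.

Census percentages follow the reporting convention of the cohort tables: the
intraparenchymal share is taken over all contacts, while per-class shares are
taken over intraparenchymal contacts only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from seegwm._rounding import percentage
from seegwm.volumes import ContactMask, Volume, mask_values, require_same_grid

GM = "GM"
GM_WM_BOUNDARY = "GM_WM_BOUNDARY"
WM = "WM"
CSF = "CSF"
TISSUE_CLASSES = (GM, GM_WM_BOUNDARY, WM, CSF)


@dataclass(frozen=True)
class TissueAtlas:
    """Labelled tissue parcellation with GM/WM label sets.

    Subcortical gray nuclei (thalamus, basal ganglia) belong in ``gm_labels``
    by default when configuring real atlases; the split is fully caller-defined.
    """

    volume: Volume
    gm_labels: frozenset[int]
    wm_labels: frozenset[int]

    def __post_init__(self):
        gm = frozenset(int(v) for v in self.gm_labels)
        wm = frozenset(int(v) for v in self.wm_labels)
        if gm & wm:
            raise ValueError(f"gm and wm label sets overlap: {sorted(gm & wm)}")
        if 0 in gm or 0 in wm:
            raise ValueError("label 0 is background/CSF and cannot be GM or WM")
        object.__setattr__(self, "gm_labels", gm)
        object.__setattr__(self, "wm_labels", wm)


@dataclass(frozen=True)
class TissueClassification:
    contact_id: str
    tissue_class: str

    @property
    def intraparenchymal(self) -> bool:
        return self.tissue_class != CSF


def classify_contact(atlas: TissueAtlas, mask: ContactMask) -> TissueClassification:
    """Classify one contact window against the tissue atlas.

    The mask must have been computed on a grid identical to the atlas volume.
    """
    if mask.source is not None:
        require_same_grid(mask.source, atlas.volume)
    labels = mask_values(atlas.volume, mask)
    has_gm = any(int(v) in atlas.gm_labels for v in labels)
    has_wm = any(int(v) in atlas.wm_labels for v in labels)
    if has_gm and has_wm:
        cls = GM_WM_BOUNDARY
    elif has_gm:
        cls = GM
    elif has_wm:
        cls = WM
    else:
        cls = CSF
    return TissueClassification(contact_id=mask.contact_id, tissue_class=cls)


def classify_contacts(
    atlas: TissueAtlas, masks: Iterable[ContactMask]
) -> list[TissueClassification]:
    return [classify_contact(atlas, m) for m in masks]


@dataclass(frozen=True)
class TissueCensus:
    """Per-class counts with report-precision percentages."""

    total: int
    counts: Mapping[str, int]  # keyed by tissue class
    ndigits: int = 2

    @property
    def n_intraparenchymal(self) -> int:
        return self.total - self.counts.get(CSF, 0)

    @property
    def pct_intraparenchymal(self) -> float:
        """Share of intraparenchymal contacts among all contacts."""
        return percentage(self.n_intraparenchymal, self.total, self.ndigits)

    @property
    def pct_csf(self) -> float:
        return percentage(self.counts.get(CSF, 0), self.total, self.ndigits)

    def pct_of_intraparenchymal(self, tissue_class: str) -> float:
        """Share of one parenchymal class among intraparenchymal contacts."""
        if tissue_class == CSF:
            raise ValueError("CSF share is taken over all contacts, not parenchyma")
        return percentage(
            self.counts.get(tissue_class, 0), self.n_intraparenchymal, self.ndigits
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in TISSUE_CLASSES:
            n = self.counts.get(cls, 0)
            pct = (
                percentage(n, self.total, self.ndigits)
                if cls == CSF
                else self.pct_of_intraparenchymal(cls)
            )
            rows.append({"class": cls, "n": n, "pct": pct})
        rows.append(
            {
                "class": "intraparenchymal",
                "n": self.n_intraparenchymal,
                "pct": self.pct_intraparenchymal,
            }
        )
        return pd.DataFrame(rows, columns=["class", "n", "pct"])


def tissue_census(
    classifications: Sequence[TissueClassification], ndigits: int = 2
) -> TissueCensus:
    """Census of a nonempty classification list."""
    if not classifications:
        raise ValueError("cannot take a census of zero contacts")
    counts = {cls: 0 for cls in TISSUE_CLASSES}
    for c in classifications:
        counts[c.tissue_class] += 1
    return TissueCensus(total=len(classifications), counts=counts, ndigits=ndigits)


def census_from_counts(
    gm: int, boundary: int, wm: int, csf: int, ndigits: int = 2
) -> TissueCensus:
    """Build a census directly from per-class counts (e.g. published tables)."""
    total = gm + boundary + wm + csf
    if total == 0:
        raise ValueError("cannot take a census of zero contacts")
    return TissueCensus(
        total=total,
        counts={GM: gm, GM_WM_BOUNDARY: boundary, WM: wm, CSF: csf},
        ndigits=ndigits,
    )


# ---------------------------------------------------------------------------
# label-set configuration file
# ---------------------------------------------------------------------------


def load_label_config(path: str | Path) -> tuple[frozenset[int], frozenset[int]]:
    """Read GM/WM label sets from a YAML file.

    Accepts either lists of integers or mappings label -> name under the keys
    ``gm`` and ``wm``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = []
    for key in ("gm", "wm"):
        if key not in cfg:
            raise ValueError(f"label config {path}: missing {key!r} section")
        section = cfg[key]
        labels = section.keys() if isinstance(section, Mapping) else section
        out.append(frozenset(int(v) for v in labels))
    return out[0], out[1]


def write_label_config(
    path: str | Path,
    gm: Mapping[int, str] | Iterable[int],
    wm: Mapping[int, str] | Iterable[int],
) -> None:
    def norm(section):
        if isinstance(section, Mapping):
            return {int(k): str(v) for k, v in section.items()}
        return sorted(int(v) for v in section)

    with open(path, "w") as fh:
        yaml.safe_dump({"gm": norm(gm), "wm": norm(wm)}, fh, sort_keys=True)
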