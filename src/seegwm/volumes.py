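"""Atlas volumes, world/voxel coordinate transforms, and the per-contact mask.

Every contact is represented in atlas voxel space by a 2 x 2 x 1 voxel window
centred on its continuous voxel coordinate, matching the physical contact size
on a 1 mm grid.  A 2-voxel window cannot be centred on a single voxel; along
each in-plane axis the window takes the two voxels whose centers bracket the
continuous coordinate, i.e. ``{floor(c), floor(c) + 1}``.  When the coordinate
falls exactly on a voxel center the bracketing pair is ambiguous and the tie is
resolved toward the negative neighbour, ``{c - 1, c}``.  The singleton axis
(default: the third array axis, inferior-superior for RAS+ volumes) takes the
nearest voxel plane, ties again toward the negative side.

With this rule every window voxel center lies within sqrt(1^2 + 1^2 + 0.5^2)
= 1.5 mm of the contact center on a 1 mm isotropic grid - strictly inside the
sqrt(3) mm voxel-diagonal ambiguity band used by the synthetic-phantom oracle,
so window-based decisions provably agree with analytic ground truth for every
contact farther than one voxel diagonal from a decision surface.

Masks are computed in the atlas's own voxel grid directly from world
coordinates; atlases are never resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from seegwm.electrodes import Contact


@dataclass(frozen=True)
class Volume:
    """A 3D scalar volume with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {data.shape}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        try:
            inv = np.linalg.inv(affine)
        except np.linalg.LinAlgError as exc:
            raise ValueError("volume affine is singular") from exc
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "_inv_affine", inv)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine))

    def to_nifti(self, path: str | Path) -> None:
        nib.Nifti1Image(self.data, self.affine).to_filename(str(path))

    def world_to_voxel(self, points_mm) -> np.ndarray:
        """Map world-space mm points to continuous voxel coordinates (no rounding)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        hom = np.c_[pts, np.ones(len(pts))]
        vox = (self._inv_affine @ hom.T).T[:, :3]
        return vox[0] if np.asarray(points_mm).ndim == 1 else vox

    def voxel_to_world(self, voxels) -> np.ndarray:
        """Map (possibly continuous) voxel coordinates to world-space mm."""
        vox = np.atleast_2d(np.asarray(voxels, dtype=float))
        hom = np.c_[vox, np.ones(len(vox))]
        world = (self.affine @ hom.T).T[:, :3]
        return world[0] if np.asarray(voxels).ndim == 1 else world

    def in_bounds(self, ijk: Sequence[int]) -> bool:
        return all(0 <= v < n for v, n in zip(ijk, self.shape))


def same_grid(a: Volume, b: Volume, tol: float = 1e-6) -> bool:
    return a.shape == b.shape and bool(np.allclose(a.affine, b.affine, atol=tol))


def require_same_grid(a: Volume, b: Volume) -> None:
    if not same_grid(a, b):
        raise ValueError(
            f"volume geometry mismatch: shapes {a.shape} vs {b.shape} or affines differ"
        )


@dataclass(frozen=True)
class ContactMask:
    """The 2x2x1-voxel window of one contact in a specific atlas grid.

    ``voxels`` holds 0-based integer voxel triples; a fully in-bounds mask has
    exactly 4 of them.  ``in_bounds`` is False iff any window voxel was clipped
    at the volume border (an entirely out-of-volume contact yields an empty
    voxel set).
    """

    contact_id: str
    voxels: frozenset[tuple[int, int, int]]
    in_bounds: bool
    source: "Volume | None" = field(default=None, compare=False, repr=False)


def _bracketing_pair(c: float) -> tuple[int, int]:
    # {floor(c), floor(c)+1}; at integer coordinates tie toward {c-1, c}
    lo = int(math.ceil(c)) - 1
    return lo, lo + 1


def _nearest_plane(c: float) -> int:
    # nearest integer, tie toward the negative side
    return int(math.ceil(c - 0.5))


def contact_mask(
    vol: Volume,
    contact: Contact | Sequence[float],
    contact_id: str | None = None,
    singleton_axis: int = 2,
) -> ContactMask:
    """Build the 2x2x1 window mask for one contact in ``vol``'s voxel grid."""
    if singleton_axis not in (0, 1, 2):
        raise ValueError("singleton_axis must be 0, 1 or 2")
    if isinstance(contact, Contact):
        center = contact.center
        cid = contact.contact_id if contact_id is None else contact_id
    else:
        center = tuple(contact)
        cid = "" if contact_id is None else contact_id
    c = vol.world_to_voxel(np.asarray(center, dtype=float))
    ranges: list[tuple[int, ...]] = [()] * 3
    for ax in range(3):
        if ax == singleton_axis:
            ranges[ax] = (_nearest_plane(float(c[ax])),)
        else:
            ranges[ax] = _bracketing_pair(float(c[ax]))
    full = [
        (i, j, k)
        for i in ranges[0]
        for j in ranges[1]
        for k in ranges[2]
    ]
    kept = frozenset(v for v in full if vol.in_bounds(v))
    return ContactMask(
        contact_id=cid, voxels=kept, in_bounds=len(kept) == len(full), source=vol
    )


def mask_values(vol: Volume, mask: ContactMask) -> np.ndarray:
    """Atlas values at the mask's voxels (empty array for an empty mask)."""
    if not mask.voxels:
        return np.empty(0, dtype=vol.data.dtype)
    idx = np.array(sorted(mask.voxels))
    return vol.data[idx[:, 0], idx[:, 1], idx[:, 2]]


def masks_to_labelmap(vol: Volume, masks: Iterable[ContactMask]) -> Volume:
    """Union of contact windows as a labelled volume (1-based, write order wins)."""
    out = np.zeros(vol.shape, dtype=np.int32)
    for label, mask in enumerate(masks, start=1):
        for i, j, k in mask.voxels:
            out[i, j, k] = label
    return Volume(out, vol.affine)
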