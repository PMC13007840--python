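"""Synthetic tissue phantoms and tube-shaped probabilistic tract atlases.

The phantom is deliberately geometric, not anatomical: a spherical brain with
a CSF exterior, a gray-matter shell, a white-matter core and an optional
ellipsoidal ventricle, plus tube tracts defined by a polyline centerline, a
radius r and a radial probability profile.  The default linear profile
``p(d) = max(0, 1 - d/r)`` puts the chance-level (0.5) crossing surface
exactly on the analytic cylinder d = r/2, giving a closed-form oracle for the
crossing rule; a Gaussian profile with the same half-probability radius is
available as an option.

Voxel volumes store the analytic functions evaluated exactly at voxel
centers, so the only discrepancy between voxelized pipeline decisions and the
analytic ground truth can come from the finite 2x2x1 sampling window - which
is confined to within one voxel diagonal (sqrt(3) mm on the 1 mm grid) of a
decision surface.  Ground-truth queries therefore flag any contact within
sqrt(3) mm of a tissue interface or of a tract's half-probability surface as
ambiguous; outside that band, window-based decisions provably match the
analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from seegwm.crossing import COMMISSURAL, TractAtlas
from seegwm.tissue import CSF, GM, TissueAtlas, WM
from seegwm.volumes import Volume

#: half of one voxel diagonal band on each side of a decision surface (mm, 1 mm grid)
AMBIGUITY_MARGIN = math.sqrt(3.0)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid (used for the ventricle)."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def __post_init__(self):
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError("ellipsoid semiaxes must be positive")

    def level(self, points: np.ndarray) -> np.ndarray:
        """Normalized radius m: m <= 1 inside, m > 1 outside."""
        rel = (np.atleast_2d(points) - np.asarray(self.center)) / np.asarray(self.semiaxes)
        return np.sqrt(np.sum(rel**2, axis=1))

    def surface_distance_lower_bound(self, points: np.ndarray) -> np.ndarray:
        """A lower bound on the Euclidean distance to the surface.

        |m - 1| * min(semiaxes) never exceeds the true distance (the level
        function's gradient norm is at most 1/min(semiaxes)), so flagging
        contacts with a small bound as ambiguous can only over-flag, never
        miss a contact that is genuinely close to the surface.
        """
        return np.abs(self.level(points) - 1.0) * min(self.semiaxes)


@dataclass(frozen=True)
class TubeTract:
    """A tube tract: polyline centerline, radius, radial probability profile."""

    name: str
    hemisphere: str  # left | right | commissural
    centerline: tuple[tuple[float, float, float], ...]
    radius: float
    profile: str = "linear"  # linear | gaussian

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"tract {self.name!r}: radius must be positive")
        if len(self.centerline) < 2:
            raise ValueError(f"tract {self.name!r}: centerline needs >= 2 points")
        if self.profile not in ("linear", "gaussian"):
            raise ValueError(f"tract {self.name!r}: unknown profile {self.profile!r}")

    @property
    def half_radius(self) -> float:
        """Distance at which the profile drops to probability 0.5 (= r/2)."""
        return self.radius / 2.0

    def centerline_distance(self, points) -> np.ndarray:
        """Minimum distance from each point to the centerline polyline."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cl = np.asarray(self.centerline, dtype=float)
        best = np.full(len(pts), np.inf)
        for a, b in zip(cl[:-1], cl[1:]):
            ab = b - a
            denom = float(ab @ ab)
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(pts - proj, axis=1)
            best = np.minimum(best, d)
        return best

    def probability(self, points) -> np.ndarray:
        """Analytic tract probability at arbitrary mm points."""
        d = self.centerline_distance(points)
        if self.profile == "linear":
            return np.maximum(0.0, 1.0 - d / self.radius)
        # Gaussian with the same half-probability radius r/2: p = 2^{-(2d/r)^2}
        return np.exp2(-((2.0 * d / self.radius) ** 2))

    def true_crossing(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Analytic crossing decision (d <= r/2) and sqrt(3)-band ambiguity flag."""
        d = self.centerline_distance(points)
        crossed = d <= self.half_radius
        ambiguous = np.abs(d - self.half_radius) <= AMBIGUITY_MARGIN
        return crossed, ambiguous


def default_tracts() -> tuple[TubeTract, ...]:
    """Three radius-8 mm tubes: one per hemisphere plus one commissural band."""
    return (
        TubeTract(
            name="left_association",
            hemisphere="left",
            centerline=((-25.0, -35.0, 0.0), (-25.0, 35.0, 0.0)),
            radius=8.0,
        ),
        TubeTract(
            name="right_association",
            hemisphere="right",
            centerline=((25.0, -35.0, 0.0), (25.0, 0.0, 5.0), (25.0, 35.0, 0.0)),
            radius=8.0,
        ),
        # runs through both association tubes so multi-tract overlap regions exist,
        # as commissural fibers do in real disconnectome maps
        TubeTract(
            name="commissural_band",
            hemisphere=COMMISSURAL,
            centerline=((-35.0, 0.0, 0.0), (35.0, 0.0, 0.0)),
            radius=8.0,
        ),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic brain phantom (1 mm isotropic by default)."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 1.0
    brain_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    brain_radius: float = 54.0
    gm_thickness: float = 4.0
    ventricle: Ellipsoid | None = Ellipsoid((0.0, -15.0, 0.0), (6.0, 10.0, 6.0))
    tracts: tuple[TubeTract, ...] = field(default_factory=default_tracts)
    gm_label: int = 1
    wm_label: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if self.gm_thickness <= 0:
            raise ValueError("GM shell thickness must be positive")
        if self.brain_radius <= self.gm_thickness:
            raise ValueError("brain radius must exceed the GM shell thickness")
        center = np.asarray(self.brain_center)
        for tract in self.tracts:
            rho = np.linalg.norm(np.asarray(tract.centerline) - center, axis=1)
            if np.any(rho > self.wm_radius):
                raise ValueError(
                    f"tract {tract.name!r}: centerline exits the WM core "
                    f"(max radius {rho.max():.1f} > {self.wm_radius:.1f} mm)"
                )

    @property
    def wm_radius(self) -> float:
        return self.brain_radius - self.gm_thickness

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine placing the brain center at the volume center."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size
        half = (np.asarray(self.shape) - 1) / 2.0 * self.voxel_size
        aff[:3, 3] = np.asarray(self.brain_center) - half
        return aff


def default_phantom_spec(**overrides) -> PhantomSpec:
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


@dataclass(frozen=True)
class Phantom:
    """A built phantom: voxelized atlases plus the analytic ground-truth oracle."""

    spec: PhantomSpec
    tissue_atlas: TissueAtlas
    tract_atlases: tuple[TractAtlas, ...]

    # -- analytic oracle ----------------------------------------------------

    def true_tissue(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Analytic tissue class per point plus sqrt(3)-band ambiguity flag.

        The analytic truth knows only GM / WM / CSF; a window-based boundary
        classification can only arise within the ambiguity band around the
        GM/WM interface.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        spec = self.spec
        rho = np.linalg.norm(pts - np.asarray(spec.brain_center), axis=1)
        classes = np.where(
            rho > spec.brain_radius, CSF, np.where(rho > spec.wm_radius, GM, WM)
        ).astype(object)
        interface = np.minimum(
            np.abs(rho - spec.brain_radius), np.abs(rho - spec.wm_radius)
        )
        if spec.ventricle is not None:
            inside = spec.ventricle.level(pts) <= 1.0
            classes[inside] = CSF
            interface = np.minimum(
                interface, spec.ventricle.surface_distance_lower_bound(pts)
            )
        ambiguous = interface <= AMBIGUITY_MARGIN
        return classes, ambiguous

    def true_crossings(self, contact_ids: Sequence[str], points) -> pd.DataFrame:
        """Ground-truth crossing table for a set of contact centers."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rows = []
        for tract in self.spec.tracts:
            crossed, ambiguous = tract.true_crossing(pts)
            for cid, cr, am in zip(contact_ids, crossed, ambiguous):
                rows.append(
                    {
                        "contact": cid,
                        "tract": tract.name,
                        "true_crossed": bool(cr),
                        "ambiguous": bool(am),
                    }
                )
        df = pd.DataFrame(rows, columns=["contact", "tract", "true_crossed", "ambiguous"])
        return df.sort_values(["contact", "tract"], kind="stable").reset_index(drop=True)


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize a phantom spec into tissue and tract atlases.

    All volumes store the analytic geometry evaluated exactly at voxel
    centers; the build is fully deterministic.
    """
    affine = spec.affine
    shape = tuple(spec.shape)
    # world coordinates of all voxel centers
    ii, jj, kk = np.indices(shape, dtype=float)
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vox * spec.voxel_size + affine[:3, 3]

    center = np.asarray(spec.brain_center)
    rho = np.linalg.norm(world - center, axis=1)
    labels = np.zeros(len(world), dtype=np.int16)
    labels[rho <= spec.brain_radius] = spec.gm_label
    labels[rho <= spec.wm_radius] = spec.wm_label
    if spec.ventricle is not None:
        labels[spec.ventricle.level(world) <= 1.0] = 0
    tissue_vol = Volume(labels.reshape(shape), affine)
    tissue_atlas = TissueAtlas(
        volume=tissue_vol,
        gm_labels=frozenset({spec.gm_label}),
        wm_labels=frozenset({spec.wm_label}),
    )

    tract_atlases = []
    for tract in spec.tracts:
        data = np.zeros(len(world), dtype=np.float32)
        # only evaluate inside the tube's bounding box (plus margin)
        cl = np.asarray(tract.centerline)
        lo = cl.min(axis=0) - tract.radius - 2 * spec.voxel_size
        hi = cl.max(axis=0) + tract.radius + 2 * spec.voxel_size
        box = np.all((world >= lo) & (world <= hi), axis=1)
        if np.any(box):
            data[box] = tract.probability(world[box]).astype(np.float32)
        tract_atlases.append(
            TractAtlas(
                tract_name=tract.name,
                hemisphere=tract.hemisphere,
                volume=Volume(data.reshape(shape), affine),
            )
        )
    return Phantom(spec=spec, tissue_atlas=tissue_atlas, tract_atlases=tuple(tract_atlases))


# ---------------------------------------------------------------------------
# YAML (de)serialization of phantom specs
# ---------------------------------------------------------------------------


def spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "shape": list(spec.shape),
        "voxel_size": spec.voxel_size,
        "brain_center": list(spec.brain_center),
        "brain_radius": spec.brain_radius,
        "gm_thickness": spec.gm_thickness,
        "ventricle": (
            None
            if spec.ventricle is None
            else {
                "center": list(spec.ventricle.center),
                "semiaxes": list(spec.ventricle.semiaxes),
            }
        ),
        "tracts": [
            {
                "name": t.name,
                "hemisphere": t.hemisphere,
                "centerline": [list(p) for p in t.centerline],
                "radius": t.radius,
                "profile": t.profile,
            }
            for t in spec.tracts
        ],
        "gm_label": spec.gm_label,
        "wm_label": spec.wm_label,
        "rng_seed": spec.rng_seed,
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    ventricle = d.get("ventricle")
    tracts = tuple(
        TubeTract(
            name=t["name"],
            hemisphere=t["hemisphere"],
            centerline=tuple(tuple(float(v) for v in p) for p in t["centerline"]),
            radius=float(t["radius"]),
            profile=t.get("profile", "linear"),
        )
        for t in d.get("tracts", [])
    )
    return PhantomSpec(
        shape=tuple(int(v) for v in d.get("shape", (128, 128, 128))),
        voxel_size=float(d.get("voxel_size", 1.0)),
        brain_center=tuple(float(v) for v in d.get("brain_center", (0, 0, 0))),
        brain_radius=float(d.get("brain_radius", 54.0)),
        gm_thickness=float(d.get("gm_thickness", 4.0)),
        ventricle=(
            None
            if ventricle is None
            else Ellipsoid(
                center=tuple(float(v) for v in ventricle["center"]),
                semiaxes=tuple(float(v) for v in ventricle["semiaxes"]),
            )
        ),
        tracts=tracts if tracts else default_tracts(),
        gm_label=int(d.get("gm_label", 1)),
        wm_label=int(d.get("wm_label", 2)),
        rng_seed=int(d.get("rng_seed", 0)),
    )
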