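"""Synthetic canine pelvis geometry and CT-like phantom.

The study animal's CT data are confidential, so the canonical geometry here
is a parametric landmark model: named 3-D attachment points for every
ligament spring, fixed support, joint interface and load point, sized
loosely to a 25 kg Labrador retriever.  The coordinates are synthetic
defaults, not measured values.

Coordinate convention (right-handed, mm): origin at the mid-sagittal point
between the acetabula; +x lateral towards the dog's right, +y dorsal,
+z cranial.  The canonical geometry is exactly mirror-symmetric about the
x = 0 plane.

The module also renders the landmark set into a CT-like labelled voxel
volume (simple ellipsoidal solids per bone plus intensity-coded fiducial
markers) and segments it back by thresholding and connected-component
labelling, standing in for the threshold-based segmentation stage of a real
pipeline.  Operator placement noise across repeated trials is emulated by
seeded isotropic Gaussian perturbation of the spring attachment points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SIDES",
    "SPRING_ATTACHMENT_CLASSES",
    "PelvisLandmarks",
    "OperatorNoiseModel",
    "SyntheticCT",
    "SegmentationResult",
    "make_canonical_pelvis",
    "perturb_landmarks",
    "render_ct",
    "threshold_segment",
    "recover_fiducials",
    "save_nifti",
    "export_stl",
]

SIDES = ("L", "R")

#: Landmark classes that are ligament-spring attachment points; these are the
#: default targets of operator placement noise.
SPRING_ATTACHMENT_CLASSES = (
    "dorsal_sacrum_pts",
    "dorsal_ilium_pts",
    "ventral_sacrum_pts",
    "ventral_ilium_pts",
    "sij_sacrum_pts",
    "sij_ilium_pts",
    "st_origin_s3",
    "st_origin_c1",
    "st_insertion_tuber",
)

_PER_SIDE_CLASSES = SPRING_ATTACHMENT_CLASSES + ("acetabulum_center",)

# Canonical right-side coordinates (mm) at 25 kg, scale 1.  The left side is
# the exact mirror image (x -> -x).  Synthetic defaults, not measured data.
_CANON_REFERENCE_MASS = 25.0  # kg

_CANON_RIGHT = {
    "acetabulum_center": [[35.0, -15.0, 0.0]],
    "dorsal_sacrum_pts": [[10.0, 26.0, z] for z in (64.0, 57.0, 50.0, 43.0)],
    "dorsal_ilium_pts": [[24.0, 28.0, z] for z in (64.0, 57.0, 50.0, 43.0)],
    "ventral_sacrum_pts": [[12.0, 4.0, z] for z in (64.0, 57.0, 50.0, 43.0)],
    "ventral_ilium_pts": [[26.0, 2.0, z] for z in (64.0, 57.0, 50.0, 43.0)],
    "sij_sacrum_pts": [
        [14.0, y, z] for y in (10.0, 18.0) for z in (62.0, 57.0, 52.0, 47.0, 42.0)
    ],
    "sij_ilium_pts": [
        [18.0, y, z] for y in (10.0, 18.0) for z in (62.0, 57.0, 52.0, 47.0, 42.0)
    ],
    "st_origin_s3": [[11.0, 16.0, 18.0]],
    "st_origin_c1": [[8.0, 14.0, 2.0]],
    "st_insertion_tuber": [[30.0, -8.0, -45.0]],
}

_CANON_MIDLINE = {
    "load_point": [0.0, 24.0, 55.0],
    "sacrocaudal_sacrum": [0.0, 12.0, 10.0],
    "sacrocaudal_c1": [0.0, 12.0, 7.0],
}

_CANON_JOINT_AREA = 200.0  # mm^2
_CANON_JOINT_THICKNESS = 3.0  # mm

# Phantom bone solids (ellipsoids): name -> (center mm, semi-axes mm) at scale 1.
_CANON_BONES = {
    "sacrum": ([0.0, 14.0, 40.0], [13.0, 13.0, 28.0]),
    "hemipelvis_R": ([26.0, 0.0, 0.0], [7.0, 20.0, 50.0]),
    "hemipelvis_L": ([-26.0, 0.0, 0.0], [7.0, 20.0, 50.0]),
    "c1": ([0.0, 12.0, -2.0], [8.0, 8.0, 9.0]),
}

BONE_INTENSITY = 1200.0
FIDUCIAL_BASE_INTENSITY = 2000.0
NOMINAL_THRESHOLD = 300.0


def _mirror(points: np.ndarray) -> np.ndarray:
    out = points.copy()
    out[..., 0] *= -1.0
    return out


@dataclass
class PelvisLandmarks:
    """Named attachment-point geometry for the spring-network pelvis model.

    Per-side classes map side ("L"/"R") to an (n, 3) array of mm coordinates;
    midline points are (3,) arrays.  ``scale_factor`` records the overall
    linear scaling applied relative to the canonical 25 kg geometry (used by
    the phantom renderer to size bone solids consistently).
    """

    acetabulum_center: dict[str, np.ndarray]
    dorsal_sacrum_pts: dict[str, np.ndarray]
    dorsal_ilium_pts: dict[str, np.ndarray]
    ventral_sacrum_pts: dict[str, np.ndarray]
    ventral_ilium_pts: dict[str, np.ndarray]
    sij_sacrum_pts: dict[str, np.ndarray]
    sij_ilium_pts: dict[str, np.ndarray]
    st_origin_s3: dict[str, np.ndarray]
    st_origin_c1: dict[str, np.ndarray]
    st_insertion_tuber: dict[str, np.ndarray]
    load_point: np.ndarray
    sacrocaudal_sacrum: np.ndarray
    sacrocaudal_c1: np.ndarray
    sacrocaudal_area: float = _CANON_JOINT_AREA
    sacrocaudal_thickness: float = _CANON_JOINT_THICKNESS
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        expected = {
            "acetabulum_center": 1,
            "dorsal_sacrum_pts": 4,
            "dorsal_ilium_pts": 4,
            "ventral_sacrum_pts": 4,
            "ventral_ilium_pts": 4,
            "sij_sacrum_pts": 10,
            "sij_ilium_pts": 10,
            "st_origin_s3": 1,
            "st_origin_c1": 1,
            "st_insertion_tuber": 1,
        }
        for name, n in expected.items():
            cls = getattr(self, name)
            for side in SIDES:
                arr = np.asarray(cls[side], dtype=float)
                if arr.shape != (n, 3):
                    raise ValueError(
                        f"{name}[{side}] must have shape ({n}, 3), got {arr.shape}"
                    )
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"{name}[{side}] contains non-finite values")
                cls[side] = arr
        for name in ("load_point", "sacrocaudal_sacrum", "sacrocaudal_c1"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if not (self.sacrocaudal_area > 0 and self.sacrocaudal_thickness > 0):
            raise ValueError("joint area and thickness must be positive")

    # -- iteration / serialization ---------------------------------------

    def iter_point_arrays(self):
        """Yield (class_name, side_or_None, (n,3)-or-(3,) array) in fixed order."""
        for name in _PER_SIDE_CLASSES:
            cls = getattr(self, name)
            for side in SIDES:
                yield name, side, cls[side]
        for name in ("load_point", "sacrocaudal_sacrum", "sacrocaudal_c1"):
            yield name, None, getattr(self, name)

    def named_points(self) -> dict[str, np.ndarray]:
        """Flat name -> (3,) map, e.g. 'sij_sacrum_pts/R/3'."""
        out: dict[str, np.ndarray] = {}
        for name, side, arr in self.iter_point_arrays():
            if side is None:
                out[name] = arr
            else:
                for i, p in enumerate(np.atleast_2d(arr)):
                    out[f"{name}/{side}/{i}"] = p
        return out

    def all_points(self) -> np.ndarray:
        return np.vstack(list(self.named_points().values()))

    def copy(self) -> "PelvisLandmarks":
        kw = {}
        for name in _PER_SIDE_CLASSES:
            kw[name] = {s: getattr(self, name)[s].copy() for s in SIDES}
        for name in ("load_point", "sacrocaudal_sacrum", "sacrocaudal_c1"):
            kw[name] = getattr(self, name).copy()
        return PelvisLandmarks(
            **kw,
            sacrocaudal_area=self.sacrocaudal_area,
            sacrocaudal_thickness=self.sacrocaudal_thickness,
            scale_factor=self.scale_factor,
        )

    def to_dict(self) -> dict:
        d: dict = {"sacrocaudal_area": self.sacrocaudal_area,
                   "sacrocaudal_thickness": self.sacrocaudal_thickness,
                   "scale_factor": self.scale_factor}
        for name in _PER_SIDE_CLASSES:
            d[name] = {s: getattr(self, name)[s].tolist() for s in SIDES}
        for name in ("load_point", "sacrocaudal_sacrum", "sacrocaudal_c1"):
            d[name] = getattr(self, name).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PelvisLandmarks":
        kw = {}
        for name in _PER_SIDE_CLASSES:
            kw[name] = {s: np.asarray(d[name][s], dtype=float) for s in SIDES}
        for name in ("load_point", "sacrocaudal_sacrum", "sacrocaudal_c1"):
            kw[name] = np.asarray(d[name], dtype=float)
        return cls(
            **kw,
            sacrocaudal_area=float(d["sacrocaudal_area"]),
            sacrocaudal_thickness=float(d["sacrocaudal_thickness"]),
            scale_factor=float(d.get("scale_factor", 1.0)),
        )

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path) -> "PelvisLandmarks":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_canonical_pelvis(body_mass: float = 25.0, scale: float = 1.0) -> PelvisLandmarks:
    """Build the canonical mirror-symmetric Labrador-scale landmark set.

    All linear dimensions scale by ``scale * (body_mass / 25)**(1/3)``
    (isometric scaling from the 25 kg reference); the joint interface area
    scales with the square of that factor.
    """
    if not body_mass > 0:
        raise ValueError(f"body mass must be positive, got {body_mass}")
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    f = float(scale) * float(body_mass / _CANON_REFERENCE_MASS) ** (1.0 / 3.0)
    kw = {}
    for name in _PER_SIDE_CLASSES:
        right = np.asarray(_CANON_RIGHT[name], dtype=float) * f
        kw[name] = {"R": right, "L": _mirror(right)}
    for name, p in _CANON_MIDLINE.items():
        kw[name] = np.asarray(p, dtype=float) * f
    return PelvisLandmarks(
        **kw,
        sacrocaudal_area=_CANON_JOINT_AREA * f**2,
        sacrocaudal_thickness=_CANON_JOINT_THICKNESS * f,
        scale_factor=f,
    )


# --------------------------------------------------------------------------
# Operator placement noise
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatorNoiseModel:
    """Isotropic Gaussian placement noise applied to landmark classes.

    ``sd`` is the per-axis standard deviation in mm.  The default target set
    is every ligament-spring attachment class; supports, the load point and
    joint interfaces are left untouched.  The same seed always reproduces
    the same perturbation.
    """

    sd: float = 0.25
    seed: int = 0
    targets: tuple[str, ...] = SPRING_ATTACHMENT_CLASSES

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"noise sd must be non-negative, got {self.sd}")
        unknown = set(self.targets) - set(SPRING_ATTACHMENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown landmark classes: {sorted(unknown)}")


def perturb_landmarks(lm: PelvisLandmarks, noise: OperatorNoiseModel) -> PelvisLandmarks:
    """Displace targeted attachment points by i.i.d. N(0, sd^2) per axis."""
    out = lm.copy()
    if noise.sd == 0:
        return out
    rng = np.random.default_rng(noise.seed)
    # fixed iteration order (class declaration order, then L before R) makes
    # the perturbation a pure function of (landmarks, sd, seed)
    for name in SPRING_ATTACHMENT_CLASSES:
        if name not in noise.targets:
            continue
        cls = getattr(out, name)
        for side in SIDES:
            cls[side] = cls[side] + rng.normal(0.0, noise.sd, size=cls[side].shape)
    return out


# --------------------------------------------------------------------------
# CT-like phantom
# --------------------------------------------------------------------------

@dataclass
class SyntheticCT:
    """CT-like labelled volume with fiducial markers at every landmark.

    ``voxels`` is indexed [i, j, k] along (x, y, z); ``origin`` is the mm
    position of voxel (0, 0, 0)'s centre.  ``fiducials`` maps flat landmark
    names to voxel indices; each fiducial voxel carries a unique intensity
    ``FIDUCIAL_BASE_INTENSITY + id``.  ``bones`` records the generating
    ellipsoids (centre, semi-axes, analytic volume) for round-trip checks.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray
    n_slices: int
    fiducials: dict[str, tuple[int, int, int]]
    fiducial_ids: dict[str, int]
    bones: dict[str, dict]

    def voxel_to_mm(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def mm_to_voxel(self, p) -> tuple[int, int, int]:
        rel = (np.asarray(p, dtype=float) - self.origin) / np.asarray(self.spacing)
        return tuple(int(round(v)) for v in rel)


def _ellipsoid_mask(shape, spacing, origin, center, semi):
    idx = np.indices(shape, dtype=float)
    coords = [origin[d] + idx[d] * spacing[d] for d in range(3)]
    q = sum(((coords[d] - center[d]) / semi[d]) ** 2 for d in range(3))
    return q <= 1.0


def render_ct(
    lm: PelvisLandmarks,
    spacing: tuple[float, float, float] = (1.0, 1.0, 0.625),
    n_slices: int = 226,
    margin: float = 8.0,
) -> SyntheticCT:
    """Render the landmark set into a CT-like voxel volume.

    Four ellipsoidal bone solids (sacrum, both hemipelves, first caudal
    vertebra) are drawn at ``BONE_INTENSITY`` over a zero background, and a
    single voxel at every landmark is overwritten with a unique fiducial
    intensity.  The number of transverse (z) slices is exactly ``n_slices``;
    in-plane extent is derived from the geometry plus ``margin``.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    f = lm.scale_factor
    bones = {
        name: (np.asarray(c, dtype=float) * f, np.asarray(a, dtype=float) * f)
        for name, (c, a) in _CANON_BONES.items()
    }
    pts = lm.all_points()
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    for center, semi in bones.values():
        lo = np.minimum(lo, center - semi)
        hi = np.maximum(hi, center + semi)
    lo -= margin
    hi += margin
    nx = int(np.ceil((hi[0] - lo[0]) / spacing[0])) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / spacing[1])) + 1
    nz = int(n_slices)
    z_extent = (nz - 1) * spacing[2]
    if z_extent < hi[2] - lo[2]:
        raise ValueError(
            f"{n_slices} slices at dz={spacing[2]} mm cover {z_extent:.1f} mm "
            f"but the geometry spans {hi[2] - lo[2]:.1f} mm"
        )
    # centre the geometry in the z stack
    origin = np.array(
        [lo[0], lo[1], lo[2] - 0.5 * (z_extent - (hi[2] - lo[2]))], dtype=float
    )
    shape = (nx, ny, nz)
    vol = np.zeros(shape, dtype=np.float32)
    bone_meta: dict[str, dict] = {}
    for name, (center, semi) in bones.items():
        mask = _ellipsoid_mask(shape, spacing, origin, center, semi)
        vol[mask] = BONE_INTENSITY
        bone_meta[name] = {
            "center": center,
            "semi_axes": semi,
            "analytic_volume": 4.0 / 3.0 * np.pi * float(np.prod(semi)),
        }

    fiducials: dict[str, tuple[int, int, int]] = {}
    fiducial_ids: dict[str, int] = {}
    for k, (name, p) in enumerate(sorted(lm.named_points().items())):
        idx = tuple(int(round(v)) for v in (p - origin) / np.asarray(spacing))
        if not all(0 <= idx[d] < shape[d] for d in range(3)):
            raise ValueError(f"landmark {name} at {p} is outside the field of view")
        vol[idx] = FIDUCIAL_BASE_INTENSITY + k
        fiducials[name] = idx
        fiducial_ids[name] = k
    return SyntheticCT(
        voxels=vol,
        spacing=spacing,
        origin=origin,
        n_slices=nz,
        fiducials=fiducials,
        fiducial_ids=fiducial_ids,
        bones=bone_meta,
    )


@dataclass
class SegmentationResult:
    """Thresholded, connected-component-labelled bone masks."""

    labels: np.ndarray
    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: np.ndarray

    def volume_mm3(self, bone: str) -> float:
        return float(self.masks[bone].sum()) * float(np.prod(self.spacing))


def threshold_segment(ct: SyntheticCT, threshold: float = NOMINAL_THRESHOLD) -> SegmentationResult:
    """Segment bones by thresholding and connected-component labelling.

    Fiducial-coded voxels are excluded from the bone mask (they carry
    synthetic marker intensities, not attenuation).  Each connected
    component is mapped to a bone name via the generating solid's centre;
    if one component contains several bone centres the threshold was too
    low and an ambiguity error naming the merged bones is raised.
    """
    vmin, vmax = float(ct.voxels.min()), float(ct.voxels.max())
    if not (vmin <= threshold <= vmax):
        raise ValueError(
            f"threshold {threshold} outside intensity range [{vmin}, {vmax}]"
        )
    mask = (ct.voxels >= threshold) & (ct.voxels < FIDUCIAL_BASE_INTENSITY)
    if not mask.any():
        raise ValueError(f"empty segmentation: no voxels at or above {threshold}")
    labels, _ = ndimage.label(mask)
    label_to_bones: dict[int, list[str]] = {}
    masks: dict[str, np.ndarray] = {}
    for name, meta in ct.bones.items():
        idx = ct.mm_to_voxel(meta["center"])
        lab = int(labels[idx])
        if lab == 0:
            raise ValueError(f"bone {name} not present at threshold {threshold}")
        label_to_bones.setdefault(lab, []).append(name)
        masks[name] = labels == lab
    merged = {lab: names for lab, names in label_to_bones.items() if len(names) > 1}
    if merged:
        desc = "; ".join(" + ".join(names) for names in merged.values())
        raise ValueError(f"threshold {threshold} merges bones: {desc}")
    return SegmentationResult(
        labels=labels, masks=masks, spacing=ct.spacing, origin=ct.origin.copy()
    )


def recover_fiducials(ct: SyntheticCT) -> dict[str, np.ndarray]:
    """Recover landmark mm positions from fiducial intensities in the volume.

    Reads the intensity-coded voxels back out of the image (not the stored
    index map), emulating marker-based landmark identification.
    """
    out: dict[str, np.ndarray] = {}
    for name, fid in ct.fiducial_ids.items():
        hits = np.argwhere(ct.voxels == FIDUCIAL_BASE_INTENSITY + fid)
        if len(hits) != 1:
            raise ValueError(f"fiducial for {name} not uniquely recoverable")
        out[name] = ct.voxel_to_mm(hits[0])
    return out


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------

def save_nifti(volume: np.ndarray, spacing, origin, path) -> None:
    """Write a volume (intensities or integer labels) as NIfTI with spacing."""
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = np.asarray(origin, dtype=float)
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def export_stl(mask: np.ndarray, spacing, origin, path) -> None:
    """Extract the iso-surface of a binary mask and write a binary STL."""
    import trimesh
    from skimage import measure

    verts, faces, _, _ = measure.marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=tuple(spacing)
    )
    verts = verts + np.asarray(origin, dtype=float)
    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(str(path))
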