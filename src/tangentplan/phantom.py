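"""Synthetic breast-phantom generation.

Builds voxelized patient models that stand in for a planning CT with
approved contours: a half-cylindrical thorax with a hemispherical breast
bulge, ellipsoidal lungs, a spherical heart, a smaller contralateral
breast bulge, and the anterior midline "tattoo" setup point.  Shapes are
analytic so beam's-eye-view projections have closed forms usable as test
oracles.

Grid frame is LPS-like: x toward the patient's left, y posterior,
z superior.  Anterior skin is therefore at *low* y.  Densities are
relative electron densities (air 0, lung ~0.25, soft tissue 1.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "PatientModel",
    "generate_phantom",
    "erode_to_planning_ptv",
    "downsample",
    "save_phantom",
    "load_phantom",
    "make_hotspot_patient",
]

STRUCTURE_NAMES = (
    "PTV_Breast",
    "PTV_planning",
    "Ipsilateral Lung",
    "Contralateral Lung",
    "Heart",
    "Contralateral Breast",
    "External",
)


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration cannot hold the requested anatomy."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic thorax/breast phantom.

    Lengths are in cm.  ``extents`` is the grid size in voxels as
    (nx, ny, nz); ``grid_spacing`` is the isotropic voxel edge
    (0.25 cm default; 0.5 cm for the coarse optimization grid).
    """

    grid_spacing: float = 0.25
    extents: tuple[int, int, int] = (96, 80, 48)
    laterality: str = "left"
    breast_radius: float = 5.0
    chest_radius: float = 8.5
    chest_depth: float = 9.0
    heart_offset: float = 2.8
    heart_radius: float = 3.4
    lung_scale: float = 1.0
    contra_breast_radius: float = 3.2
    skin_retraction: float = 0.5
    lung_density: float = 0.25
    tissue_density: float = 1.0
    seed: int = 1
    jitter: float = 0.04

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise PhantomConfigError("grid_spacing must be positive")
        if any(int(n) < 20 for n in self.extents):
            raise PhantomConfigError("extents must be >= 20 voxels per axis")
        if self.skin_retraction < 0:
            raise PhantomConfigError("skin_retraction must be >= 0")
        if self.laterality not in ("left", "right"):
            raise PhantomConfigError(f"unknown laterality {self.laterality!r}")


@dataclass
class PatientModel:
    """Voxelized patient: density grid, structure masks, tattoo, laterality."""

    density: np.ndarray
    structures: dict[str, np.ndarray]
    tattoo: np.ndarray  # (x, y, z) cm, on the anterior midline skin
    laterality: str
    spacing: float
    origin: np.ndarray  # world position (cm) of voxel index (0, 0, 0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.structures[name]
        except KeyError:
            raise KeyError(f"structure {name!r} not present in patient model") from None

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (N, 3) of voxel centers, optionally masked."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (inverse of voxel_centers)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing - 0.5


def _axis_coords(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = cfg.extents
    sp = cfg.grid_spacing
    # Grid centred on x=0 (midline) and z=0; y chosen so the anterior body
    # surface sits comfortably inside the grid.
    origin = np.array(
        [-nx * sp / 2.0, -ny * sp * 0.66, -nz * sp / 2.0]
    )
    xs = origin[0] + (np.arange(nx) + 0.5) * sp
    ys = origin[1] + (np.arange(ny) + 0.5) * sp
    zs = origin[2] + (np.arange(nz) + 0.5) * sp
    return xs, ys, zs, origin


def generate_phantom(config: PhantomConfig | None = None, **overrides) -> PatientModel:
    """Generate a deterministic, seeded breast phantom.

    The same config (including seed) always yields bit-identical masks.
    The seed perturbs the organ geometry by a few percent so seed sweeps
    exercise distinct but anatomically similar patients.
    """
    cfg = config or PhantomConfig()
    if overrides:
        cfg = replace(cfg, **overrides)

    rng = np.random.default_rng(cfg.seed)
    jit = lambda: 1.0 + cfg.jitter * float(rng.uniform(-1.0, 1.0))  # noqa: E731

    r_chest = cfg.chest_radius * jit()
    r_breast = cfg.breast_radius * jit()
    r_heart = cfg.heart_radius * jit()
    r_contra = cfg.contra_breast_radius * jit()
    lung_ax = cfg.lung_scale * jit()

    xs, ys, zs, origin = _axis_coords(cfg)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    sp = cfg.grid_spacing

    side = 1.0 if cfg.laterality == "left" else -1.0  # ipsilateral x sign

    # Thorax: elliptical cylinder along z, flattened posteriorly.
    cyl_center_y = 0.0
    chest = (X / (1.15 * r_chest)) ** 2 + ((Y - cyl_center_y) / r_chest) ** 2 <= 1.0
    chest &= Y <= r_chest * 0.75  # posterior flat couch cut

    # Ipsilateral breast bulge: sphere centred on the anterior chest surface.
    ang = np.deg2rad(30.0)
    bc = np.array([side * 1.15 * r_chest * np.sin(ang), -r_chest * np.cos(ang), 0.0])
    breast = (X - bc[0]) ** 2 + (Y - bc[1]) ** 2 + (Z - bc[2]) ** 2 <= r_breast**2

    # Contralateral breast bulge (smaller).
    cc = np.array([-side * 1.15 * r_chest * np.sin(ang), -r_chest * np.cos(ang), 0.0])
    contra = (X - cc[0]) ** 2 + (Y - cc[1]) ** 2 + (Z - cc[2]) ** 2 <= r_contra**2

    external = chest | breast | contra

    # Lungs: ellipsoids inside the chest; the ipsilateral anterior face
    # sits close enough to the chest wall that tangent fields include a
    # small sliver, as they do clinically.
    lung_semi = np.array([3.3, 4.4, 7.5]) * lung_ax
    lung_cx = 1.15 * r_chest * 0.42
    lung_cy = 0.3
    lung_l = (
        ((X - lung_cx) / lung_semi[0]) ** 2
        + ((Y - lung_cy) / lung_semi[1]) ** 2
        + (Z / lung_semi[2]) ** 2
        <= 1.0
    )
    lung_r = (
        ((X + lung_cx) / lung_semi[0]) ** 2
        + ((Y - lung_cy) / lung_semi[1]) ** 2
        + (Z / lung_semi[2]) ** 2
        <= 1.0
    )

    # Heart: sphere offset toward the patient's LEFT (+x) regardless of
    # laterality, anterior-inferior between the lungs.
    hc = np.array([cfg.heart_offset, 0.4, -1.2])
    heart = (X - hc[0]) ** 2 + (Y - hc[1]) ** 2 + (Z - hc[2]) ** 2 <= r_heart**2

    lung_l &= external & ~heart
    lung_r &= external & ~heart
    heart &= external

    ipsi_lung = lung_l if cfg.laterality == "left" else lung_r
    contra_lung = lung_r if cfg.laterality == "left" else lung_l

    # Breast tissue sits on the pectoral muscle: bound the PTV posteriorly by
    # a shrunken copy of the chest ellipse so it cannot wrap onto lung/heart.
    chest_core = (X / (1.15 * r_chest * 0.82)) ** 2 + (
        (Y - cyl_center_y) / (r_chest * 0.82)
    ) ** 2 <= 1.0
    # The PTV stops at the sternal edge: a field edge pinned on the midline
    # tattoo can then clear it with a finite margin.
    sternal_gap = 1.5
    ptv = breast & external & ~chest_core & ~(lung_l | lung_r | heart)
    ptv &= side * X >= sternal_gap
    contra_breast = contra & external & ~chest_core & ~(lung_l | lung_r | heart) & ~ptv

    if not ptv.any() or not ipsi_lung.any() or not heart.any():
        raise PhantomConfigError(
            "extents too small: an organ fell entirely outside the grid"
        )
    # Organs must not be clipped by the grid boundary.  The thorax cylinder
    # legitimately runs through the superior/inferior faces (a CT section
    # does too), so External is only checked on the x/y faces; the PTV must
    # be fully contained.
    edge_xy = np.zeros_like(external)
    edge_xy[[0, -1], :, :] = True
    edge_xy[:, [0, -1], :] = True
    if (external & edge_xy).any():
        raise PhantomConfigError("extents too small: External touches the grid edge")
    edge_all = edge_xy.copy()
    edge_all[:, :, [0, -1]] = True
    if (ptv & edge_all).any():
        raise PhantomConfigError("extents too small: PTV touches the grid edge")

    ptv_planning = erode_to_planning_ptv(ptv, external, cfg.skin_retraction, spacing=sp)

    density = np.zeros(cfg.extents, dtype=np.float64)
    density[external] = cfg.tissue_density
    density[lung_l | lung_r] = cfg.lung_density

    # Tattoo: most anterior midline External voxel on the PTV mid-plane slice.
    kz = int(round(np.mean(np.argwhere(ptv)[:, 2])))
    ix_mid = int(np.argmin(np.abs(xs)))
    col = external[ix_mid, :, kz]
    if not col.any():
        raise PhantomConfigError("no External tissue on the midline at PTV mid-plane")
    iy = int(np.argmax(col))  # first True along +y = most anterior
    tattoo = np.array([xs[ix_mid], ys[iy], zs[kz]])

    structures = {
        "PTV_Breast": ptv,
        "PTV_planning": ptv_planning,
        "Ipsilateral Lung": ipsi_lung,
        "Contralateral Lung": contra_lung,
        "Heart": heart,
        "Contralateral Breast": contra_breast,
        "External": external,
    }
    return PatientModel(
        density=density,
        structures=structures,
        tattoo=tattoo,
        laterality=cfg.laterality,
        spacing=sp,
        origin=origin,
    )


def erode_to_planning_ptv(
    ptv_mask: np.ndarray,
    external: np.ndarray,
    retraction: float,
    *,
    spacing: float = 0.25,
) -> np.ndarray:
    """Retract a PTV away from the skin by ``retraction`` cm.

    Removes every PTV voxel whose Euclidean distance to the nearest
    non-External voxel is below the retraction (0.5 cm clinically, to keep
    the optimizer away from the build-up region at the surface).
    """
    if retraction < 0:
        raise ValueError("retraction must be >= 0")
    if (ptv_mask & ~external).any():
        raise ValueError("PTV mask must be a subset of the External mask")
    if retraction == 0:
        return ptv_mask.copy()
    dist = ndimage.distance_transform_edt(external, sampling=spacing)
    out = ptv_mask & (dist >= retraction)
    if ptv_mask.any() and not out.any():
        warnings.warn(
            "skin retraction removed the entire PTV (retraction exceeds "
            "structure thickness)",
            stacklevel=2,
        )
    return out


def downsample(patient: PatientModel, factor: int = 2) -> PatientModel:
    """Block-average the patient onto a coarser grid (for optimization).

    Density is block-averaged; masks take block majority and are then
    re-intersected so the subset invariants survive the resampling.
    """
    nx, ny, nz = patient.shape
    f = int(factor)
    cx, cy, cz = nx // f, ny // f, nz // f

    def blocks(a: np.ndarray) -> np.ndarray:
        a = a[: cx * f, : cy * f, : cz * f]
        return a.reshape(cx, f, cy, f, cz, f).astype(float).mean(axis=(1, 3, 5))

    density = blocks(patient.density)
    structures = {n: blocks(m) >= 0.5 for n, m in patient.structures.items()}
    ext = structures["External"]
    for n in structures:
        if n != "External":
            structures[n] &= ext
    structures["PTV_planning"] &= structures["PTV_Breast"]
    for n in ("Ipsilateral Lung", "Contralateral Lung", "Heart"):
        structures[n] &= ~structures["PTV_Breast"]
    return PatientModel(
        density=density,
        structures=structures,
        tattoo=patient.tattoo.copy(),
        laterality=patient.laterality,
        spacing=patient.spacing * f,
        origin=patient.origin.copy(),
    )


def make_hotspot_patient(seed: int = 1) -> PatientModel:
    """A contrived patient whose open-field weighting must hit the max cap.

    Starts from a seeded phantom and replaces the planning PTV by a thin
    posterior sliver of the breast hugging the chest wall.  The sliver sits
    in the posterior penumbra of the tangent fields, so driving its *mean*
    dose to 85% of prescription pushes the dose elsewhere in the body far
    above 95%, exercising the open-weighting cap branch.  Synthetic by
    design; not an anatomic scenario.
    """
    patient = generate_phantom(PhantomConfig(seed=seed))
    ptv = patient.structures["PTV_Breast"]
    ext = patient.structures["External"]
    dist_skin = ndimage.distance_transform_edt(ext, sampling=patient.spacing)
    deep = ptv & (dist_skin >= np.percentile(dist_skin[ptv], 86.0))
    if not deep.any():  # pragma: no cover - defensive
        deep = patient.structures["PTV_planning"]
    patient.structures["PTV_planning"] = deep
    return patient


# ---------------------------------------------------------------------------
# HDF5 container

def save_phantom(patient: PatientModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("density", data=patient.density, compression="gzip")
        g = f.create_group("structures")
        for name, mask in patient.structures.items():
            g.create_dataset(name, data=mask.astype(np.uint8), compression="gzip")
        f.attrs["spacing"] = patient.spacing
        f.attrs["origin"] = patient.origin
        f.attrs["laterality"] = patient.laterality
        f.attrs["tattoo"] = patient.tattoo


def load_phantom(path) -> PatientModel:
    with h5py.File(path, "r") as f:
        density = f["density"][...]
        structures = {n: f["structures"][n][...].astype(bool) for n in f["structures"]}
        return PatientModel(
            density=density,
            structures=structures,
            tattoo=np.asarray(f.attrs["tattoo"], dtype=float),
            laterality=str(f.attrs["laterality"]),
            spacing=float(f.attrs["spacing"]),
            origin=np.asarray(f.attrs["origin"], dtype=float),
        )
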