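"""Tangent-field construction for whole-breast planning.

Builds the opposed tangential beam pair from a voxel patient model: the
posterior field-edge line is found by rotating a line about the midline
tattoo until the planning target (plus margin) is covered with the least
body tissue inside the field; the medial and posterior border points are
its intersections with the skin at the PTV mid-plane; gantry angles,
isocenter and energy selection follow the clinical border-point rules.

Border coordinates are reported in a planning frame with the lateral
axis positive toward the *ipsilateral* side and the anterior-posterior
axis positive posterior.  In that frame a single arctangent formula pair
(with the laterality switch ``360 - theta``) reproduces the correct IEC
gantry angles for both left- and right-sided patients; a post-hoc check
in :func:`build_tangent_geometry` asserts the beam axis really runs from
the medial entry toward the posterior border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import PatientModel

__all__ = [
    "BorderPoints",
    "Beam",
    "TangentGeometry",
    "EnergyPolicy",
    "InfeasibleGeometryError",
    "DegenerateGeometryError",
    "optimize_tangent",
    "compute_borders",
    "medial_gantry_angle",
    "lateral_gantry_angle",
    "isocenter_position",
    "select_energies",
    "fit_conformal_apertures",
    "build_tangent_geometry",
]

SAD = 100.0  # source-axis distance, cm
MAX_FIELD = 40.0  # maximum jaw opening, cm
LEAF_WIDTH = 0.5  # MLC leaf width at isocenter, cm


class InfeasibleGeometryError(RuntimeError):
    """No tangent rotation covers the PTV plus margin."""


class DegenerateGeometryError(RuntimeError):
    """The field edge line does not cross the body in two points."""


@dataclass(frozen=True)
class BorderPoints:
    """Medial and posterior beam entry points on the mid-plane skin.

    Coordinates in cm: ``x`` lateral (positive toward the ipsilateral
    side), ``y`` anterior-posterior (positive posterior).  ``*_world``
    keep the untransformed grid-frame (x patient-left) points for
    mask-based checks.
    """

    x_m: float
    y_m: float
    x_p: float
    y_p: float
    medial_world: tuple[float, float] = (0.0, 0.0)
    posterior_world: tuple[float, float] = (0.0, 0.0)

    @property
    def separation(self) -> float:
        """Straight-line medial-posterior border distance (cm)."""
        return float(np.hypot(self.x_m - self.x_p, self.y_m - self.y_p))


@dataclass(frozen=True)
class EnergyPolicy:
    """Mixed-energy rule: beyond the separation threshold the open pair is
    duplicated and split equally between the low and high energy."""

    separation_threshold: float = 25.0
    low_energy: float = 6.0
    high_energy: float = 18.0

    def __post_init__(self) -> None:
        if self.separation_threshold <= 0:
            raise ValueError("separation threshold must be positive")


@dataclass
class Beam:
    """One treatment beam: geometric frame plus aperture.

    ``source``: world position of the point source (cm).
    ``axis``: unit vector, source toward isocenter (in the axial plane).
    ``anterior``: unit vector normal to the axis in the axial plane,
    pointing to the open (anterior) side of the nondivergent edge.
    Aperture: per-leaf-row anterior tip positions ``leaf_tips`` (cm, in
    the isocenter plane, measured along ``anterior`` from the posterior
    edge at 0) for rows with edges ``leaf_edges_z`` along z.
    """

    beam_id: str
    source: np.ndarray
    axis: np.ndarray
    anterior: np.ndarray
    isocenter: np.ndarray
    energy: float
    gantry_angle: float
    leaf_edges_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    leaf_tips: np.ndarray = field(default_factory=lambda: np.zeros(0))
    weight: float = 1.0

    @property
    def jaws(self) -> dict[str, float]:
        """Jaw positions (cm at isocenter): posterior fixed at 0.0."""
        open_rows = self.leaf_tips > 0
        if not open_rows.any():
            return {"posterior": 0.0, "anterior": 0.0, "z_inf": 0.0, "z_sup": 0.0}
        z_lo = float(self.leaf_edges_z[:-1][open_rows].min())
        z_hi = float(self.leaf_edges_z[1:][open_rows].max())
        return {
            "posterior": 0.0,
            "anterior": float(self.leaf_tips.max()),
            "z_inf": z_lo,
            "z_sup": z_hi,
        }


@dataclass
class TangentGeometry:
    """The full tangential field setup for one patient."""

    theta_medial: float
    theta_lateral: float
    collimator: float
    isocenter: np.ndarray
    borders: BorderPoints
    energies: list[float]
    beams: list[Beam]
    edge_point: np.ndarray  # a point on the posterior edge line (tattoo)
    edge_dir: np.ndarray  # unit direction of the edge line (medial->posterior)
    anterior_normal: np.ndarray  # unit normal pointing to the field side

    def to_dict(self) -> dict:
        return {
            "theta_medial_deg": self.theta_medial,
            "theta_lateral_deg": self.theta_lateral,
            "collimator_deg": self.collimator,
            "isocenter_cm": [round(float(v), 4) for v in self.isocenter],
            "borders_cm": {
                "medial": [self.borders.x_m, self.borders.y_m],
                "posterior": [self.borders.x_p, self.borders.y_p],
            },
            "separation_cm": round(self.borders.separation, 3),
            "energies_MV": list(self.energies),
            "beams": [
                {
                    "id": b.beam_id,
                    "energy_MV": b.energy,
                    "gantry_deg": b.gantry_angle,
                    "weight": b.weight,
                    "jaws_cm": b.jaws,
                    "leaf_tips_cm": [round(float(t), 3) for t in b.leaf_tips],
                }
                for b in self.beams
            ],
        }


# ---------------------------------------------------------------------------
# tangent-line search


def _midplane_slice(patient: PatientModel) -> int:
    ptv = patient.mask("PTV_Breast")
    return int(round(np.mean(np.argwhere(ptv)[:, 2])))


def optimize_tangent(
    patient: PatientModel,
    margin: float = 1.0,
    *,
    step_deg: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Find the posterior field-edge line through the midline tattoo.

    Scans line rotations about the tattoo in ``step_deg`` increments.
    A candidate is feasible when every PTV voxel (projected to the axial
    plane) lies at least ``margin`` cm on the anterior side of the line;
    near the pivot the requirement tapers linearly to zero (inside 2 cm
    of the tattoo mere coverage is required, the full margin applies from
    6 cm out), since a line pinned on the skin entry point cannot clear
    adjacent target voxels by a finite margin.  Among feasible candidates
    the one including the least External area on the PTV mid-plane is
    returned.

    Returns ``(direction, normal)``: unit vectors of the edge line and of
    its anterior (field-side) normal, in the axial plane.

    Raises
    ------
    InfeasibleGeometryError
        if no rotation covers the PTV plus margin.
    """
    ptv = patient.mask("PTV_planning")
    if not ptv.any():
        ptv = patient.mask("PTV_Breast")
    if not ptv.any() or not patient.mask("External").any():
        raise InfeasibleGeometryError("empty PTV or External")

    t_xy = patient.tattoo[:2]
    ptv_xy = np.unique(np.argwhere(ptv)[:, :2], axis=0)
    ptv_pts = patient.origin[:2] + (ptv_xy + 0.5) * patient.spacing - t_xy

    kz = _midplane_slice(patient)
    ext_xy = np.argwhere(patient.mask("External")[:, :, kz])
    ext_pts = patient.origin[:2] + (ext_xy + 0.5) * patient.spacing - t_xy

    phis = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    normals = np.stack([np.cos(phis), np.sin(phis)], axis=1)  # (K, 2)

    lever = np.linalg.norm(ptv_pts, axis=1)
    req = margin * np.clip((lever - 2.0) / 4.0, 0.0, 1.0)  # tapered margin
    d_ptv = ptv_pts @ normals.T  # (Nptv, K) signed distances
    feasible = (d_ptv >= req[:, None]).all(axis=0)
    if not feasible.any():
        raise InfeasibleGeometryError(
            f"no tangent through the tattoo covers the PTV plus {margin} cm margin"
        )
    d_ext = ext_pts @ normals.T
    area = (d_ext[:, feasible] >= 0.0).sum(axis=0)
    k_best = np.flatnonzero(feasible)[int(np.argmin(area))]

    n = normals[k_best]
    d = np.array([-n[1], n[0]])
    return d, n


def compute_borders(
    patient: PatientModel,
    edge_dir: np.ndarray,
    anterior_normal: np.ndarray | None = None,
) -> BorderPoints:
    """Intersect the posterior edge line with the skin at the PTV mid-plane.

    The line runs through the tattoo along ``edge_dir``.  The body must be
    crossed in a single chord; its two endpoints are the borders, the one
    nearer the tattoo being medial.
    """
    kz = _midplane_slice(patient)
    ext = patient.mask("External")[:, :, kz]
    t_xy = patient.tattoo[:2]
    d = np.asarray(edge_dir, dtype=float)
    d = d / np.linalg.norm(d)

    half = float(np.hypot(*(patient.spacing * np.array(ext.shape))))
    ts = np.arange(-half, half, patient.spacing / 4.0)
    pts = t_xy[None, :] + ts[:, None] * d[None, :]
    idx = (pts - patient.origin[None, :2]) / patient.spacing - 0.5
    inside = (
        ndimage.map_coordinates(
            ext.astype(np.float32), idx.T, order=0, mode="constant", cval=0.0
        )
        > 0.5
    )
    if not inside.any():
        raise DegenerateGeometryError("edge line misses the body")
    t_in = ts[inside]
    t0, t1 = float(t_in.min()), float(t_in.max())
    if t1 - t0 < 2.0 * patient.spacing:
        raise DegenerateGeometryError("edge line only grazes the body")

    p0 = t_xy + t0 * d
    p1 = t_xy + t1 * d
    # medial point = the one nearer the tattoo
    if np.linalg.norm(p0 - t_xy) <= np.linalg.norm(p1 - t_xy):
        medial, posterior = p0, p1
    else:
        medial, posterior = p1, p0

    # Report in the planning frame: lateral axis positive toward the
    # ipsilateral side (grid +x is patient-left), y posterior as in the grid.
    s = 1.0 if patient.laterality == "left" else -1.0
    return BorderPoints(
        x_m=float(s * medial[0]),
        y_m=float(medial[1]),
        x_p=float(s * posterior[0]),
        y_p=float(posterior[1]),
        medial_world=(float(medial[0]), float(medial[1])),
        posterior_world=(float(posterior[0]), float(posterior[1])),
    )


# ---------------------------------------------------------------------------
# border-point formulas


def medial_gantry_angle(borders: BorderPoints, laterality: str) -> int:
    """Medial tangent gantry angle (degrees, nearest integer).

    Right-sided: ``theta = atan((x_m - x_p) / (y_m - y_p))``; left-sided:
    ``360 - atan(...)``; normalized to [0, 360) and rounded half-to-even
    to the nearest full degree.
    """
    dy = borders.y_m - borders.y_p
    if dy == 0:
        raise ValueError("undefined gantry angle: y_m equals y_p")
    theta = np.degrees(np.arctan((borders.x_m - borders.x_p) / dy))
    if laterality == "left":
        theta = 360.0 - theta
    theta %= 360.0
    return int(np.round(theta)) % 360


def lateral_gantry_angle(theta_medial: float) -> float:
    """Opposing gantry angle, giving the closed-jaw nondivergent edge."""
    if not 0 <= theta_medial < 360:
        raise ValueError("gantry angle must be in [0, 360)")
    return (theta_medial + 180.0) % 360.0


def isocenter_position(
    borders: BorderPoints,
    laterality: str,
    tattoo_xy: np.ndarray | tuple[float, float],
    *,
    max_halfwidth: float = 10.0,
) -> np.ndarray:
    """Isocenter on the posterior edge line (planning-frame cm).

    Mid-separation of the borders when they are less than ``2*max_halfwidth``
    apart in the lateral coordinate; for wider fields, a 10 cm step from the
    medial border toward the posterior border along the border line.  The
    result is then snapped so that its displacement from the tattoo *along*
    the edge line is a whole number of cm (round half-to-even), leaving the
    cross-line component exact.
    """
    dx = borders.x_m - borders.x_p
    dy = borders.y_m - borders.y_p
    if abs(dx) < max_halfwidth:
        iso = np.array(
            [(borders.x_m + borders.x_p) / 2.0, (borders.y_m + borders.y_p) / 2.0]
        )
    else:
        step = max_halfwidth * np.sign(borders.x_p - borders.x_m)
        slope = dy / dx  # == (y_p - y_m) / (x_p - x_m)
        iso = np.array([borders.x_m + step, borders.y_m + step * slope])

    t_xy = np.asarray(tattoo_xy, dtype=float)
    d = np.array([borders.x_p - borders.x_m, borders.y_p - borders.y_m])
    d = d / np.linalg.norm(d)
    n = np.array([-d[1], d[0]])
    disp = iso - t_xy
    along = float(disp @ d)
    across = float(disp @ n)
    along_snapped = float(np.round(along))  # 1 cm lattice, banker's rounding
    return t_xy + along_snapped * d + across * n


def select_energies(borders: BorderPoints, policy: EnergyPolicy | None = None) -> list[float]:
    """Energy list for the open beams: [low, low] or, when the border
    separation strictly exceeds the threshold, [low, high, low, high]
    (the pair is duplicated and split between the two energies)."""
    policy = policy or EnergyPolicy()
    if borders.separation > policy.separation_threshold:
        return [
            policy.low_energy,
            policy.high_energy,
            policy.low_energy,
            policy.high_energy,
        ]
    return [policy.low_energy, policy.low_energy]


# ---------------------------------------------------------------------------
# conformal apertures


def _bev_coords(points: np.ndarray, source: np.ndarray, axis: np.ndarray, anterior: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project world points through the source onto the isocenter plane.

    Returns (u, v): u along ``anterior``, v along z, both in cm at
    isocenter (magnification SAD / depth-along-axis).
    """
    rel = points - source[None, :]
    a = rel @ axis
    u = (rel @ anterior) * SAD / a
    v = rel[:, 2] * SAD / a
    return u, v


def fit_conformal_apertures(
    patient: PatientModel,
    geom: "TangentGeometry",
    margin: float = 0.7,
    flash: float = 2.0,
    *,
    target: str = "PTV_Breast",
) -> None:
    """Fit per-leaf apertures to the BEV target projection, in place.

    Each leaf row's anterior tip encloses the projected target plus
    ``margin`` (applied isotropically in 3D before projection) and is
    extended ``flash`` cm beyond the projected skin within the target's
    leaf-row span.  The posterior jaw stays at 0 (nondivergent edge).
    Both open beams receive the same aperture, expressed in the shared
    edge-plane frame.  ``flash=0`` fits the target projection exactly.
    """
    ptv = patient.mask(target)
    if margin > 0:
        r = int(np.ceil(margin / patient.spacing))
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = (xx**2 + yy**2 + zz**2) * patient.spacing**2 <= margin**2 + 1e-9
        ptv = ndimage.binary_dilation(ptv, structure=ball)
    ptv_pts = patient.voxel_centers(ptv)
    ext_pts = patient.voxel_centers(patient.mask("External"))

    ref = geom.beams[0]
    u_t, v_t = _bev_coords(ptv_pts, ref.source, ref.axis, ref.anterior)
    u_e, v_e = _bev_coords(ext_pts, ref.source, ref.axis, ref.anterior)

    if u_t.max() - 0.0 > MAX_FIELD or v_t.max() - v_t.min() > MAX_FIELD:
        raise ValueError("target projection exceeds the maximum 40x40 cm field")

    z_lo = np.floor(v_t.min() / LEAF_WIDTH) * LEAF_WIDTH
    z_hi = np.ceil(v_t.max() / LEAF_WIDTH) * LEAF_WIDTH
    edges = np.arange(z_lo, z_hi + LEAF_WIDTH / 2, LEAF_WIDTH)
    tips = np.zeros(len(edges) - 1)
    for i in range(len(tips)):
        sel = (v_t >= edges[i]) & (v_t < edges[i + 1])
        if not sel.any():
            continue
        tip = float(u_t[sel].max())
        if flash > 0:
            sel_e = (v_e >= edges[i]) & (v_e < edges[i + 1])
            if sel_e.any():
                tip = max(tip, float(u_e[sel_e].max()) + flash)
        tips[i] = min(tip, MAX_FIELD)

    for beam in geom.beams:
        beam.leaf_edges_z = edges.copy()
        beam.leaf_tips = tips.copy()


# ---------------------------------------------------------------------------
# assembly


def build_tangent_geometry(
    patient: PatientModel,
    *,
    tangent_margin: float = 1.0,
    aperture_margin: float = 0.7,
    flash: float = 2.0,
    energy_policy: EnergyPolicy | None = None,
) -> TangentGeometry:
    """Run the full geometric setup: tangent line, borders, angles,
    isocenter, energies and conformal open apertures."""
    energy_policy = energy_policy or EnergyPolicy()
    d, n = optimize_tangent(patient, tangent_margin)
    borders = compute_borders(patient, d, n)

    theta_m = medial_gantry_angle(borders, patient.laterality)
    theta_l = lateral_gantry_angle(theta_m)

    iso_plan = isocenter_position(borders, patient.laterality, _tattoo_planning_xy(patient))
    s = 1.0 if patient.laterality == "left" else -1.0
    kz = _midplane_slice(patient)
    z_iso = patient.origin[2] + (kz + 0.5) * patient.spacing
    iso_world = np.array([s * iso_plan[0], iso_plan[1], z_iso])

    energies = select_energies(borders, energy_policy)

    med_w = np.array(borders.medial_world)
    post_w = np.array(borders.posterior_world)
    d_world = np.append((post_w - med_w) / np.linalg.norm(post_w - med_w), 0.0)
    n_world = np.append(n, 0.0)
    # Post-hoc sign validation: the IEC source direction implied by the
    # reported medial gantry angle (gantry 0 anterior, 90 patient-left)
    # must coincide with the geometric source side, i.e. the beam axis
    # runs from the medial entry toward the posterior border.  Catches
    # sign-convention errors on either laterality.
    iec_src = np.array([np.sin(np.radians(theta_m)), -np.cos(np.radians(theta_m))])
    if iec_src @ (-d_world[:2]) < np.cos(np.radians(2.0)):
        raise AssertionError(
            "gantry-angle convention mismatch: beam axis does not run from "
            "the medial entry toward the posterior border"
        )

    beams: list[Beam] = []
    n_pairs = len(energies) // 2
    if n_pairs == 1:
        combos = [("medial", d_world, energies[0]), ("lateral", -d_world, energies[1])]
    else:
        combos = [
            ("medial", d_world, energies[0]),
            ("medial", d_world, energies[1]),
            ("lateral", -d_world, energies[2]),
            ("lateral", -d_world, energies[3]),
        ]
    for name, ax, e in combos:
        theta = theta_m if name == "medial" else theta_l
        beams.append(
            Beam(
                beam_id=f"open_{name}_{e:g}MV",
                source=iso_world - SAD * ax,
                axis=ax,
                anterior=n_world,
                isocenter=iso_world,
                energy=e,
                gantry_angle=float(theta),
            )
        )

    geom = TangentGeometry(
        theta_medial=float(theta_m),
        theta_lateral=float(theta_l),
        collimator=0.0,
        isocenter=iso_world,
        borders=borders,
        energies=energies,
        beams=beams,
        edge_point=np.append(patient.tattoo[:2], z_iso),
        edge_dir=d_world,
        anterior_normal=n_world,
    )
    fit_conformal_apertures(patient, geom, aperture_margin, flash)
    return geom


def _tattoo_planning_xy(patient: PatientModel) -> np.ndarray:
    s = 1.0 if patient.laterality == "left" else -1.0
    return np.array([s * patient.tattoo[0], patient.tattoo[1]])


def make_imrt_beams(geom: TangentGeometry) -> list[Beam]:
    """Modulated tuning beams: identical gantry/collimator geometry to the
    open pair (low energy only), with the aperture fitted to the target
    without anterior flash (the open beams carry the flash)."""
    out = []
    seen = set()
    for b in geom.beams:
        key = (round(b.gantry_angle, 3),)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            Beam(
                beam_id=f"imrt_{'medial' if b.gantry_angle == geom.theta_medial else 'lateral'}",
                source=b.source.copy(),
                axis=b.axis.copy(),
                anterior=b.anterior.copy(),
                isocenter=b.isocenter.copy(),
                energy=min(geom.energies),
                gantry_angle=b.gantry_angle,
                leaf_edges_z=b.leaf_edges_z.copy(),
                leaf_tips=b.leaf_tips.copy(),
            )
        )
    return out
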