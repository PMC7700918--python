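"""Tangent geometry: border-point trigonometry, isocenter placement,
energy selection, tangent-line search and conformal apertures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tangentplan.geometry import (
    SAD,
    BorderPoints,
    DegenerateGeometryError,
    EnergyPolicy,
    InfeasibleGeometryError,
    build_tangent_geometry,
    compute_borders,
    fit_conformal_apertures,
    isocenter_position,
    lateral_gantry_angle,
    medial_gantry_angle,
    optimize_tangent,
    select_energies,
)
from tangentplan.phantom import PatientModel


def borders(xm, ym, xp, yp):
    return BorderPoints(x_m=xm, y_m=ym, x_p=xp, y_p=yp,
                        medial_world=(xm, ym), posterior_world=(xp, yp))


# ---------------------------------------------------------------------------
# gantry angles


@pytest.mark.parametrize(
    "laterality, b, expected",
    [
        ("right", borders(10, 10, 0, 0), 45),    # atan(1) = 45
        ("left", borders(10, 10, 0, 0), 315),    # 360 - 45
        ("right", borders(5, 0, 5, 10), 0),      # x_m == x_p -> 0 after normalization
        ("left", borders(5, 0, 5, 10), 0),
    ],
)
def test_medial_gantry_angle_examples(laterality, b, expected):
    assert medial_gantry_angle(b, laterality) == expected


def test_medial_gantry_angle_undefined_when_y_equal():
    with pytest.raises(ValueError):
        medial_gantry_angle(borders(1, 5, 2, 5), "left")


@pytest.mark.parametrize("theta, expected", [(45, 225), (315, 135), (180, 0)])
def test_lateral_angle_opposes_medial(theta, expected):
    assert lateral_gantry_angle(theta) == expected


def test_lateral_angle_rejects_out_of_range():
    with pytest.raises(ValueError):
        lateral_gantry_angle(360.0)


@settings(max_examples=200, deadline=None)
@given(
    xm=st.floats(-15, 15), ym=st.floats(-15, 15),
    xp=st.floats(-15, 15), yp=st.floats(-15, 15),
)
def test_laterality_mirror_symmetry(xm, ym, xp, yp):
    """The left and right formulas on the same border coordinates are
    mirror images: their angles sum to 0 mod 360."""
    if abs(ym - yp) < 1e-6:
        return
    b = borders(xm, ym, xp, yp)
    s = medial_gantry_angle(b, "left") + medial_gantry_angle(b, "right")
    assert s % 360 == 0


# ---------------------------------------------------------------------------
# isocenter


def test_isocenter_midpoint_branch():
    b = borders(4, 0, -4, 6)
    iso = isocenter_position(b, "left", (4, 0))  # tattoo at the medial border
    # midpoint (0, 3); snapping moves it along the border line by < half cm
    d = np.array([-8, 6]) / 10.0
    disp = iso - np.array([4.0, 0.0])
    along = disp @ d
    assert abs(along - round(along)) < 1e-9
    across = disp @ np.array([-d[1], d[0]])
    mid_across = (np.array([0.0, 3.0]) - np.array([4.0, 0.0])) @ np.array([-d[1], d[0]])
    assert across == pytest.approx(mid_across)  # cross-line component exact
    assert np.linalg.norm(iso - np.array([0.0, 3.0])) <= 0.5 + 1e-9


def test_isocenter_wide_field_branch_is_collinear():
    b = borders(6, 0, -6, 12)
    iso = isocenter_position(b, "left", (6, 0))
    # 10 cm step from the medial border toward the posterior border:
    # x = 6 - 10 = -4, y = 0 + (-10) * slope(-1) = 10; on the border line
    slope = (0 - 12) / (6 - (-6))
    unsnapped = np.array([6 - 10.0, 0 + (-10.0) * slope])
    assert unsnapped[1] == pytest.approx(10.0)
    # collinearity with the borders
    v1 = unsnapped - np.array([6.0, 0.0])
    v2 = np.array([-6.0, 12.0]) - np.array([6.0, 0.0])
    assert abs(v1[0] * v2[1] - v1[1] * v2[0]) < 1e-9
    # returned point differs from unsnapped only along the line, < 0.5 cm
    dd = iso - unsnapped
    d = v2 / np.linalg.norm(v2)
    assert abs(dd @ np.array([-d[1], d[0]])) < 1e-9
    assert np.linalg.norm(dd) <= 0.5 + 1e-9


def test_isocenter_snapping_rounds_along_tangent():
    # borders horizontal: tangent along +x; tattoo 3.4 cm before midpoint
    b = borders(1.0, 0.0, 5.8, 0.0)
    iso = isocenter_position(b, "left", (0.0, 0.0))
    # unsnapped midpoint at x=3.4 -> snapped to 3.0 cm from the tattoo
    assert iso[0] == pytest.approx(3.0)
    assert iso[1] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# energies


@pytest.mark.parametrize(
    "sep, expected",
    [(24.0, [6.0, 6.0]), (25.0, [6.0, 6.0]), (26.0, [6.0, 18.0, 6.0, 18.0])],
)
def test_energy_selection_threshold(sep, expected):
    b = borders(0, 0, sep, 0)
    assert select_energies(b, EnergyPolicy()) == expected


def test_energy_policy_validation():
    with pytest.raises(ValueError):
        EnergyPolicy(separation_threshold=0.0)


# ---------------------------------------------------------------------------
# border computation on an analytic circle


def circle_patient(radius=10.0, spacing=0.25, tattoo_angle=180.0):
    n = int(2 * (radius + 2) / spacing)
    shape = (n, n, 9)
    origin = np.array([-(radius + 2), -(radius + 2), -9 * spacing / 2])
    xs = origin[0] + (np.arange(n) + 0.5) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    disk = X**2 + Y**2 <= radius**2
    ext = np.repeat(disk[:, :, None], 9, axis=2)
    ptv = np.zeros(shape, bool)
    ptv[n // 2 - 4 : n // 2 + 4, 2 : n // 4, 3:6] = True
    ptv &= ext
    a = np.deg2rad(tattoo_angle)
    structures = {
        "External": ext, "PTV_Breast": ptv, "PTV_planning": ptv.copy(),
        "Ipsilateral Lung": np.zeros(shape, bool),
        "Contralateral Lung": np.zeros(shape, bool),
        "Heart": np.zeros(shape, bool),
        "Contralateral Breast": np.zeros(shape, bool),
    }
    tattoo = np.array([radius * np.cos(a), radius * np.sin(a), 0.0])
    return PatientModel(density=ext.astype(float), structures=structures,
                        tattoo=tattoo, laterality="left", spacing=spacing, origin=origin)


def test_borders_on_circle_match_analytic_intersections():
    """A diameter line through a 10 cm circle crosses at (-10,0), (10,0);
    the medial point is the one near the tattoo."""
    p = circle_patient()
    b = compute_borders(p, np.array([1.0, 0.0]))
    assert b.medial_world[0] == pytest.approx(-10.0, abs=2 * p.spacing)
    assert abs(b.medial_world[1]) < 2 * p.spacing
    assert b.posterior_world[0] == pytest.approx(10.0, abs=2 * p.spacing)
    assert b.separation == pytest.approx(20.0, abs=4 * p.spacing)


def test_borders_degenerate_when_line_misses():
    p = circle_patient()
    p = PatientModel(density=p.density, structures=p.structures,
                     tattoo=np.array([0.0, 11.5, 0.0]), laterality="left",
                     spacing=p.spacing, origin=p.origin)
    with pytest.raises(DegenerateGeometryError):
        compute_borders(p, np.array([1.0, 0.0]))


def test_borders_of_optimized_line_lie_on_the_skin(default_patient, default_geometry):
    p = default_patient
    for pt in (default_geometry.borders.medial_world, default_geometry.borders.posterior_world):
        kz = int(round(np.mean(np.argwhere(p.mask("PTV_Breast"))[:, 2])))
        idx = np.round(p.world_to_index(np.array([pt[0], pt[1], 0.0]))).astype(int)
        patch = p.mask("External")[idx[0] - 1 : idx[0] + 2, idx[1] - 1 : idx[1] + 2, kz]
        assert patch.any() and not patch.all(), "border point not on the surface"


# ---------------------------------------------------------------------------
# tangent-line optimization


def test_optimized_tangent_matches_exhaustive_scan(default_patient):
    """The returned rotation must equal the optimum of an independent
    brute-force scan over 0.5-degree rotations about the tattoo."""
    p = default_patient
    d, n = optimize_tangent(p, margin=1.0)

    ptv = p.mask("PTV_planning")
    t_xy = p.tattoo[:2]
    pts = p.voxel_centers(ptv)[:, :2] - t_xy
    kz = int(round(np.mean(np.argwhere(p.mask("PTV_Breast"))[:, 2])))
    # brute force (independently coded)
    ext_idx = np.argwhere(p.mask("External")[:, :, kz])
    ext_pts = p.origin[:2] + (ext_idx + 0.5) * p.spacing - t_xy
    lever = np.linalg.norm(pts, axis=1)
    req = 1.0 * np.clip((lever - 2.0) / 4.0, 0.0, 1.0)
    best = None
    for phi in np.arange(0.0, 360.0, 0.5):
        nv = np.array([np.cos(np.radians(phi)), np.sin(np.radians(phi))])
        if (pts @ nv >= req).all():
            area = int((ext_pts @ nv >= 0).sum())
            if best is None or area < best[0]:
                best = (area, nv)
    assert best is not None
    got_area = int((ext_pts @ n >= 0).sum())
    assert got_area == best[0]


def test_infeasible_geometry_raises(water_patient):
    """A target filling the block interior cannot be covered by any line
    pinned on the surface."""
    with pytest.raises(InfeasibleGeometryError):
        optimize_tangent(water_patient, margin=8.0)


def test_included_area_monotone_in_margin(default_patient):
    p = default_patient
    kz = int(round(np.mean(np.argwhere(p.mask("PTV_Breast"))[:, 2])))
    ext_idx = np.argwhere(p.mask("External")[:, :, kz])
    ext_pts = p.origin[:2] + (ext_idx + 0.5) * p.spacing - p.tattoo[:2]
    areas = []
    for margin in (0.0, 0.5, 1.0):
        _, n = optimize_tangent(p, margin=margin)
        areas.append(int((ext_pts @ n >= 0).sum()))
    assert areas[0] <= areas[1] <= areas[2]


# ---------------------------------------------------------------------------
# conformal apertures


def test_aperture_encloses_box_projection(water_patient):
    """For a box target and no margin/flash the leaf tips must match the
    closed-form projection of the box corners through the point source."""
    # build a synthetic beam along +y through the box
    from tangentplan.geometry import Beam, TangentGeometry

    p = water_patient
    iso = np.array([0.0, 0.0, 0.0])
    axis = np.array([0.0, 1.0, 0.0])
    anterior = np.array([1.0, 0.0, 0.0])
    beam = Beam(beam_id="b", source=iso - SAD * axis, axis=axis, anterior=anterior,
                isocenter=iso, energy=6.0, gantry_angle=90.0)
    geom = TangentGeometry(
        theta_medial=90.0, theta_lateral=270.0, collimator=0.0, isocenter=iso,
        borders=BorderPoints(0, 0, 0, 1), energies=[6.0], beams=[beam],
        edge_point=iso, edge_dir=axis, anterior_normal=anterior)
    fit_conformal_apertures(p, geom, margin=0.0, flash=0.0)

    # analytic: box corners, max magnified u over the rows they span
    ptv_pts = p.voxel_centers(p.mask("PTV_Breast"))
    rel = ptv_pts - beam.source
    u_proj = (rel @ anterior) * SAD / (rel @ axis)
    tips = beam.leaf_tips[beam.leaf_tips > 0]
    assert tips.max() == pytest.approx(u_proj.max(), abs=1e-9)
    # every projected target point is enclosed by its row's leaf
    v_proj = (rel @ np.array([0, 0, 1.0])) * SAD / (rel @ axis)
    rows = np.clip(np.searchsorted(beam.leaf_edges_z, v_proj) - 1, 0,
                   len(beam.leaf_tips) - 1)
    assert (u_proj <= beam.leaf_tips[rows] + 1e-9).all()


def test_flash_extends_leaves_past_skin(default_patient, default_geometry):
    """With 2 cm flash every open leaf tip sits >= 2 cm beyond the
    projected skin within that leaf row."""
    import copy

    p = default_patient
    geom = copy.deepcopy(default_geometry)
    fit_conformal_apertures(p, geom, margin=0.7, flash=2.0)
    beam = geom.beams[0]
    ext_pts = p.voxel_centers(p.mask("External"))
    rel = ext_pts - beam.source
    a = rel @ beam.axis
    u = (rel @ beam.anterior) * SAD / a
    v = (rel @ np.array([0, 0, 1.0])) * SAD / a
    for i, tip in enumerate(beam.leaf_tips):
        if tip <= 0:
            continue
        sel = (v >= beam.leaf_edges_z[i]) & (v < beam.leaf_edges_z[i + 1])
        if sel.any():
            assert tip >= u[sel].max() + 2.0 - 1e-6


def test_posterior_jaw_fixed_at_zero(default_geometry):
    for beam in default_geometry.beams:
        assert beam.jaws["posterior"] == 0.0


def test_opposed_beams_and_angles(default_geometry):
    g = default_geometry
    assert (g.theta_lateral - (g.theta_medial + 180.0)) % 360.0 == pytest.approx(0.0)
    med = [b for b in g.beams if b.gantry_angle == g.theta_medial][0]
    lat = [b for b in g.beams if b.gantry_angle == g.theta_lateral][0]
    assert np.allclose(med.axis, -lat.axis)
    # central axis runs from the medial entry toward the posterior border
    mw = np.array(g.borders.medial_world)
    pw = np.array(g.borders.posterior_world)
    assert med.axis[:2] @ (pw - mw) > 0
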