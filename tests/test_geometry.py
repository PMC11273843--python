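"""Surface volumes, AHA-17 thickness, and the spheroid fixture generator."""

import math

import numpy as np
import pytest
import trimesh

from lvmech.geometry import (
    LVSurfacePair,
    SurfaceTopologyError,
    TriSurface,
    aha17_segments,
    aha17_thickness,
    cavity_volume,
    equivalent_radii,
    export_vtk,
    load_surface,
    make_spheroid_pair,
    point_surface_distance,
    save_surface,
    segment_means,
    wall_volume,
)

HEMI_VOL = 2.0 * math.pi / 3.0


@pytest.fixture(scope="module")
def hemi_pair():
    """Concentric hemispheres, radii 2 and 3 cm (uniform 1 cm wall)."""
    return make_spheroid_pair((2.0, 2.0, 2.0), 1.0, truncation_z=0.0, refinement=3)


@pytest.fixture(scope="module")
def closed_sphere():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.3)
    return TriSurface(np.asarray(ico.vertices), np.asarray(ico.faces))


# ---------------------------------------------------------------- volumes ---

def test_hemisphere_cavity_volume_matches_analytic():
    pair = make_spheroid_pair((1.0, 1.0, 1.0), 0.5, truncation_z=0.0, refinement=3)
    assert cavity_volume(pair.endo) == pytest.approx(HEMI_VOL, rel=5e-3)


def test_cavity_volume_refinement_error_decreases():
    errs = [
        abs(cavity_volume(make_spheroid_pair((1, 1, 1), 0.5, 0.0, refinement=lvl).endo) - HEMI_VOL)
        for lvl in (1, 2, 3)
    ]
    assert errs[0] > errs[1] > errs[2]


def test_cavity_volume_equals_signed_tet_sum_from_any_reference(closed_sphere):
    """Divergence-theorem value equals tetrahedra summed from an arbitrary
    interior point, to 1e-10 relative (closed surface)."""
    v = cavity_volume(closed_sphere)
    ref = np.array([0.3, -0.2, 0.5])
    tri = closed_sphere.triangle_coords() - ref
    v_tet = np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    assert abs(v - v_tet) / abs(v) < 1e-10


def test_closed_surface_translation_invariance_and_flip(closed_sphere):
    v = cavity_volume(closed_sphere)
    assert cavity_volume(closed_sphere.translated([5.0, -3.0, 2.0])) == pytest.approx(v, abs=1e-12)
    flipped = TriSurface(closed_sphere.vertices, closed_sphere.faces[:, [0, 2, 1]])
    assert cavity_volume(flipped) == pytest.approx(-v, abs=1e-12)


def test_cavity_volume_vertex_permutation_invariance(hemi_pair, rng):
    s = hemi_pair.endo
    perm = rng.permutation(len(s.vertices))
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    s2 = TriSurface(s.vertices[perm], inv[s.faces])
    assert cavity_volume(s2) == pytest.approx(cavity_volume(s), abs=1e-12)


def test_cavity_volume_rejects_off_plane_boundary(hemi_pair):
    with pytest.raises(SurfaceTopologyError):
        cavity_volume(hemi_pair.endo.translated([0.0, 0.0, 0.5]))


def test_cavity_volume_rejects_multiple_loops():
    a = make_spheroid_pair((1, 1, 1), 0.5, 0.0, refinement=1).endo
    b = a.translated([5.0, 0.0, 0.0])
    merged = TriSurface(
        np.vstack([a.vertices, b.vertices]),
        np.vstack([a.faces, b.faces + len(a.vertices)]),
    )
    with pytest.raises(SurfaceTopologyError):
        cavity_volume(merged)


def test_cavity_volume_rejects_non_manifold_edge(hemi_pair):
    s = hemi_pair.endo
    # add a fin: re-use an existing edge in a third face
    f0 = s.faces[0]
    extra_v = np.vstack([s.vertices, s.vertices[f0[0]] + [0.5, 0.5, -0.5]])
    extra_f = np.vstack([s.faces, [f0[0], f0[1], len(s.vertices)]])
    with pytest.raises(SurfaceTopologyError):
        cavity_volume(TriSurface(extra_v, extra_f))


def test_wall_volume_analytic_shell(hemi_pair):
    exact = HEMI_VOL * (27.0 - 8.0)
    assert wall_volume(hemi_pair) == pytest.approx(exact, rel=5e-3)


def test_wall_volume_scales_cubically(hemi_pair):
    k = 1.7
    scaled = LVSurfacePair(
        TriSurface(hemi_pair.endo.vertices * k, hemi_pair.endo.faces),
        TriSurface(hemi_pair.epi.vertices * k, hemi_pair.epi.faces),
    )
    assert wall_volume(scaled) == pytest.approx(k**3 * wall_volume(hemi_pair), rel=1e-12)


def test_degenerate_pair_rejected(hemi_pair):
    with pytest.raises(ValueError):
        LVSurfacePair(hemi_pair.endo, hemi_pair.endo)


def test_equivalent_radii_concentric_spheres(hemi_pair):
    # hemispheres of radii 2 and 3: half-sphere volumes give radii /2^(1/3)
    ri, ro = equivalent_radii(hemi_pair)
    assert ri == pytest.approx(2.0 / 2 ** (1 / 3), rel=5e-3)
    assert ro == pytest.approx(3.0 / 2 ** (1 / 3), rel=5e-3)
    assert ro > ri


# ----------------------------------------------------------- AHA-17 model ---

def test_aha17_uniform_wall_is_constant(hemi_pair):
    th = aha17_thickness(hemi_pair)
    assert np.all(np.abs(th.values_cm - 1.0) < 0.02)


def test_aha17_septal_thickening_exceeds_free_wall():
    """Thickening the septal azimuth (60-180 deg) raises exactly the septal
    segments 2, 3, 8, 9, 14 above the free-wall segments 5, 6, 11, 12, 16."""

    def h(phi):
        phi = np.asarray(phi)
        return 1.0 + 0.5 * ((phi >= math.pi / 3) & (phi < math.pi))

    th = aha17_thickness(make_spheroid_pair((2, 2, 2), h, 0.0, refinement=3))
    for septal, free in zip((2, 3, 8, 9, 14), (5, 6, 11, 12, 16)):
        assert th[septal] > th[free] + 0.2


def test_aha17_rotation_shifts_sectors():
    """A 180-degree rotation permutes basal/mid sectors by 3, apical by 2."""

    def h(phi):
        phi = np.asarray(phi)
        return 1.0 + 0.4 * np.cos(phi) + 0.2 * np.sin(phi)

    base = make_spheroid_pair((2, 2, 2.6), h, 0.0, refinement=3)
    # detune the vertex columns off the sector boundaries so that the
    # floating-point sector floor cannot flip boundary columns
    delta = math.pi / 384.0
    pair = LVSurfacePair(
        base.endo.rotated_about_z(delta), base.epi.rotated_about_z(delta)
    )
    rot = LVSurfacePair(
        pair.endo.rotated_about_z(math.pi), pair.epi.rotated_about_z(math.pi)
    )
    a = aha17_thickness(pair).values_cm
    b = aha17_thickness(rot).values_cm
    shift6 = [3, 4, 5, 0, 1, 2]
    assert np.allclose(b[:6], a[:6][shift6], atol=5e-3)
    assert np.allclose(b[6:12], a[6:12][shift6], atol=5e-3)
    assert np.allclose(b[12:16], a[12:16][[2, 3, 0, 1]], atol=5e-3)
    assert b[16] == pytest.approx(a[16], abs=5e-3)


def test_aha17_segment_assignment_rings():
    z = np.array([-0.1, -1.1, -2.1, -2.9])  # basal, mid, apical, apex cap
    pts = np.column_stack([np.full(4, 0.5), np.zeros(4), z])
    seg = aha17_segments(pts)  # extent 2.9; thirds at 0.967, 1.933
    assert list(seg) == [1, 7, 13, 17]
    # sector winding: phi just past 60 degrees falls in segment 2
    pts2 = np.array([[0.4, 0.8, -0.1], [-0.5, -0.5, -0.1], [0.0, 0.0, -2.9]])
    assert list(aha17_segments(pts2)[:2]) == [2, 4]


def test_segment_means_names_empty_segment():
    seg = np.array([1] * 16 + [s for s in range(1, 17)])  # no segment 17
    with pytest.raises(ValueError, match="segment 17"):
        segment_means(seg, np.ones_like(seg, dtype=float))


# ------------------------------------------------- fixture generator + IO ---

def test_make_spheroid_pair_validation():
    with pytest.raises(ValueError):
        make_spheroid_pair((2, 2, 2), -0.5)
    with pytest.raises(ValueError):
        make_spheroid_pair((2, 2, 2), 1.0, truncation_z=2.5)


def test_make_spheroid_pair_deterministic():
    a = make_spheroid_pair((2, 2, 3), 1.0, 0.0, refinement=2)
    b = make_spheroid_pair((2, 2, 3), 1.0, 0.0, refinement=2)
    assert np.array_equal(a.endo.vertices, b.endo.vertices)
    assert np.array_equal(a.epi.faces, b.epi.faces)


def test_spheroid_surfaces_open_with_single_basal_loop(hemi_pair):
    for s in (hemi_pair.endo, hemi_pair.epi):
        loops = s.boundary_loops()
        assert len(loops) == 1
        assert np.allclose(s.vertices[loops[0], 2], 0.0, atol=1e-12)


def test_closed_surface_euler_characteristic(closed_sphere):
    assert closed_sphere.euler_characteristic() == 2


def test_point_surface_distance_matches_brute_force(rng):
    pair = make_spheroid_pair((2, 2, 2.5), 1.0, 0.0, refinement=1)
    pts = pair.endo.vertices[rng.choice(len(pair.endo.vertices), 40, replace=False)]
    fast = point_surface_distance(pts, pair.epi)
    tri = pair.epi.triangle_coords()
    from lvmech.geometry import _point_triangle_distance

    n, m = len(pts), len(tri)
    brute = _point_triangle_distance(
        np.repeat(pts, m, axis=0), np.tile(tri, (n, 1, 1))
    ).reshape(n, m).min(axis=1)
    assert np.allclose(fast, brute, atol=1e-12)


def test_surface_io_roundtrip(tmp_path, hemi_pair):
    s = hemi_pair.endo
    for name in ("endo.ply", "endo.obj"):
        save_surface(s, tmp_path / name)
        s2 = load_surface(tmp_path / name)
        assert np.allclose(s.vertices, s2.vertices, atol=1e-6)
        assert np.array_equal(s.faces, s2.faces)
    export_vtk(s, tmp_path / "endo.vtk")
    text = (tmp_path / "endo.vtk").read_text()
    assert text.startswith("# vtk DataFile") and "POLYGONS" in text
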