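"""Surface-based left-ventricular geometry.

Triangulated endocardial/epicardial surfaces carry the cavity-volume integral
``V = (1/3) oint x . n da`` (evaluated as a signed-tetrahedron sum after the
open basal boundary is closed with a fan cap), wall-volume and equivalent-radius
reduction, AHA 17-segment wall thickness, and an idealized truncated-spheroid
surface generator used as a deterministic fixture.

Coordinate convention: base plane at z = 0, apex at negative z, long axis = z.
Circumferential sector 1 starts at the +x axis, proceeding counterclockwise
when viewed from the base.  Surfaces are stored with cavity-outward normals;
a flipped orientation shows up as a negated signed volume.

ASCII PLY/OBJ input/output goes through :mod:`trimesh`; a legacy-ASCII VTK
polydata writer is provided for visualization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriSurface",
    "LVSurfacePair",
    "SegmentThickness",
    "cavity_volume",
    "wall_volume",
    "equivalent_radii",
    "aha17_thickness",
    "aha17_segments",
    "segment_means",
    "make_spheroid_pair",
    "load_surface",
    "save_surface",
    "export_vtk",
    "point_surface_distance",
    "SurfaceTopologyError",
]

DEGENERATE_AREA_CM2 = 1e-10
BASE_PLANE_TOL_CM = 1e-6

# AHA-17 circumferential sector counts per longitudinal ring and the fraction
# of the apical third treated as the apex cap (segment 17).
_APEX_CAP_FRACTION = 0.2


class SurfaceTopologyError(ValueError):
    """Surface violates the topology the operation requires."""


@dataclass(frozen=True)
class TriSurface:
    """Triangulated surface: vertices (cm) and faces, outward orientation."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if np.any(self.face_areas() < DEGENERATE_AREA_CM2):
            raise ValueError(f"degenerate (area < {DEGENERATE_AREA_CM2} cm^2) triangle present")

    def triangle_coords(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangle_coords()
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def boundary_loops(self) -> list[np.ndarray]:
        """Boundary loops as ordered vertex-index arrays.

        Raises :class:`SurfaceTopologyError` on non-manifold edges (an edge
        shared by more than two faces).
        """
        e = self.edges()
        key = np.sort(e, axis=1)
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise SurfaceTopologyError("non-manifold edge (shared by > 2 faces)")
        boundary = uniq[counts == 1]
        if len(boundary) == 0:
            return []
        nxt: dict[int, list[int]] = {}
        for a, b in boundary:
            nxt.setdefault(int(a), []).append(int(b))
            nxt.setdefault(int(b), []).append(int(a))
        if any(len(v) != 2 for v in nxt.values()):
            raise SurfaceTopologyError("boundary is not a union of simple loops")
        loops: list[np.ndarray] = []
        seen: set[int] = set()
        for start in sorted(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                a, b = nxt[cur]
                step = a if a != prev else b
                if step == start:
                    break
                loop.append(step)
                seen.add(step)
                prev, cur = cur, step
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def is_closed(self) -> bool:
        return len(self.boundary_loops()) == 0

    def euler_characteristic(self) -> int:
        n_e = len(np.unique(np.sort(self.edges(), axis=1), axis=0))
        return len(self.vertices) - n_e + len(self.faces)

    def translated(self, offset) -> "TriSurface":
        return TriSurface(self.vertices + np.asarray(offset, dtype=float), self.faces)

    def rotated_about_z(self, angle_rad: float) -> "TriSurface":
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return TriSurface(self.vertices @ rot.T, self.faces)


@dataclass(frozen=True)
class LVSurfacePair:
    """Endocardial + epicardial surfaces sharing a base plane (z = 0)."""

    endo: TriSurface
    epi: TriSurface
    base_plane_z: float = 0.0

    def __post_init__(self) -> None:
        v_endo = cavity_volume(self.endo, self.base_plane_z)
        v_epi = cavity_volume(self.epi, self.base_plane_z)
        if not v_epi > v_endo:
            raise ValueError("epicardium must enclose endocardium (epi volume > endo volume)")


@dataclass(frozen=True)
class SegmentThickness:
    """Mean wall thickness (cm) per AHA segment, indexed 1-17."""

    values_cm: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values_cm, dtype=float)
        if v.shape != (17,):
            raise ValueError("expected 17 segment values")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("segment thickness must be positive and finite")
        object.__setattr__(self, "values_cm", v)

    def __getitem__(self, segment_id: int) -> float:
        if not 1 <= segment_id <= 17:
            raise KeyError("AHA segment ids run 1-17")
        return float(self.values_cm[segment_id - 1])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"segment_id": np.arange(1, 18), "thickness_cm": self.values_cm}
        ).to_csv(path, index=False)


def _closed_triangles(surface: TriSurface, base_plane_z: float) -> np.ndarray:
    """Triangle array of the surface closed by a fan cap over its basal loop.

    Returns (m, 3, 3) coordinates.  A closed surface is returned unchanged;
    a single boundary loop must lie in the base plane and is capped by a fan
    about its centroid, wound opposite to the adjacent surface triangles so
    orientation stays consistent.
    """
    loops = surface.boundary_loops()
    tri = surface.triangle_coords()
    if not loops:
        return tri
    if len(loops) > 1:
        raise SurfaceTopologyError(f"expected one boundary loop, found {len(loops)}")
    loop = loops[0]
    z = surface.vertices[loop, 2]
    if np.any(np.abs(z - base_plane_z) > BASE_PLANE_TOL_CM):
        raise SurfaceTopologyError(
            f"boundary loop not within {BASE_PLANE_TOL_CM} cm of base plane z={base_plane_z}"
        )
    # Orient the cap opposite to the surface winding along the boundary: find
    # one boundary edge inside a face and reuse its (a, b) order reversed.
    edge_dir: dict[tuple[int, int], int] = {}
    for f in surface.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_dir[(int(a), int(b))] = 1
    centroid = surface.vertices[loop].mean(axis=0)
    cap = []
    n = len(loop)
    for i in range(n):
        a, b = int(loop[i]), int(loop[(i + 1) % n])
        # surface holds edge (a, b) or (b, a); the cap triangle must traverse
        # it in the opposite direction to keep the closed surface orientable
        if (a, b) in edge_dir:
            cap.append([surface.vertices[b], surface.vertices[a], centroid])
        else:
            cap.append([surface.vertices[a], surface.vertices[b], centroid])
    return np.concatenate([tri, np.asarray(cap)], axis=0)


def _signed_volume(triangles: np.ndarray) -> float:
    """Sum of signed tetrahedra (apex at origin) over closed triangle soup."""
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def cavity_volume(surface: TriSurface, base_plane_z: float = 0.0) -> float:
    """Enclosed volume (mL) of a surface open at the base plane.

    Implements the divergence-theorem cavity volume: the surface is closed by
    a fan-triangulated basal cap and the enclosed volume is the sum of signed
    tetrahedra, positive for cavity-outward orientation.  A negative return
    value signals flipped orientation (the caller sees the sign).
    """
    return _signed_volume(_closed_triangles(surface, base_plane_z))


def wall_volume(pair: LVSurfacePair) -> float:
    """Myocardial wall volume (mL): epicardial minus endocardial cavity volume."""
    v = cavity_volume(pair.epi, pair.base_plane_z) - cavity_volume(pair.endo, pair.base_plane_z)
    if not v > 0:
        raise ValueError("non-positive wall volume: inconsistent surface pair")
    return v


def equivalent_radii(pair: LVSurfacePair) -> tuple[float, float]:
    """Volume-equivalent inner and outer sphere radii (cm) of the pair."""
    v_cav = cavity_volume(pair.endo, pair.base_plane_z)
    v_wall = wall_volume(pair)
    inner = (3.0 * v_cav / (4.0 * math.pi)) ** (1.0 / 3.0)
    outer = (3.0 * (v_cav + v_wall) / (4.0 * math.pi)) ** (1.0 / 3.0)
    return inner, outer


# ---------------------------------------------------------------------------
# point -> triangle-mesh distance (KD-tree prefilter + exact triangle distance)
# ---------------------------------------------------------------------------

def _point_triangle_distance(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact distance from points[i] to triangles[i] (paired), vectorized."""
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, ap = b - a, c - a, points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def assign(mask: np.ndarray, value: np.ndarray) -> None:
        m = mask & ~done
        closest[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)

    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    assign(np.ones(len(points), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)

    return np.linalg.norm(points - closest, axis=1)


def point_surface_distance(
    points: np.ndarray, surface: TriSurface, n_candidates: int = 24
) -> np.ndarray:
    """Distance from each point to the nearest point on the triangle mesh.

    A KD-tree on triangle centroids prefilters candidate triangles; the exact
    point-triangle distance is taken over the candidate set, enlarged by the
    largest triangle circumradius so the prefilter cannot miss the true
    nearest triangle.
    """
    points = np.asarray(points, dtype=float)
    tri = surface.triangle_coords()
    centroids = tri.mean(axis=1)
    k = min(n_candidates, len(tri))
    tree = cKDTree(centroids)
    _, idx = tree.query(points, k=k)
    if k == 1:
        idx = idx[:, None]
    n_pts = len(points)
    pts_rep = np.repeat(points, k, axis=0)
    tris_rep = tri[idx.ravel()]
    d = _point_triangle_distance(pts_rep, tris_rep).reshape(n_pts, k)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# AHA 17-segment wall thickness
# ---------------------------------------------------------------------------

def aha17_segments(vertices: np.ndarray, base_plane_z: float = 0.0) -> np.ndarray:
    """AHA segment id (1-17) for each endocardial vertex.

    Longitudinal thirds of the base-to-apex extent give basal (1-6) and mid
    (7-12) rings in 60-degree circumferential sectors and an apical ring in
    90-degree sectors (13-16); the most apical 20% of the apical third is the
    apex cap, segment 17.  Sector 1 starts at +x, counterclockwise viewed
    from the base.
    """
    v = np.asarray(vertices, dtype=float)
    depth = base_plane_z - v[:, 2]
    extent = depth.max()
    if extent <= 0:
        raise ValueError("apex must lie below the base plane")
    frac = depth / extent
    phi = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2.0 * math.pi)
    seg = np.empty(len(v), dtype=np.int64)

    basal = frac < 1.0 / 3.0
    mid = (frac >= 1.0 / 3.0) & (frac < 2.0 / 3.0)
    apex_cap = frac >= (2.0 / 3.0 + (1.0 - _APEX_CAP_FRACTION) / 3.0)
    apical = (frac >= 2.0 / 3.0) & ~apex_cap

    sector6 = np.floor(phi / (math.pi / 3.0)).astype(np.int64) % 6
    sector4 = np.floor(phi / (math.pi / 2.0)).astype(np.int64) % 4
    seg[basal] = 1 + sector6[basal]
    seg[mid] = 7 + sector6[mid]
    seg[apical] = 13 + sector4[apical]
    seg[apex_cap] = 17
    return seg


def aha17_thickness(pair: LVSurfacePair) -> SegmentThickness:
    """Mean endo-to-epi wall thickness (cm) per AHA 17 segment.

    Per-vertex thickness is the distance from each endocardial vertex to the
    nearest point on the epicardial surface; segment values are means over
    the vertices assigned to each segment.
    """
    seg = aha17_segments(pair.endo.vertices, pair.base_plane_z)
    thick = point_surface_distance(pair.endo.vertices, pair.epi)
    return SegmentThickness(segment_means(seg, thick))


def segment_means(segments: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Mean value per AHA segment 1-17; an empty segment raises, named."""
    out = np.empty(17)
    for s in range(1, 18):
        mask = segments == s
        if not np.any(mask):
            raise ValueError(f"AHA segment {s} contains no endocardial vertices")
        out[s - 1] = values[mask].mean()
    return out


# ---------------------------------------------------------------------------
# idealized truncated-spheroid fixture generator
# ---------------------------------------------------------------------------

def _spheroid_surface(
    semi_axes: tuple[float, float, float],
    truncation_z: float,
    refinement: int,
    offset_fn=None,
) -> TriSurface:
    """Deterministic tessellation of a spheroid truncated at height z_t.

    The spheroid is centered at the origin, the part with z <= z_t is kept and
    translated so the cut lies at z = 0 (base plane), apex at negative z.
    ``offset_fn(phi)`` optionally displaces each point outward along the exact
    ellipsoid normal (used to build epicardial surfaces of prescribed, possibly
    circumferentially varying, wall thickness).
    """
    ax, ay, az = semi_axes
    if truncation_z >= az or truncation_z <= -az:
        raise ValueError("truncation plane must cut the spheroid below its dome top")
    n_theta = 8 * 2**refinement
    n_phi = 16 * 2**refinement
    theta0 = math.acos(truncation_z / az)
    thetas = np.linspace(theta0, math.pi, n_theta + 1)
    phis = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)

    rings = []
    for th in thetas[:-1]:
        x = ax * math.sin(th) * np.cos(phis)
        y = ay * math.sin(th) * np.sin(phis)
        z = np.full(n_phi, az * math.cos(th))
        rings.append(np.column_stack([x, y, z]))
    apex = np.array([[0.0, 0.0, -az]])
    verts = np.concatenate(rings + [apex], axis=0)

    if offset_fn is not None:
        normals = np.column_stack(
            [verts[:, 0] / ax**2, verts[:, 1] / ay**2, verts[:, 2] / az**2]
        )
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        h = np.asarray(offset_fn(np.mod(np.arctan2(verts[:, 1], verts[:, 0]), 2 * math.pi)))
        verts = verts + h[:, None] * normals
        # keep the basal ring exactly in the cut plane
        verts[:n_phi, 2] = truncation_z

    verts[:, 2] -= truncation_z

    faces = []
    for i in range(n_theta - 1):
        r0, r1 = i * n_phi, (i + 1) * n_phi
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            faces.append([r0 + j, r1 + j, r1 + jn])
            faces.append([r0 + j, r1 + jn, r0 + jn])
    apex_idx = len(verts) - 1
    last = (n_theta - 1) * n_phi
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        faces.append([last + j, apex_idx, last + jn])
    surf = TriSurface(verts, np.asarray(faces, dtype=np.int64))
    if cavity_volume(surf) < 0:  # enforce cavity-outward orientation
        surf = TriSurface(verts, surf.faces[:, [0, 2, 1]])
    return surf


def make_spheroid_pair(
    endo_semi_axes: tuple[float, float, float],
    wall_thickness_cm,
    truncation_z: float = 0.0,
    refinement: int = 3,
) -> LVSurfacePair:
    """Truncated prolate-spheroid endo/epi pair, base at z = 0.

    ``wall_thickness_cm`` is a positive scalar or a callable of the
    circumferential angle phi (radians) returning per-point thickness; the
    epicardium is the endocardial spheroid offset along its exact outward
    normal.  Tessellation is deterministic for a given refinement level.
    """
    if callable(wall_thickness_cm):
        fn = wall_thickness_cm
        probe = np.asarray(fn(np.linspace(0, 2 * math.pi, 16)))
        if np.any(probe <= 0):
            raise ValueError("wall thickness must be positive everywhere")
    else:
        if not wall_thickness_cm > 0:
            raise ValueError("wall thickness must be positive")
        h = float(wall_thickness_cm)
        fn = lambda phi: np.full_like(np.asarray(phi, dtype=float), h)
    endo = _spheroid_surface(endo_semi_axes, truncation_z, refinement)
    epi = _spheroid_surface(endo_semi_axes, truncation_z, refinement, offset_fn=fn)
    return LVSurfacePair(endo=endo, epi=epi, base_plane_z=0.0)


# ---------------------------------------------------------------------------
# surface input/output
# ---------------------------------------------------------------------------

def load_surface(path) -> TriSurface:
    """Read a triangulated surface from ASCII PLY or OBJ."""
    mesh = trimesh.load(str(path), process=False, force="mesh")
    return TriSurface(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64))


def save_surface(surface: TriSurface, path) -> None:
    """Write a surface to ASCII PLY or OBJ (by file extension)."""
    path = Path(path)
    mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
    if path.suffix.lower() == ".ply":
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    elif path.suffix.lower() == ".obj":
        path.write_text(trimesh.exchange.obj.export_obj(mesh))
    else:
        raise ValueError(f"unsupported surface format: {path.suffix}")


def export_vtk(surface: TriSurface, path) -> None:
    """Write legacy-ASCII VTK polydata (triangles) for visualization."""
    lines = [
        "# vtk DataFile Version 3.0",
        "lvmech surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(surface.vertices)} double",
    ]
    lines += [" ".join(f"{c:.10g}" for c in v) for v in surface.vertices]
    lines.append(f"POLYGONS {len(surface.faces)} {4 * len(surface.faces)}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in surface.faces]
    Path(path).write_text("\n".join(lines) + "\n")
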