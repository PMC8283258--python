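"""LV mesh representation, short-axis slicing, rasterization and labeling.

Coordinates are millimetres throughout.  The long axis is found by PCA on
the epicardial vertices and oriented apex-to-base; 25 short-axis planes are
placed at regular intervals from 20 % of the axis length above the apex to
the base.  Plane/mesh intersections become closed 2D contours, contours
become 256x256 binary myocardium masks at 1 mm/pixel, and a slice's binary
ground truth is whether its plane intersects the scar sub-mesh.  Slices are
excluded when self-intersecting, valve-contaminated, or under 50 foreground
pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import shapely
import trimesh
from shapely.geometry import LineString, Polygon

__all__ = [
    "GeometryError",
    "LVMesh",
    "AxisFrame",
    "SliceContours",
    "AnatomicalMask",
    "SliceSample",
    "compute_axes",
    "slice_mesh",
    "rasterize",
    "filter_slice",
    "label_slice",
    "slice_samples",
]

GRID_SIZE = 256
RESOLUTION_MM = 1.0
N_SLICES = 25
APEX_OFFSET = 0.20
MIN_PIXELS = 50
VALVE_CLEARANCE_MM = 2.0


class GeometryError(ValueError):
    """Raised for degenerate or out-of-contract geometry."""


@dataclass
class LVMesh:
    """Closed epicardial + endocardial surface pair, optional scar and valves.

    Vertices are ``(n, 3)`` float arrays in mm, faces ``(m, 3)`` int arrays.
    The endocardial surface must lie strictly inside the epicardial one;
    the scar sub-mesh, when present, lies within the myocardial shell.
    """

    patient_id: str
    epi_vertices: np.ndarray
    epi_faces: np.ndarray
    endo_vertices: np.ndarray
    endo_faces: np.ndarray
    scar_vertices: Optional[np.ndarray] = None
    scar_faces: Optional[np.ndarray] = None
    valve_points: Optional[np.ndarray] = None

    @property
    def has_scar(self) -> bool:
        return self.scar_vertices is not None and len(self.scar_vertices) > 0

    def epi_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.epi_vertices, self.epi_faces, process=False)

    def endo_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.endo_vertices, self.endo_faces, process=False)

    def scar_trimesh(self) -> Optional[trimesh.Trimesh]:
        if not self.has_scar:
            return None
        return trimesh.Trimesh(self.scar_vertices, self.scar_faces, process=False)

    def validate(self) -> None:
        """Check closedness, finiteness and surface nesting; raise on failure."""
        for name, v in (("epi", self.epi_vertices), ("endo", self.endo_vertices)):
            if not np.isfinite(v).all():
                raise GeometryError(f"{name} vertices contain non-finite values")
        for name, tm in (("epi", self.epi_trimesh()), ("endo", self.endo_trimesh())):
            if not tm.is_watertight:
                raise GeometryError(f"{name} surface is not closed (open edges present)")
        # nesting: every endo vertex inside the epi surface
        inside = points_inside_mesh(self.epi_vertices, self.epi_faces, self.endo_vertices)
        if not inside.all():
            raise GeometryError("endocardial surface is not inside the epicardial surface")


@dataclass
class AxisFrame:
    """Apex-to-base long axis of an LV mesh."""

    apex_point: np.ndarray
    base_point: np.ndarray
    long_axis: np.ndarray
    length: float


@dataclass
class SliceContours:
    """Planar epicardial/endocardial contours of one short-axis plane.

    Contours are closed ``(k, 2)`` polylines (first vertex repeated last) in
    the plane's 2D frame spanned by ``basis_u``/``basis_v``.
    """

    plane_origin: np.ndarray
    plane_normal: np.ndarray
    epi_contours: list
    endo_contours: list
    hits_valve: bool = False
    self_intersecting: bool = False
    slice_index: int = 0
    normalized_position: float = 0.0
    basis_u: Optional[np.ndarray] = None
    basis_v: Optional[np.ndarray] = None

    @property
    def is_empty(self) -> bool:
        return len(self.epi_contours) == 0


@dataclass
class AnatomicalMask:
    """256x256 binary myocardium raster at 1 mm/pixel for one slice.

    ``grid[row, col]`` with world position of a pixel center at
    ``origin + (col * resolution, row * resolution)``.
    """

    grid: np.ndarray
    resolution: float = RESOLUTION_MM
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    patient_id: str = ""
    slice_index: int = 0
    normalized_position: float = 0.0

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())


@dataclass
class SliceSample:
    """One slice's mask, ground-truth label and validity after exclusion rules."""

    mask: "AnatomicalMask"
    label: int
    valid: bool = True
    reason: str = "none"
    contours: Optional[SliceContours] = None


def points_inside_mesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    points: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Ray-parity membership test for points against a closed triangle mesh.

    Casts a +z ray from each point and counts triangle crossings
    (vectorized Moller-Trumbore); odd crossing count means inside.  A tiny
    deterministic ray tilt avoids edge-grazing degeneracies.
    """
    V = np.asarray(vertices, dtype=np.float64)
    F = np.asarray(faces, dtype=np.int64)
    P = np.atleast_2d(np.asarray(points, dtype=np.float64))
    d = np.array([1.17e-5, 2.31e-5, 1.0])
    d /= np.linalg.norm(d)
    v0, v1, v2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(d, e2)  # (m, 3)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    inv_a = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    inside = np.zeros(len(P), dtype=bool)
    for s0 in range(0, len(P), chunk):
        p = P[s0 : s0 + chunk]
        s = p[:, None, :] - v0[None, :, :]  # (n, m, 3)
        u = np.einsum("nmj,mj->nm", s, h) * inv_a
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("nmj,j->nm", q, d) * inv_a
        t = np.einsum("nmj,mj->nm", q, e2) * inv_a
        hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        inside[s0 : s0 + chunk] = hit.sum(axis=1) % 2 == 1
    return inside


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed in-plane basis (u, v) with u x v = normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def compute_axes(mesh: LVMesh) -> AxisFrame:
    """Long axis by PCA of the epicardial vertices, oriented apex-to-base.

    The first principal component of the epicardial vertex cloud is the long
    axis.  PCA leaves the sign free; the base end is the one nearer the valve
    markers when present, otherwise the end with the larger endocardial
    cross-sectional (cavity) area.  Near-spherical meshes (degenerate leading
    eigenvalues) resolve deterministically with a warning.
    """
    verts = np.asarray(mesh.epi_vertices, dtype=float)
    if verts.shape[0] < 4:
        raise GeometryError("need at least 4 epicardial vertices for PCA")
    center = verts.mean(axis=0)
    centered = verts - center
    cov = centered.T @ centered / len(verts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12 * max(evals[2], 1.0):
        raise GeometryError(
            "epicardial vertex cloud is rank deficient (collinear/coplanar); "
            f"eigenvalues {evals}"
        )
    if (evals[2] - evals[1]) <= 1e-9 * evals[2]:
        warnings.warn(
            "degenerate PCA (near-spherical mesh): long axis resolved by fixed "
            "eigendecomposition ordering",
            stacklevel=2,
        )
    axis = evecs[:, 2]
    # deterministic sign before anatomical orientation
    j = int(np.argmax(np.abs(axis)))
    if axis[j] < 0:
        axis = -axis

    t = centered @ axis
    t_min, t_max = float(t.min()), float(t.max())

    flip = False
    if mesh.valve_points is not None and len(mesh.valve_points) > 0:
        tv = float(np.mean((np.asarray(mesh.valve_points, float) - center) @ axis))
        flip = abs(tv - t_min) < abs(tv - t_max)  # valves nearer low end -> flip
    else:
        area_hi = _cavity_area(mesh, center, axis, t_min + 0.85 * (t_max - t_min))
        area_lo = _cavity_area(mesh, center, axis, t_min + 0.15 * (t_max - t_min))
        flip = area_lo > area_hi
    if flip:
        axis = -axis
        t_min, t_max = -t_max, -t_min

    apex = center + t_min * axis
    base = center + t_max * axis
    return AxisFrame(apex_point=apex, base_point=base, long_axis=axis, length=t_max - t_min)


def _cavity_area(mesh: LVMesh, center: np.ndarray, axis: np.ndarray, t: float) -> float:
    """Total endocardial cross-section area at projection offset ``t``."""
    origin = center + t * axis
    polys = _section_polylines(mesh.endo_trimesh(), origin, axis)
    area = 0.0
    for poly in polys:
        if len(poly) >= 4:
            area += abs(Polygon(poly).area)
    return area


def _section_polylines(
    tm: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray
) -> list:
    """Closed 2D contours of a plane/mesh intersection in the plane frame."""
    sec = tm.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return []
    u, v = _plane_basis(normal)
    out = []
    for curve in sec.discrete:
        pts = np.asarray(curve, dtype=float)
        rel = pts - origin
        poly = np.column_stack([rel @ u, rel @ v])
        if not np.allclose(poly[0], poly[-1], atol=1e-9):
            poly = np.vstack([poly, poly[0]])
        out.append(poly)
    return out


def _is_self_intersecting(poly: np.ndarray) -> bool:
    if len(poly) < 4:
        return False
    return not LineString(poly).is_simple


def slice_mesh(
    mesh: LVMesh,
    frame: AxisFrame,
    n_slices: int = N_SLICES,
    apex_offset: float = APEX_OFFSET,
    valve_clearance: float = VALVE_CLEARANCE_MM,
    jitter_rng: Optional[np.random.Generator] = None,
) -> list:
    """Cut ``n_slices`` short-axis planes at regular intervals.

    Plane origins run from ``apex + apex_offset * length`` along the long
    axis to the base, both endpoints included.  A plane is valve-contaminated
    when it passes within ``valve_clearance`` of a valve marker or its
    epicardial intersection is not a single simple closed curve.  With
    ``jitter_rng`` given, each interior plane is displaced by up to half the
    inter-plane spacing (data augmentation; off by default).
    """
    if n_slices < 2:
        raise GeometryError("n_slices must be >= 2")
    if not 0.0 <= apex_offset < 1.0:
        raise GeometryError("apex_offset must be in [0, 1)")
    axis = frame.long_axis
    positions = np.linspace(apex_offset * frame.length, frame.length, n_slices)
    if jitter_rng is not None:
        spacing = (positions[-1] - positions[0]) / (n_slices - 1)
        positions = positions + jitter_rng.uniform(-0.5, 0.5, n_slices) * spacing
        positions = np.clip(positions, 0.0, frame.length)
    epi_tm = mesh.epi_trimesh()
    endo_tm = mesh.endo_trimesh()
    u, v = _plane_basis(axis)
    valve_t = None
    if mesh.valve_points is not None and len(mesh.valve_points) > 0:
        valve_t = (np.asarray(mesh.valve_points, float) - frame.apex_point) @ axis

    out = []
    for i, s in enumerate(positions):
        origin = frame.apex_point + s * axis
        epi_c = _section_polylines(epi_tm, origin, axis)
        endo_c = _section_polylines(endo_tm, origin, axis)
        hits_valve = False
        if valve_t is not None:
            hits_valve = bool(np.any(np.abs(valve_t - s) < valve_clearance))
        if len(epi_c) != 1:
            hits_valve = True  # non-simple epicardial topology at the base
        self_x = any(_is_self_intersecting(p) for p in epi_c + endo_c)
        out.append(
            SliceContours(
                plane_origin=origin,
                plane_normal=axis.copy(),
                epi_contours=epi_c,
                endo_contours=endo_c,
                hits_valve=hits_valve,
                self_intersecting=self_x,
                slice_index=i,
                normalized_position=float(s / frame.length),
                basis_u=u,
                basis_v=v,
            )
        )
    return out


def _parity_inside(contours: Sequence[np.ndarray], xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd membership of points over a set of closed contours.

    A point exactly on a contour counts as inside that contour.
    """
    count = np.zeros(xs.shape, dtype=np.int64)
    on_boundary = np.zeros(xs.shape, dtype=bool)
    for c in contours:
        if len(c) < 4:
            continue
        poly = Polygon(c)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.is_empty:
                continue
        count += shapely.contains_xy(poly, xs, ys).astype(np.int64)
        on_boundary |= shapely.intersects_xy(poly.boundary, xs, ys)
    return (count % 2 == 1) | on_boundary


def rasterize(
    contours: SliceContours,
    size: int = GRID_SIZE,
    resolution: float = RESOLUTION_MM,
    patient_id: str = "",
) -> AnatomicalMask:
    """Fill the wall region between epi and endo contours onto a pixel grid.

    A pixel is foreground iff its center lies inside an epicardial contour
    and outside every endocardial contour, by the even-odd rule with
    pixel-center sampling (a center exactly on a contour counts as inside
    that contour).  The grid is centered on the epicardial area centroid.
    """
    if contours.is_empty:
        raise GeometryError("no epicardial contour to rasterize")
    largest = max(contours.epi_contours, key=lambda c: abs(Polygon(c).area) if len(c) >= 4 else 0.0)
    cent = Polygon(largest).centroid if len(largest) >= 4 else None
    if cent is None or cent.is_empty:
        cx, cy = largest[:, 0].mean(), largest[:, 1].mean()
    else:
        cx, cy = cent.x, cent.y

    all_pts = np.vstack(contours.epi_contours)
    extent = max(
        all_pts[:, 0].max() - all_pts[:, 0].min(),
        all_pts[:, 1].max() - all_pts[:, 1].min(),
    )
    fov = size * resolution
    if extent > fov:
        raise GeometryError(
            f"contour extent {extent:.1f} mm exceeds the {fov:.0f} mm field of view"
        )

    half = (size - 1) / 2.0
    origin = np.array([cx - half * resolution, cy - half * resolution])
    coords = np.arange(size) * resolution
    X, Y = np.meshgrid(origin[0] + coords, origin[1] + coords)  # row -> y, col -> x
    xs, ys = X.ravel(), Y.ravel()

    inside_epi = _parity_inside(contours.epi_contours, xs, ys)
    inside_endo = _parity_inside(contours.endo_contours, xs, ys)
    grid = (inside_epi & ~inside_endo).reshape(size, size).astype(np.uint8)
    return AnatomicalMask(
        grid=grid,
        resolution=resolution,
        origin=origin,
        patient_id=patient_id,
        slice_index=contours.slice_index,
        normalized_position=contours.normalized_position,
    )


def filter_slice(sample: SliceSample, min_pixels: int = MIN_PIXELS) -> SliceSample:
    """Apply the exclusion rules; total and idempotent.

    A slice is excluded when its contours self-intersect, its plane hits a
    valve, or its mask has under ``min_pixels`` foreground pixels (strict).
    """
    reason = "none"
    c = sample.contours
    if c is not None and c.self_intersecting:
        reason = "self_intersecting"
    elif c is not None and c.hits_valve:
        reason = "valve"
    elif sample.mask.foreground_count < min_pixels:
        reason = "too_small"
    return replace(sample, valid=(reason == "none"), reason=reason)


def label_slice(contours: SliceContours, scar_mesh: Optional[trimesh.Trimesh]) -> int:
    """Binary ground truth: 1 iff the slice plane intersects the scar mesh."""
    if scar_mesh is None:
        return 0
    if not scar_mesh.is_watertight:
        edges = scar_mesh.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        raise GeometryError(
            f"scar mesh is open: {int((counts == 1).sum())} boundary edges"
        )
    d = (scar_mesh.vertices - contours.plane_origin) @ contours.plane_normal
    return int(d.min() <= 0.0 <= d.max())


def slice_samples(
    mesh: LVMesh,
    n_slices: int = N_SLICES,
    apex_offset: float = APEX_OFFSET,
    min_pixels: int = MIN_PIXELS,
    valve_clearance: float = VALVE_CLEARANCE_MM,
    size: int = GRID_SIZE,
    resolution: float = RESOLUTION_MM,
    scar_mesh: Optional[trimesh.Trimesh] = None,
    jitter_rng: Optional[np.random.Generator] = None,
) -> list:
    """Full per-mesh protocol: axes -> planes -> masks -> labels -> exclusions.

    ``scar_mesh`` overrides the mesh's own scar sub-mesh when given (used for
    transferred cross-modality ground truth).
    """
    frame = compute_axes(mesh)
    if scar_mesh is None:
        scar_mesh = mesh.scar_trimesh()
    samples = []
    for contours in slice_mesh(
        mesh, frame, n_slices=n_slices, apex_offset=apex_offset,
        valve_clearance=valve_clearance, jitter_rng=jitter_rng,
    ):
        if contours.is_empty:
            mask = AnatomicalMask(
                grid=np.zeros((size, size), dtype=np.uint8),
                resolution=resolution,
                patient_id=mesh.patient_id,
                slice_index=contours.slice_index,
                normalized_position=contours.normalized_position,
            )
        else:
            mask = rasterize(contours, size=size, resolution=resolution,
                             patient_id=mesh.patient_id)
        label = label_slice(contours, scar_mesh)
        samples.append(
            filter_slice(
                SliceSample(mask=mask, label=label, contours=contours),
                min_pixels=min_pixels,
            )
        )
    return samples
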