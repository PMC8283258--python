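"""Seeded synthetic LV cohorts with scar-driven wall thinning.

Clinical mesh data for this problem are restricted, so the generator
emulates what a segmentation tool emits: a closed two-surface LV shell
(truncated prolate spheroid with smooth low-order shape perturbation,
flat basal cap, valve markers on the basal rim) and, for scarred patients,
a contiguous patch where wall thickness is multiplied by a thinning factor
with a smooth taper, plus a closed mid-wall scar sub-mesh filling the
patch.  Localized thinning is the anatomical biomarker of ischemic scar
that the classifier is meant to learn.

Each patient comes as a pair: an "MRI-like" mesh carrying the scar ground
truth and a "CTA-like" re-generation of the same heart with independent
shape noise, a global volume perturbation (defaulting to a mean paired
blood-volume difference of 19 %) and a random rigid displacement that the
registration stage must undo.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import trimesh

from .geometry import LVMesh, compute_axes, label_slice, slice_mesh

__all__ = [
    "ScarSpec",
    "CohortSpec",
    "Patient",
    "Cohort",
    "generate_lv_mesh",
    "generate_cohort",
]

_TRUNCATION_DEG = 110.0  # polar angle of the basal rim, measured from the apex
_TRANSVERSE_RATIO = 0.36  # epicardial transverse semi-axis as fraction of length


@dataclass
class ScarSpec:
    """Geometry of the scarred patch.

    ``center_position`` is (apex-to-base fraction, angle in degrees); the
    cohort generator re-samples it per patient.  ``thinning_factor`` is the
    scarred-to-remote wall thickness ratio; values near 1 model recent scar
    with minimal remodeling (hard cases).
    """

    angular_extent: float = 75.0
    axial_extent: float = 0.35
    center_position: tuple = (0.45, 180.0)
    thinning_factor: float = 0.5
    shape_noise: float = 0.02

    def __post_init__(self):
        if not 0.0 < self.thinning_factor <= 1.0:
            raise ValueError("thinning_factor must be in (0, 1]")
        if self.angular_extent <= 0 or self.axial_extent <= 0:
            raise ValueError("scar extents must be positive")


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 60
    scar_prevalence: float = 0.5
    size_range: tuple = (80.0, 100.0)
    wall_thickness_range: tuple = (8.0, 12.0)
    scar_spec: ScarSpec = field(default_factory=ScarSpec)
    modality_perturbation: float = 0.19
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.scar_prevalence <= 1.0:
            raise ValueError("scar_prevalence must be in [0, 1]")
        for rng_ in (self.size_range, self.wall_thickness_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("ranges must be positive and ordered")


@dataclass
class Patient:
    """A paired synthetic patient: source ("MRI-like") and target ("CTA-like")."""

    patient_id: str
    scarred: bool
    mesh_a: LVMesh
    mesh_b: LVMesh
    labels_a: np.ndarray
    labels_b: np.ndarray
    true_transform: tuple  # (R, t) applied to mesh_b after generation
    seed: int


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)


def _smooth_field(rng: np.random.Generator, amplitude: float):
    """Random smooth periodic-in-theta field on (theta, v) from low-order modes."""
    ks = np.arange(1, 4)
    ms = np.arange(0, 3)
    amps = rng.normal(0.0, amplitude / 3.0, size=(len(ks), len(ms)))
    ph_t = rng.uniform(0, 2 * np.pi, size=(len(ks), len(ms)))
    ph_v = rng.uniform(0, 2 * np.pi, size=(len(ks), len(ms)))

    def f(theta, v):
        out = np.zeros(np.broadcast(theta, v).shape)
        for i, k in enumerate(ks):
            for j, m in enumerate(ms):
                out = out + amps[i, j] * np.cos(k * theta + ph_t[i, j]) * np.cos(
                    m * np.pi * v + ph_v[i, j]
                )
        return out

    return f

def _plateau_taper(x: np.ndarray, half_width: float, plateau: float = 0.6) -> np.ndarray:
    """1 inside ``plateau*half_width``, cosine falloff to 0 at ``half_width``."""
    ax = np.abs(x)
    out = np.zeros_like(ax, dtype=float)
    inner = ax <= plateau * half_width
    ramp = (ax > plateau * half_width) & (ax < half_width)
    out[inner] = 1.0
    t = (ax[ramp] - plateau * half_width) / ((1.0 - plateau) * half_width)
    out[ramp] = 0.5 * (1.0 + np.cos(np.pi * t))
    return out


def _angdiff(a: np.ndarray, b: float) -> np.ndarray:
    """Signed angular difference a-b wrapped to [-pi, pi)."""
    return (a - b + np.pi) % (2 * np.pi) - np.pi


def _close_grid_surface(grid: np.ndarray, apex_vertex: np.ndarray) -> tuple:
    """Triangulate an (n_phi, n_theta, 3) open-ended grid into a closed surface.

    Adds the apex pole (fan to the first ring) and a flat basal cap (fan from
    the last ring to its centroid).  Returns (vertices, faces).
    """
    n_phi, n_theta, _ = grid.shape
    verts = [apex_vertex[None, :], grid.reshape(-1, 3)]
    apex_i = 0
    ring = lambda i, j: 1 + i * n_theta + (j % n_theta)
    faces = []
    for j in range(n_theta):
        faces.append([apex_i, ring(0, j), ring(0, j + 1)])
    for i in range(n_phi - 1):
        for j in range(n_theta):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    rim_center = grid[-1].mean(axis=0)
    ci = 1 + n_phi * n_theta
    verts.append(rim_center[None, :])
    for j in range(n_theta):
        faces.append([ring(n_phi - 1, j), ci, ring(n_phi - 1, j + 1)])
    faces = np.asarray(faces, dtype=np.int64)[:, [0, 2, 1]]  # outward winding
    return np.vstack(verts), faces


def _closed_slab(outer: np.ndarray, inner: np.ndarray) -> tuple:
    """Close two (m, n, 3) sheets into a watertight slab (vertices, faces)."""
    m, n, _ = outer.shape
    verts = np.vstack([outer.reshape(-1, 3), inner.reshape(-1, 3)])
    O = lambda i, j: i * n + j
    I = lambda i, j: m * n + i * n + j
    faces = []
    for i in range(m - 1):
        for j in range(n - 1):
            faces += [[O(i, j), O(i, j + 1), O(i + 1, j)],
                      [O(i, j + 1), O(i + 1, j + 1), O(i + 1, j)]]
            faces += [[I(i, j), I(i + 1, j), I(i, j + 1)],
                      [I(i, j + 1), I(i + 1, j), I(i + 1, j + 1)]]
    for j in range(n - 1):  # axial edges
        faces += [[O(0, j), I(0, j), O(0, j + 1)], [I(0, j), I(0, j + 1), O(0, j + 1)]]
        faces += [[O(m - 1, j), O(m - 1, j + 1), I(m - 1, j)],
                  [I(m - 1, j), O(m - 1, j + 1), I(m - 1, j + 1)]]
    for i in range(m - 1):  # angular edges
        faces += [[O(i, 0), O(i + 1, 0), I(i, 0)], [I(i, 0), O(i + 1, 0), I(i + 1, 0)]]
        faces += [[O(i, n - 1), I(i, n - 1), O(i + 1, n - 1)],
                  [I(i, n - 1), I(i + 1, n - 1), O(i + 1, n - 1)]]
    return verts, np.asarray(faces, dtype=np.int64)


def generate_lv_mesh(
    spec: CohortSpec,
    scarred: bool,
    seed: int,
    scar_spec: Optional[ScarSpec] = None,
    scale: float = 1.0,
    patient_id: str = "synthetic",
    n_theta: int = 96,
    n_phi: int = 40,
) -> LVMesh:
    """One closed two-surface LV shell, optionally with a thinned scar patch.

    Bit-reproducible from ``seed``.  ``scale`` applies an isotropic global
    size factor (used for inter-modality volume perturbation).
    """
    rng = np.random.default_rng(seed)
    scar = scar_spec if scar_spec is not None else spec.scar_spec
    length = rng.uniform(*spec.size_range) * scale
    t0 = rng.uniform(*spec.wall_thickness_range) * scale
    if scarred and scar.thinning_factor * t0 <= 0:
        raise ValueError("thinning produces non-positive wall thickness")
    shape = _smooth_field(rng, scar.shape_noise)
    thick_mod = _smooth_field(rng, 0.05)

    phi_t = np.deg2rad(_TRUNCATION_DEG)
    c = length / (1.0 - np.cos(phi_t))  # apex at z=-c, rim at z=-c*cos(phi_t)
    a = _TRANSVERSE_RATIO * length

    phi = np.linspace(np.pi / n_phi, phi_t, n_phi)  # from near-apex to rim
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    TH, PH = np.meshgrid(theta, phi)
    z = -c * np.cos(PH)
    v_frac = (z - (-c)) / length  # 0 at apex, 1 at base rim
    rho = 1.0 + shape(TH, v_frac)

    ex = a * rho * np.sin(PH) * np.cos(TH)
    ey = a * rho * np.sin(PH) * np.sin(TH)
    epi_grid = np.stack([ex, ey, z], axis=-1)

    # outward spheroid normal (unperturbed reference shape)
    nx = np.sin(PH) * np.cos(TH) / a
    ny = np.sin(PH) * np.sin(TH) / a
    nz = -np.cos(PH) / c
    nrm = np.stack([nx, ny, nz], axis=-1)
    nrm /= np.linalg.norm(nrm, axis=-1, keepdims=True)

    thickness = t0 * (1.0 + thick_mod(TH, v_frac))
    if scarred:
        vc, ang = scar.center_position
        half_v = scar.axial_extent / 2.0
        half_a = np.deg2rad(scar.angular_extent) / 2.0
        bump = _plateau_taper(v_frac - vc, half_v) * _plateau_taper(
            _angdiff(TH, np.deg2rad(ang)), half_a
        )
        thickness = thickness * (1.0 - (1.0 - scar.thinning_factor) * bump)
    if np.any(thickness <= 0):
        raise ValueError("thinning produced non-positive wall thickness")

    endo_grid = epi_grid - thickness[..., None] * nrm

    apex_epi = np.array([0.0, 0.0, -c])
    apex_endo = apex_epi + np.array([0.0, 0.0, thickness[0].mean()])
    epi_v, epi_f = _close_grid_surface(epi_grid, apex_epi)
    endo_v, endo_f = _close_grid_surface(endo_grid, apex_endo)

    scar_v = scar_f = None
    if scarred:
        vc, ang = scar.center_position
        half_v = scar.axial_extent / 2.0
        half_a = np.deg2rad(scar.angular_extent) / 2.0
        m, n = 12, 16
        # patch parameterized on its own (v, angle) subgrid via phi inversion
        v_lo, v_hi = vc - half_v, vc + half_v
        cosphi = np.clip(1.0 - np.array(np.linspace(v_lo, v_hi, m)) * length / c, -1.0, 1.0)
        phi_p = np.arccos(cosphi)
        th_p = np.deg2rad(ang) + np.linspace(-half_a, half_a, n)
        THp, PHp = np.meshgrid(th_p, phi_p)
        zp = -c * np.cos(PHp)
        vfp = (zp + c) / length
        rhop = 1.0 + shape(THp, vfp)
        ep = np.stack(
            [a * rhop * np.sin(PHp) * np.cos(THp), a * rhop * np.sin(PHp) * np.sin(THp), zp],
            axis=-1,
        )
        npx = np.sin(PHp) * np.cos(THp) / a
        npy = np.sin(PHp) * np.sin(THp) / a
        npz = -np.cos(PHp) / c
        nn = np.stack([npx, npy, npz], axis=-1)
        nn /= np.linalg.norm(nn, axis=-1, keepdims=True)
        tp = t0 * (1.0 + thick_mod(THp, vfp))
        tp = tp * (1.0 - (1.0 - scar.thinning_factor) * _plateau_taper(vfp - vc, half_v)
                   * _plateau_taper(_angdiff(THp, np.deg2rad(ang)), half_a))
        outer = ep - 0.30 * tp[..., None] * nn
        inner = ep - 0.70 * tp[..., None] * nn
        scar_v, scar_f = _closed_slab(outer, inner)
        stm = trimesh.Trimesh(scar_v, scar_f, process=False)
        stm.fix_normals()
        scar_v, scar_f = np.asarray(stm.vertices), np.asarray(stm.faces)

    rim = epi_grid[-1]
    valve_idx = [int(np.argmin(np.abs(_angdiff(theta, np.deg2rad(d))))) for d in (30.0, 120.0, 240.0)]
    valve_points = rim[valve_idx].copy()

    return LVMesh(
        patient_id=patient_id,
        epi_vertices=epi_v,
        epi_faces=epi_f,
        endo_vertices=endo_v,
        endo_faces=endo_f,
        scar_vertices=scar_v,
        scar_faces=scar_f,
        valve_points=valve_points,
    )


def _random_rigid(rng: np.random.Generator) -> tuple:
    ax = rng.normal(size=3)
    ax /= np.linalg.norm(ax)
    ang = rng.uniform(np.deg2rad(5.0), np.deg2rad(25.0))
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    t = rng.uniform(-15.0, 15.0, size=3)
    return R, t


def _apply_rigid(mesh: LVMesh, R: np.ndarray, t: np.ndarray) -> LVMesh:
    f = lambda v: None if v is None else v @ R.T + t
    return replace(
        mesh,
        epi_vertices=f(mesh.epi_vertices),
        endo_vertices=f(mesh.endo_vertices),
        scar_vertices=f(mesh.scar_vertices),
        valve_points=f(mesh.valve_points),
    )


def _native_labels(mesh: LVMesh, n_slices: int = 25) -> np.ndarray:
    frame = compute_axes(mesh)
    scar = mesh.scar_trimesh()
    return np.array(
        [label_slice(sc, scar) for sc in slice_mesh(mesh, frame, n_slices=n_slices)],
        dtype=np.int64,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Paired cohort with ``ceil(n * prevalence)`` scarred patients.

    Per patient: an "MRI-like" mesh, a "CTA-like" re-generation with
    independent shape noise and an isotropic volume perturbation drawn so the
    paired blood-volume difference has mean magnitude ``modality_perturbation``,
    displaced by a random rigid transform.  Per-slice labels come from the
    slicing protocol applied to each mesh's own scar sub-mesh.
    """
    n_scarred = int(np.ceil(spec.n_patients * spec.scar_prevalence))
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_patients)
    # half-normal |dV|/V with mean = modality_perturbation
    sigma = spec.modality_perturbation * np.sqrt(np.pi / 2.0)
    patients = []
    for i in range(spec.n_patients):
        pid = f"p{i:03d}"
        scarred = i < n_scarred
        child = children[i]
        seeds = child.generate_state(4)
        prng = np.random.default_rng(seeds[3])
        scar_spec = replace(
            spec.scar_spec,
            center_position=(prng.uniform(0.30, 0.62), prng.uniform(0.0, 360.0)),
        )
        # patient-level anatomy is shared by the pair; only the modality
        # perturbation and the smooth shape noise differ between the scans
        length = prng.uniform(*spec.size_range)
        t0 = prng.uniform(*spec.wall_thickness_range)
        pspec = replace(
            spec, size_range=(length, length), wall_thickness_range=(t0, t0)
        )
        mesh_a = generate_lv_mesh(
            pspec, scarred, int(seeds[0] % (2**31)), scar_spec=scar_spec,
            patient_id=pid,
        )
        dv = prng.normal(0.0, sigma)
        dv = float(np.clip(dv, -0.6, 0.6))
        scale = (1.0 + dv) ** (1.0 / 3.0)
        mesh_b = generate_lv_mesh(
            pspec, scarred, int(seeds[1] % (2**31)), scar_spec=scar_spec,
            scale=scale, patient_id=pid,
        )
        R, t = _random_rigid(np.random.default_rng(seeds[2]))
        mesh_b = _apply_rigid(mesh_b, R, t)
        patients.append(
            Patient(
                patient_id=pid,
                scarred=scarred,
                mesh_a=mesh_a,
                mesh_b=mesh_b,
                labels_a=_native_labels(mesh_a),
                labels_b=_native_labels(mesh_b),
                true_transform=(R, t),
                seed=int(seeds[0] % (2**31)),
            )
        )
    return Cohort(spec=spec, patients=patients)


def blood_volume(mesh: LVMesh) -> float:
    """Blood-pool volume in mm^3 (volume enclosed by the endocardial surface)."""
    tm = mesh.endo_trimesh()
    return float(abs(tm.volume))
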