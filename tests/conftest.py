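"""Shared fixtures: analytic masks, spheroid shells, and a small cohort."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from lvscar.geometry import GRID_SIZE, AnatomicalMask, LVMesh
from lvscar.synthetic import CohortSpec, generate_cohort


def annulus_grid(
    center=(127.5, 127.5),
    r_in=20.0,
    r_out=30.0,
    size=GRID_SIZE,
    thin_sector=None,
):
    """Analytic annulus membership mask on pixel centers (origin at 0 mm).

    ``thin_sector=(angle_deg, width_deg, inner_radius)`` moves the inner
    radius outward over an angular sector, thinning the wall there.
    """
    xs, ys = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float))
    dx, dy = xs - center[0], ys - center[1]
    r = np.hypot(dx, dy)
    inner = np.full_like(r, r_in)
    if thin_sector is not None:
        ang0, width, r_in_sector = thin_sector
        ang = np.degrees(np.arctan2(dy, dx)) % 360.0
        d = np.abs((ang - ang0 + 180.0) % 360.0 - 180.0)
        inner = np.where(d <= width / 2.0, r_in_sector, inner)
    return ((r >= inner) & (r <= r_out)).astype(np.uint8)


def annulus_mask(center=(127.5, 127.5), r_in=20.0, r_out=30.0, size=GRID_SIZE, **kw):
    return AnatomicalMask(grid=annulus_grid(center, r_in, r_out, size, **kw))


def circle_polyline(radius: float, center=(0.0, 0.0), n: int = 256) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n + 1)
    return np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])


def spheroid_shell(
    semi_axes_epi=(45.0, 25.0, 25.0),
    semi_axes_endo=(40.0, 20.0, 20.0),
    rotation=None,
    patient_id="spheroid",
    subdivisions=3,
) -> LVMesh:
    """Closed two-surface prolate spheroid shell from a subdivided icosphere."""
    def surf(axes):
        tm = trimesh.creation.icosphere(subdivisions=subdivisions)
        v = tm.vertices * np.asarray(axes)
        if rotation is not None:
            v = v @ np.asarray(rotation).T
        return np.asarray(v, dtype=float), np.asarray(tm.faces, dtype=np.int64)

    ev, ef = surf(semi_axes_epi)
    nv, nf = surf(semi_axes_endo)
    return LVMesh(
        patient_id=patient_id,
        epi_vertices=ev, epi_faces=ef,
        endo_vertices=nv, endo_faces=nf,
    )


@pytest.fixture(scope="session")
def cohort12():
    """A small paired cohort reused by the slower integration tests."""
    return generate_cohort(CohortSpec(n_patients=12, seed=7))


@pytest.fixture(scope="session")
def scarred_mesh(cohort12):
    return cohort12.patients[0].mesh_a


@pytest.fixture(scope="session")
def plain_mesh(cohort12):
    return cohort12.patients[-1].mesh_a
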