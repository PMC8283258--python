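"""Rigid ICP registration of paired LV meshes and scar-mesh transfer.

Paired scans of the same heart in two modalities are brought into one frame
so that the scar segmentation available in the source modality can stand in
as ground truth for the target modality.  Initialization aligns the two
long-axis frames (apex to apex, long axis onto long axis, roll resolved from
the valve markers); refinement is standard point-to-point ICP on the
epicardial vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import LVMesh, compute_axes

__all__ = ["RigidTransform", "icp_register", "transfer_scar"]


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray
    converged: bool = True
    n_iterations: int = 0
    residuals: list = field(default_factory=list)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> R_s (R_o x + t_o) + t_s."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @property
    def mean_residual(self) -> float:
        return self.residuals[-1] if self.residuals else float("nan")

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "mean_residual_mm": self.mean_residual,
        }


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any axis orthogonal to a
        axis = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            axis = np.array([0.0, 1.0, 0.0])
        axis -= a * np.dot(axis, a)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * (K @ K)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    s2 = float(np.dot(v, v))
    return np.eye(3) + K + K @ K * ((1.0 - c) / s2)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    ax = axis / np.linalg.norm(axis)
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _initialize(source: LVMesh, target: LVMesh) -> RigidTransform:
    """Axis + valve-roll initialization: apex to apex, axis onto axis."""
    fs, ft = compute_axes(source), compute_axes(target)
    R = _rotation_between(fs.long_axis, ft.long_axis)
    if (
        source.valve_points is not None
        and target.valve_points is not None
        and len(source.valve_points) > 0
        and len(target.valve_points) > 0
    ):
        # roll about the target axis from the first valve-marker correspondence
        u_axis = ft.long_axis

        def roll_angle(p, apex, axis):
            w = p - apex
            w = w - np.dot(w, axis) * axis
            return w / max(np.linalg.norm(w), 1e-12)

        ws = roll_angle(R @ (source.valve_points[0] - fs.apex_point), np.zeros(3), u_axis)
        wt = roll_angle(target.valve_points[0] - ft.apex_point, np.zeros(3), u_axis)
        ang = np.arctan2(np.dot(np.cross(ws, wt), u_axis), np.dot(ws, wt))
        R = _axis_rotation(u_axis, float(ang)) @ R
    t = ft.apex_point - R @ fs.apex_point
    return RigidTransform(rotation=R, translation=t)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple:
    """Least-squares rigid transform taking P onto Q (row-wise points)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def icp_register(
    source: LVMesh,
    target: LVMesh,
    max_iterations: int = 200,
    tolerance: float = 1e-4,
    translation_only: bool = False,
) -> RigidTransform:
    """Point-to-point ICP on epicardial vertices after axis/valve initialization.

    Iterates closest-point correspondence (k-d tree on the target vertices)
    and least-squares rigid refit until the mean closest-point distance
    changes by less than ``tolerance`` mm or ``max_iterations`` is reached.
    With ``translation_only`` the per-iteration refit updates the translation
    alone (the rotation stays at its initialized value).
    """
    init = _initialize(source, target)
    P0 = np.asarray(source.epi_vertices, dtype=float)
    Q = np.asarray(target.epi_vertices, dtype=float)
    tree = cKDTree(Q)
    R, t = init.rotation.copy(), init.translation.copy()
    residuals = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        P = P0 @ R.T + t
        d, idx = tree.query(P)
        # RMS is the quantity the alternating minimization is monotone in
        mean_d = float(np.sqrt(np.mean(d**2)))
        residuals.append(mean_d)
        if abs(prev - mean_d) < tolerance:
            converged = True
            break
        prev = mean_d
        matched = Q[idx]
        if translation_only:
            t = t + (matched - P).mean(axis=0)
        else:
            dR, dt = _kabsch(P, matched)
            R = dR @ R
            t = dR @ t + dt
    if not converged:
        warnings.warn(
            f"ICP did not converge in {max_iterations} iterations "
            f"(last mean distance {residuals[-1]:.4f} mm)",
            stacklevel=2,
        )
    return RigidTransform(
        rotation=R,
        translation=t,
        converged=converged,
        n_iterations=it,
        residuals=residuals,
    )


def transfer_scar(
    scar_vertices: np.ndarray,
    scar_faces: np.ndarray,
    transform: RigidTransform,
) -> tuple:
    """Map a scar mesh into the target frame; topology unchanged."""
    return transform.apply(np.asarray(scar_vertices, dtype=float)), np.asarray(scar_faces)
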