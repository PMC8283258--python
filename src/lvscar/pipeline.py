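"""End-to-end flows: training (meshes -> CV -> final model) and paired-cohort
testing (registration -> scar transfer -> prediction), with manifests.

The training flow mirrors the protocol: long/short axes by PCA, 25
short-axis planes from 20 % above the apex to the base, 256x256 anatomical
masks, exclusion rules, polar encoding, patient-wise cross-validation, and
a final retrain on the full training set.  The test flow never lets the
model see test data: a content-fingerprint intersection between the
training and test sets is a hard error.  Test-set ground truth is
estimated, as in the paired-scan design, by rigidly registering each
source mesh onto its target and transferring the scar sub-mesh.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import __version__
from .classifier import CVResult, SliceDataset, cross_validate, predict, train
from .config import default_config, network_spec_from, train_config_from
from .evaluation import EvalReport, evaluate
from .geometry import LVMesh, slice_samples
from .nn import build_network
from .polar import to_polar
from .registration import icp_register, transfer_scar
from .synthetic import Cohort

__all__ = [
    "PipelineError",
    "TrainingRun",
    "TestRun",
    "mesh_fingerprint",
    "polar_masks_for_mesh",
    "build_dataset",
    "run_training_flow",
    "run_test_flow",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and patient id."""


@dataclass
class TrainingRun:
    dataset: SliceDataset
    cv: CVResult
    model: object
    report: EvalReport
    manifest: dict
    fingerprints: set


@dataclass
class TestRun:
    dataset: SliceDataset
    report: EvalReport
    probabilities: np.ndarray
    transferred_labels: np.ndarray
    native_labels: np.ndarray = None
    manifest: dict = field(default_factory=dict)


def mesh_fingerprint(mesh: LVMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.epi_vertices, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(mesh.endo_vertices, dtype=np.float64).tobytes())
    return h.hexdigest()


def polar_masks_for_mesh(mesh: LVMesh, cfg: dict, scar_mesh=None, keep_invalid=False):
    """Slice, rasterize, label, filter and polar-encode one mesh."""
    g = cfg["geometry"]
    samples = slice_samples(
        mesh,
        n_slices=g["n_slices"],
        apex_offset=g["apex_offset"],
        min_pixels=g["min_pixels"],
        valve_clearance=g["valve_clearance_mm"],
        size=g["mask_size"],
        resolution=g["resolution_mm"],
        scar_mesh=scar_mesh,
    )
    masks = []
    n_excluded = 0
    for s in samples:
        if not s.valid and not keep_invalid:
            n_excluded += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # apical cap centroid fallback is expected
            pm = to_polar(s.mask, size=g["mask_size"])
        pm.label = s.label
        masks.append(pm)
    return masks, n_excluded


def build_dataset(meshes, cfg: dict, scar_overrides: dict | None = None):
    """SliceDataset over the retained slices of many meshes.

    ``scar_overrides`` maps patient_id -> trimesh scar surface used for
    labeling instead of the mesh's own scar (transferred ground truth).
    Patients whose slices are all excluded are dropped with a warning.
    """
    all_masks = []
    stats = {}
    for mesh in meshes:
        try:
            override = (scar_overrides or {}).get(mesh.patient_id)
            masks, n_excl = polar_masks_for_mesh(mesh, cfg, scar_mesh=override)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise PipelineError(
                f"stage=slicing patient={mesh.patient_id}: {exc}"
            ) from exc
        stats[mesh.patient_id] = {"retained": len(masks), "excluded": n_excl}
        if not masks:
            warnings.warn(
                f"patient {mesh.patient_id} has no retained slices; dropped", stacklevel=2
            )
            continue
        all_masks.extend(masks)
    if not all_masks:
        raise PipelineError("stage=slicing: no retained slices in the whole cohort")
    return SliceDataset.from_polar_masks(all_masks), stats


def run_training_flow(
    cohort: Cohort,
    cfg: dict | None = None,
    seed: int = 0,
    cv_folds: int | None = None,
    epochs: int | None = None,
    final_epochs: int | None = None,
) -> TrainingRun:
    """Meshes -> axes -> slices -> masks -> polar -> CV -> final retrain."""
    cfg = cfg or default_config()
    t0 = time.perf_counter()
    meshes = [p.mesh_a for p in cohort]
    dataset, stats = build_dataset(meshes, cfg)
    t_data = time.perf_counter() - t0

    k = cv_folds if cv_folds is not None else cfg["train"]["cv_folds"]
    config = train_config_from(cfg, seed=seed, epochs=epochs)
    spec = network_spec_from(cfg)
    t0 = time.perf_counter()
    cv = cross_validate(dataset, config, k=k, seed=seed, spec=spec)
    t_cv = time.perf_counter() - t0

    fe = final_epochs if final_epochs is not None else cfg["train"]["final_epochs"]
    t0 = time.perf_counter()
    model = build_network(spec, seed=seed)
    from dataclasses import replace as _replace

    model, _ = train(model, dataset.X, dataset.y, _replace(config, epochs=fe))
    t_final = time.perf_counter() - t0

    fingerprints = {mesh_fingerprint(m) for m in meshes}
    manifest = {
        "tool_version": __version__,
        "seed": seed,
        "config": cfg,
        "cv_folds": k,
        "epochs": config.epochs,
        "final_epochs": fe,
        "n_patients": len(meshes),
        "n_slices_retained": int(len(dataset)),
        "n_scar_slices": int(dataset.y.sum()),
        "per_patient": stats,
        "fingerprints": sorted(fingerprints),
        "report": cv.report.to_dict(),
        "timings_s": {"data": t_data, "cv": t_cv, "final_train": t_final},
    }
    return TrainingRun(
        dataset=dataset, cv=cv, model=model, report=cv.report,
        manifest=manifest, fingerprints=fingerprints,
    )


def run_test_flow(
    model,
    cohort: Cohort,
    cfg: dict | None = None,
    train_fingerprints: set | None = None,
    seed: int = 0,
) -> TestRun:
    """Paired-cohort test: register, transfer scar, predict, score.

    For each patient the source mesh (``mesh_a``) is registered onto the
    target (``mesh_b``) by ICP; the source scar sub-mesh is transferred and
    labels the target's slices.  The target meshes must be disjoint from the
    training set (fingerprint check).
    """
    cfg = cfg or default_config()
    reg = cfg["registration"]
    overrides = {}
    native = []
    for p in cohort:
        fp = mesh_fingerprint(p.mesh_b)
        if train_fingerprints and fp in train_fingerprints:
            raise PipelineError(
                f"stage=leakage-check patient={p.patient_id}: test mesh was in the training set"
            )
        if p.mesh_a.has_scar:
            try:
                tf = icp_register(
                    p.mesh_a, p.mesh_b,
                    max_iterations=reg["max_iterations"],
                    tolerance=reg["tolerance_mm"],
                    translation_only=reg["translation_only"],
                )
                sv, sf = transfer_scar(p.mesh_a.scar_vertices, p.mesh_a.scar_faces, tf)
                overrides[p.patient_id] = trimesh.Trimesh(sv, sf, process=False)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(
                    f"stage=registration patient={p.patient_id}: {exc}"
                ) from exc
        else:
            overrides[p.patient_id] = None

    dataset, stats = build_dataset([p.mesh_b for p in cohort], cfg, scar_overrides=overrides)
    # native ground truth (the target mesh's own scar) for agreement diagnostics
    labels_b = {p.patient_id: getattr(p, "labels_b", None) for p in cohort}
    native = np.array(
        [
            labels_b[pid][si] if labels_b.get(pid) is not None else 0
            for pid, si in zip(dataset.patient_ids, dataset.slice_indices)
        ],
        dtype=np.int64,
    )
    probs, calls = predict(model, dataset.X, cfg["train"]["prediction_threshold"])
    report = evaluate(
        probs, dataset.y, threshold=cfg["train"]["prediction_threshold"], seed=seed
    )
    manifest = {
        "tool_version": __version__,
        "n_patients": len(cohort),
        "n_slices_retained": int(len(dataset)),
        "per_patient": stats,
        "report": report.to_dict(),
    }
    return TestRun(
        dataset=dataset,
        report=report,
        probabilities=probs,
        transferred_labels=dataset.y.copy(),
        native_labels=native,
        manifest=manifest,
    )


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
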