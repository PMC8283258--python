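"""Slice classification: training, patient-wise CV, tuning, and a baseline.

The classifier is a VGG-style CNN over polar myocardium masks trained with
focal loss and SGD + momentum.  Cross-validation is patient-wise (all of a
patient's slices share a fold) with fold-level balancing of the scar-slice
proportion.  Hyperparameters (learning rate, momentum, batch size, focal
gamma/alpha) can be tuned by global-best particle swarm optimization.  A
minimum-wall-thickness threshold classifier is provided as the simple
anatomical baseline the CNN must beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (
    FocalLossParams,
    Network,
    NetworkSpec,
    SGD,
    build_network,
    focal_loss_and_grad,
)

__all__ = [
    "TrainConfig",
    "SwarmConfig",
    "FoldAssignment",
    "SliceDataset",
    "make_folds",
    "train",
    "predict",
    "cross_validate",
    "tune_hyperparameters",
    "pso_maximize",
    "min_wall_thickness",
    "ThicknessBaseline",
]


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the tuned headline values."""

    learning_rate: float = 0.009
    momentum: float = 0.73
    batch_size: int = 10
    epochs: int = 100
    loss: FocalLossParams = field(default_factory=FocalLossParams)
    seed: int = 0
    prediction_threshold: float = 0.5
    augment_shift: bool = False  # random circular column shift per sample
    oversample: bool = False  # per-epoch positive oversampling (off: alpha handles it)

    def __post_init__(self):
        if min(self.learning_rate, self.momentum, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, momentum, batch_size, epochs must be positive")
        if not 0.0 < self.prediction_threshold < 1.0:
            raise ValueError("prediction_threshold must be in (0, 1)")


@dataclass
class SwarmConfig:
    """Global-best PSO settings (standard constricted coefficients)."""

    n_particles: int = 20
    iterations: int = 30
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    bounds: dict = field(
        default_factory=lambda: {
            "learning_rate": (1e-4, 0.05),
            "momentum": (0.5, 0.95),
            "batch_size": (4, 32),
            "gamma": (0.0, 3.0),
            "alpha": (0.1, 0.9),
        }
    )
    seed: int = 0

    def __post_init__(self):
        if not self.bounds:
            raise ValueError("parameter bounds must be non-empty")
        for k, (lo, hi) in self.bounds.items():
            if hi < lo:
                raise ValueError(f"bounds for {k} are not ordered")


class SliceDataset:
    """Arrays of polar masks with labels, patient ids and axial positions."""

    def __init__(self, X, y, patient_ids, positions=None, slice_indices=None):
        self.X = np.asarray(X)
        self.y = np.asarray(y, dtype=np.int64)
        self.patient_ids = np.asarray(patient_ids)
        self.positions = (
            np.zeros(len(self.y)) if positions is None else np.asarray(positions, float)
        )
        self.slice_indices = (
            np.zeros(len(self.y), dtype=np.int64)
            if slice_indices is None
            else np.asarray(slice_indices, dtype=np.int64)
        )
        if not (len(self.X) == len(self.y) == len(self.patient_ids)):
            raise ValueError("dataset arrays must have equal length")

    @classmethod
    def from_polar_masks(cls, masks) -> "SliceDataset":
        return cls(
            X=np.stack([m.grid for m in masks]),
            y=[m.label for m in masks],
            patient_ids=[m.patient_id for m in masks],
            positions=[m.normalized_position for m in masks],
            slice_indices=[m.slice_index for m in masks],
        )

    def __len__(self):
        return len(self.y)

    def subset(self, idx) -> "SliceDataset":
        return SliceDataset(
            self.X[idx], self.y[idx], self.patient_ids[idx],
            self.positions[idx], self.slice_indices[idx],
        )

    @property
    def patients(self):
        return np.unique(self.patient_ids)


@dataclass
class FoldAssignment:
    """Patient-wise fold mapping with balanced scar-slice proportions."""

    mapping: dict
    k: int

    def fold_of(self, patient_id) -> int:
        return self.mapping[patient_id]

    def test_indices(self, dataset: SliceDataset, fold: int) -> np.ndarray:
        folds = np.array([self.mapping[p] for p in dataset.patient_ids])
        return np.nonzero(folds == fold)[0]

    def train_indices(self, dataset: SliceDataset, fold: int) -> np.ndarray:
        folds = np.array([self.mapping[p] for p in dataset.patient_ids])
        return np.nonzero(folds != fold)[0]


def make_folds(dataset: SliceDataset, k: int = 10, seed: int = 0,
               balance_tolerance: float = 0.10) -> FoldAssignment:
    """Greedy patient-wise partition balancing the per-fold scar fraction.

    Patients are taken in descending order of scar-slice count (seeded
    tie-breaking).  Fold patient counts are kept within one of each other;
    among the currently smallest folds each patient goes to the one holding
    the fewest scar slices (longest-processing-time heuristic), so both fold
    sizes and scar-slice proportions come out balanced.  A fold whose scar
    fraction deviates from the global fraction by more than
    ``balance_tolerance`` (relative) triggers a warning.
    """
    patients = dataset.patients
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k} folds, got {len(patients)}")
    rng = np.random.default_rng(seed)
    scar_counts = {p: int(dataset.y[dataset.patient_ids == p].sum()) for p in patients}
    tot_counts = {p: int((dataset.patient_ids == p).sum()) for p in patients}
    order = list(patients)
    rng.shuffle(order)
    order.sort(key=lambda p: -scar_counts[p])

    fold_scar = np.zeros(k)
    fold_tot = np.zeros(k)
    fold_n = np.zeros(k, dtype=int)
    mapping = {}
    for p in order:
        allowed = np.nonzero(fold_n == fold_n.min())[0]
        j = int(allowed[np.lexsort((allowed, fold_tot[allowed], fold_scar[allowed]))[0]])
        mapping[p] = j
        fold_scar[j] += scar_counts[p]
        fold_tot[j] += tot_counts[p]
        fold_n[j] += 1

    global_frac = dataset.y.mean()
    if global_frac > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            fracs = fold_scar / np.maximum(fold_tot, 1)
        rel = np.abs(fracs - global_frac) / global_frac
        if np.any(rel > balance_tolerance):
            worst = int(np.argmax(rel))
            warnings.warn(
                f"fold {worst} scar fraction {fracs[worst]:.3f} deviates more than "
                f"{balance_tolerance:.0%} from global {global_frac:.3f}",
                stacklevel=2,
            )
    return FoldAssignment(mapping=mapping, k=k)


def _as_float_batch(X: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(X, dtype=np.float32)


def train(model: Network, X: np.ndarray, y: np.ndarray, config: TrainConfig):
    """SGD training loop; returns (model, per-epoch mean loss trace)."""
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.params, config.learning_rate, config.momentum)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    trace = []
    for _ in range(config.epochs):
        if config.oversample and len(pos) < len(neg):
            extra = rng.choice(pos, size=len(neg) - len(pos), replace=True)
            idx = np.concatenate([np.arange(len(y)), extra])
        else:
            idx = np.arange(len(y))
        rng.shuffle(idx)
        losses = []
        for s in range(0, len(idx), config.batch_size):
            b = idx[s : s + config.batch_size]
            xb = _as_float_batch(X[b])
            if config.augment_shift:
                shifts = rng.integers(0, xb.shape[-1], size=len(b))
                xb = np.stack([np.roll(x, sh, axis=-1) for x, sh in zip(xb, shifts)])
            logits = model.forward(xb, train=True)
            loss, dlog = focal_loss_and_grad(logits, y[b], config.loss)
            model.backward(dlog)
            opt.step(model.grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def predict(model: Network, X: np.ndarray, threshold: float = 0.5):
    """Per-slice probabilities and binary calls (call = probability >= threshold)."""
    probs = model.predict_proba(_as_float_batch(X))
    return probs, (probs >= threshold).astype(np.int64)


@dataclass
class CVResult:
    probabilities: np.ndarray
    calls: np.ndarray
    labels: np.ndarray
    fold_of_slice: np.ndarray
    folds: FoldAssignment
    report: "object" = None
    loss_traces: list = field(default_factory=list)


def cross_validate(
    dataset: SliceDataset,
    config: TrainConfig,
    k: int = 10,
    seed: int = 0,
    spec: NetworkSpec | None = None,
    network_factory=None,
) -> CVResult:
    """Patient-wise k-fold CV; every slice is predicted exactly once out-of-fold."""
    from .evaluation import evaluate  # local import to avoid a cycle

    spec = spec or NetworkSpec()
    folds = make_folds(dataset, k=k, seed=seed)
    probs = np.full(len(dataset), np.nan)
    traces = []
    for fold in range(k):
        tr = folds.train_indices(dataset, fold)
        te = folds.test_indices(dataset, fold)
        fold_seed = (seed * 1009 + fold) % (2**31)
        if network_factory is not None:
            model = network_factory(fold_seed)
        else:
            model = build_network(spec, seed=fold_seed)
        model, trace = train(
            model, dataset.X[tr], dataset.y[tr], replace(config, seed=fold_seed)
        )
        traces.append(trace)
        probs[te] = model.predict_proba(_as_float_batch(dataset.X[te]))
    assert not np.isnan(probs).any(), "out-of-fold prediction did not cover the dataset"
    calls = (probs >= config.prediction_threshold).astype(np.int64)
    report = evaluate(probs, dataset.y, threshold=config.prediction_threshold)
    fold_of = np.array([folds.mapping[p] for p in dataset.patient_ids])
    return CVResult(
        probabilities=probs,
        calls=calls,
        labels=dataset.y.copy(),
        fold_of_slice=fold_of,
        folds=folds,
        report=report,
        loss_traces=traces,
    )


# ---------------------------------------------------------------------------
# particle swarm optimization


def pso_maximize(objective, swarm: SwarmConfig):
    """Global-best PSO over a box; returns (best position dict, best value, trace).

    Standard velocity update with inertia, cognitive and social terms;
    positions are clamped to the bounds each step.
    """
    names = list(swarm.bounds)
    lo = np.array([swarm.bounds[n][0] for n in names], dtype=float)
    hi = np.array([swarm.bounds[n][1] for n in names], dtype=float)
    rng = np.random.default_rng(swarm.seed)
    pos = rng.uniform(lo, hi, size=(swarm.n_particles, len(names)))
    vel = rng.uniform(-(hi - lo), hi - lo, size=pos.shape) * 0.1

    def eval_at(x):
        return float(objective(dict(zip(names, x))))

    pbest = pos.copy()
    pbest_val = np.array([eval_at(x) for x in pos])
    g = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
    trace = [gbest_val]
    for _ in range(swarm.iterations):
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        vel = (
            swarm.inertia * vel
            + swarm.cognitive * r1 * (pbest - pos)
            + swarm.social * r2 * (gbest - pos)
        )
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([eval_at(x) for x in pos])
        improved = vals > pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmax(pbest_val))
        if pbest_val[g] > gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        trace.append(gbest_val)
    return dict(zip(names, gbest)), gbest_val, trace


def _config_from_position(x: dict, base: TrainConfig) -> TrainConfig:
    return replace(
        base,
        learning_rate=float(x.get("learning_rate", base.learning_rate)),
        momentum=float(x.get("momentum", base.momentum)),
        batch_size=int(round(x.get("batch_size", base.batch_size))),
        loss=FocalLossParams(
            gamma=float(x.get("gamma", base.loss.gamma)),
            alpha=float(x.get("alpha", base.loss.alpha)),
        ),
    )


def tune_hyperparameters(
    dataset: SliceDataset,
    swarm: SwarmConfig,
    objective=None,
    base_config: TrainConfig | None = None,
    k: int = 5,
    tuning_epochs: int = 10,
    spec: NetworkSpec | None = None,
):
    """PSO search over training hyperparameters.

    The default objective is cross-validated accuracy at a reduced epoch
    budget.  Returns (best TrainConfig, best objective value, search trace).
    """
    base = base_config or TrainConfig()
    if objective is None:
        def objective(x):
            cfg = replace(_config_from_position(x, base), epochs=tuning_epochs)
            res = cross_validate(dataset, cfg, k=k, seed=swarm.seed, spec=spec)
            return res.report.accuracy

    best_x, best_val, trace = pso_maximize(objective, swarm)
    return _config_from_position(best_x, base), best_val, trace


# ---------------------------------------------------------------------------
# wall-thickness baseline


def min_wall_thickness(polar_grid: np.ndarray, resolution: float = 1.0) -> float:
    """Minimum radial wall thickness (mm) of a polar mask.

    Thickness at an angle is the foreground count of that column; the
    minimum is taken over columns containing any foreground.
    """
    counts = polar_grid.astype(bool).sum(axis=0)
    hit = counts > 0
    if not hit.any():
        raise ValueError("empty polar mask has no wall thickness")
    return float(counts[hit].min() * resolution)


class ThicknessBaseline:
    """Scar call when the minimum wall thickness falls below a threshold.

    The threshold is chosen to maximize training-set accuracy; scores for
    ranking (ROC) are negated thicknesses, so thinner walls rank as more
    scar-like.
    """

    def __init__(self):
        self.threshold_ = None

    @staticmethod
    def _thicknesses(X) -> np.ndarray:
        return np.array([min_wall_thickness(g) for g in X])

    def fit(self, X, y) -> "ThicknessBaseline":
        t = self._thicknesses(X)
        y = np.asarray(y)
        cand = np.unique(t)
        cand = np.concatenate([[cand[0] - 0.5], (cand[:-1] + cand[1:]) / 2, [cand[-1] + 0.5]])
        accs = [( (t < c).astype(int) == y).mean() for c in cand]
        self.threshold_ = float(cand[int(np.argmax(accs))])
        return self

    def decision_scores(self, X) -> np.ndarray:
        return -self._thicknesses(X)

    def predict(self, X) -> np.ndarray:
        if self.threshold_ is None:
            raise RuntimeError("baseline not fitted")
        return (self._thicknesses(X) < self.threshold_).astype(np.int64)
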