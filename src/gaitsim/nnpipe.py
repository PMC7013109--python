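"""Fully-connected network pipeline: flattening, training, validation.

The regressor maps one flattened gait cycle of IMU data to one flattened
cycle of joint curves.  Inputs are 5 sensors x 6 channels x 101 frames
(3,030 features); targets are 18 channels x 101 frames (1,818 outputs).
Because the network is a plain feed-forward net, time enters only through
the fixed 101-point normalization — curves are unrolled channel-major
before entering the input layer.

Architecture and schedule (defaults): two hidden layers of 4,000/6,000
units for the kinematic task (20% dropout, 12,500 steps per phase) and
6,000/4,000 for the kinetic task (40% dropout, 15,000 steps per phase);
ReLU hidden activations, linear output, MSE loss, Adam with initial
learning rate 1e-4, and a four-phase schedule with batch sizes
16-32-32-64.  A ``scale`` multiplier shrinks widths and step counts
proportionally for desk-scale runs; the full-scale values stay the config
defaults.  The implementation is a compact numpy MLP (manual
forward/backward pass) with inverted dropout and per-feature z-scoring
fitted on the training pool only.

Validation is always split by whole subject: a 5-fold scheme with a fixed
test set for hyperparameter search, and leave-one-subject-out (one fold per
subject, no validation set) for per-subject evaluation in two scenarios —
training on measured data only, or on measured plus simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalizedSample",
    "ModelConfig",
    "SplitPlan",
    "MLP",
    "flatten",
    "unflatten",
    "build_model",
    "train",
    "make_splits",
    "run_scenario",
    "N_INPUT",
    "N_OUTPUT",
    "INPUT_SHAPE",
    "TARGET_SHAPE",
]

INPUT_SHAPE = (30, 101)  # 5 sensors x 6 channels, time-normalized
TARGET_SHAPE = (18, 101)  # 18 joint curves
N_INPUT = INPUT_SHAPE[0] * INPUT_SHAPE[1]  # 3030
N_OUTPUT = TARGET_SHAPE[0] * TARGET_SHAPE[1]  # 1818


@dataclass
class NormalizedSample:
    """One time-normalized gait cycle: inputs, targets, provenance."""

    subject_id: str
    inputs: np.ndarray  # (30, 101)
    targets: np.ndarray  # (18, 101)
    source: str = "simulated"  # "measured" | "simulated"

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.shape != INPUT_SHAPE:
            raise ValueError(f"inputs must be {INPUT_SHAPE}, got {self.inputs.shape}")
        if self.targets.shape != TARGET_SHAPE:
            raise ValueError(f"targets must be {TARGET_SHAPE}, got {self.targets.shape}")
        if self.source not in ("measured", "simulated"):
            raise ValueError(f"source must be measured|simulated, got {self.source!r}")


@dataclass
class ModelConfig:
    """Architecture + schedule; defaults are the full-scale settings."""

    task: str = "kinematic"  # "kinematic" | "kinetic"
    hidden_sizes: tuple[int, int] | None = None
    dropout: float | None = None
    lr: float = 1e-4
    batch_schedule: tuple[int, ...] = (16, 32, 32, 64)
    steps_per_phase: int | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.task not in ("kinematic", "kinetic"):
            raise ValueError(f"task must be kinematic|kinetic, got {self.task!r}")
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must be in (0, 1]")
        if self.hidden_sizes is None:
            self.hidden_sizes = (4000, 6000) if self.task == "kinematic" else (6000, 4000)
        if self.dropout is None:
            self.dropout = 0.20 if self.task == "kinematic" else 0.40
        if self.steps_per_phase is None:
            self.steps_per_phase = 12_500 if self.task == "kinematic" else 15_000

    @property
    def scaled_hidden(self) -> tuple[int, int]:
        return tuple(max(int(round(h * self.scale)), 1) for h in self.hidden_sizes)

    @property
    def scaled_steps(self) -> int:
        return max(int(round(self.steps_per_phase * self.scale)), 1)


@dataclass
class SplitPlan:
    """Subject-wise fold assignments; no subject crosses partitions."""

    kind: str  # "kfold" | "loocv"
    folds: list[dict]  # each: {"train": set, "validation": set, "test": set}

    def validate(self) -> None:
        for i, fold in enumerate(self.folds):
            parts = [fold.get(k, set()) for k in ("train", "validation", "test")]
            for a in range(3):
                for b in range(a + 1, 3):
                    overlap = parts[a] & parts[b]
                    if overlap:
                        raise AssertionError(
                            f"subject leakage in fold {i}: {sorted(overlap)}"
                        )


def flatten(sample: NormalizedSample) -> tuple[np.ndarray, np.ndarray]:
    """Channel-major (row-major) unrolling to 3,030- and 1,818-vectors."""
    return sample.inputs.reshape(-1), sample.targets.reshape(-1)


def unflatten(
    input_vec: np.ndarray | None = None, target_vec: np.ndarray | None = None
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Inverse of :func:`flatten`; exact (a reshape, no copy semantics)."""
    x = y = None
    if input_vec is not None:
        input_vec = np.asarray(input_vec)
        if input_vec.shape[-1] != N_INPUT:
            raise ValueError(f"input axis must have length {N_INPUT}, got {input_vec.shape}")
        x = input_vec.reshape(input_vec.shape[:-1] + INPUT_SHAPE)
    if target_vec is not None:
        target_vec = np.asarray(target_vec)
        if target_vec.shape[-1] != N_OUTPUT:
            raise ValueError(f"target axis must have length {N_OUTPUT}, got {target_vec.shape}")
        y = target_vec.reshape(target_vec.shape[:-1] + TARGET_SHAPE)
    return x, y


class MLP:
    """Two-hidden-layer ReLU network trained with Adam on MSE.

    Weights use He-normal initialization; dropout is the inverted variant
    (active only during training).  Inputs and targets are z-scored with
    statistics from the training pool; predictions are returned on the
    original scale.  Deterministic given its seed.
    """

    def __init__(self, layer_sizes: list[int], dropout: float, seed: int = 0):
        self.layer_sizes = list(layer_sizes)
        self.dropout = float(dropout)
        self.rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            self.W.append(self.rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in))
            self.b.append(np.zeros(n_out))
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0
        # z-score statistics, fitted by `fit_scalers`
        self.x_mean = self.x_std = self.y_mean = self.y_std = None

    def fit_scalers(self, X: np.ndarray, Y: np.ndarray) -> None:
        self.x_mean = X.mean(axis=0)
        self.x_std = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
        self.y_mean = Y.mean(axis=0)
        self.y_std = np.where(Y.std(axis=0) > 1e-12, Y.std(axis=0), 1.0)

    def _forward(self, X: np.ndarray, training: bool) -> tuple[np.ndarray, list]:
        cache = []
        h = X
        n_layers = len(self.W)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            if i < n_layers - 1:
                a = np.maximum(z, 0.0)
                if training and self.dropout > 0:
                    mask = self.rng.random(a.shape) >= self.dropout
                    a = a * mask / (1.0 - self.dropout)
                else:
                    mask = None
                cache.append((h, z, mask))
                h = a
            else:
                cache.append((h, z, None))
                h = z  # linear output
        return h, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.x_mean) / self.x_std
        out, _ = self._forward(Xs, training=False)
        return out * self.y_std + self.y_mean

    def train_step(self, X: np.ndarray, Y: np.ndarray, lr: float) -> float:
        """One Adam step on a mini-batch; returns the batch MSE loss."""
        Xs = (X - self.x_mean) / self.x_std
        Ys = (Y - self.y_mean) / self.y_std
        out, cache = self._forward(Xs, training=True)
        err = out - Ys
        loss = float(np.mean(err**2))
        n_layers = len(self.W)
        grad = 2.0 * err / err.size
        gW, gb = [None] * n_layers, [None] * n_layers
        for i in reversed(range(n_layers)):
            h_in, z, mask = cache[i]
            gW[i] = h_in.T @ grad
            gb[i] = grad.sum(axis=0)
            if i > 0:
                grad = grad @ self.W[i].T
                _, z_prev, mask_prev = cache[i - 1]
                grad = grad * (z_prev > 0)
                if mask_prev is not None:
                    grad = grad * mask_prev / (1.0 - self.dropout)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.W + self.b
        grads = gW + gb
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self._adam_t)
            vhat = v / (1 - b2**self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss


def build_model(cfg: ModelConfig, seed: int = 0) -> MLP:
    """Instantiate the net: input(3030) -> h1 -> h2 -> output(1818)."""
    h1, h2 = cfg.scaled_hidden
    return MLP([N_INPUT, h1, h2, N_OUTPUT], dropout=cfg.dropout, seed=seed)


def train(
    model: MLP,
    samples: list[NormalizedSample],
    cfg: ModelConfig,
    seed: int = 0,
) -> tuple[MLP, list[dict]]:
    """Four-phase schedule with growing batch sizes; returns loss history.

    Each phase runs ``cfg.scaled_steps`` Adam steps at its batch size,
    sampling mini-batches with replacement from the training pool.  Aborts
    with diagnostics if the loss goes non-finite.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    X = np.stack([flatten(s)[0] for s in samples])
    Y = np.stack([flatten(s)[1] for s in samples])
    model.fit_scalers(X, Y)
    rng = np.random.default_rng(seed)
    history = []
    for phase, batch in enumerate(cfg.batch_schedule):
        losses = []
        for _ in range(cfg.scaled_steps):
            idx = rng.integers(0, len(samples), size=min(batch, len(samples)))
            loss = model.train_step(X[idx], Y[idx], cfg.lr)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged in phase {phase} (batch={batch}, lr={cfg.lr})"
                )
            losses.append(loss)
        history.append(
            {"phase": phase, "batch_size": batch, "steps": cfg.scaled_steps,
             "mean_loss": float(np.mean(losses)), "final_loss": losses[-1]}
        )
    return model, history


def make_splits(subjects: list[str], kind: str, seed: int = 0, n_folds: int = 5,
                test_fraction: float = 0.2) -> SplitPlan:
    """Subject-wise split plans.

    ``kfold``: one fixed test set (``test_fraction`` of subjects) plus
    ``n_folds`` rotating validation folds over the remainder.  ``loocv``:
    one fold per subject with that subject as the test set and no
    validation set (hyperparameters are fixed beforehand).
    """
    subjects = list(dict.fromkeys(subjects))
    if kind == "kfold":
        if len(subjects) < 3:
            raise ValueError("k-fold needs at least 3 subjects")
        rng = np.random.default_rng(seed)
        order = list(rng.permutation(subjects))
        n_test = max(int(round(test_fraction * len(order))), 1)
        test = set(order[:n_test])
        rest = order[n_test:]
        folds = []
        chunks = np.array_split(np.arange(len(rest)), n_folds)
        for chunk in chunks:
            val = {rest[i] for i in chunk}
            folds.append(
                {"train": set(rest) - val, "validation": val, "test": set(test)}
            )
        plan = SplitPlan(kind="kfold", folds=folds)
    elif kind == "loocv":
        if len(subjects) < 2:
            raise ValueError("leave-one-out needs at least 2 subjects")
        folds = [
            {"train": set(subjects) - {s}, "validation": set(), "test": {s}}
            for s in subjects
        ]
        plan = SplitPlan(kind="loocv", folds=folds)
    else:
        raise ValueError(f"kind must be kfold|loocv, got {kind!r}")
    plan.validate()
    return plan


def run_scenario(
    samples: list[NormalizedSample],
    scenario: str,
    plan: SplitPlan,
    cfg: ModelConfig,
    seed: int = 0,
) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Leave-one-subject-out evaluation under a training-pool scenario.

    ``measured_only`` trains on measured samples of the fold's training
    subjects; ``combined`` adds the simulated samples of those subjects.
    The held-out subject's measured samples are predicted; returns, per test
    subject, a list of ``(predicted, truth)`` pairs of 18x101 curve
    matrices.
    """
    if scenario not in ("measured_only", "combined"):
        raise ValueError(f"scenario must be measured_only|combined, got {scenario!r}")
    plan.validate()
    predictions: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for fold_i, fold in enumerate(plan.folds):
        train_subjects, test_subjects = fold["train"], fold["test"]
        pool = [
            s for s in samples
            if s.subject_id in train_subjects
            and (s.source == "measured" or scenario == "combined")
        ]
        test_samples = [
            s for s in samples if s.subject_id in test_subjects and s.source == "measured"
        ]
        # leakage guard: held-out subjects must never enter the pool
        assert not any(s.subject_id in test_subjects for s in pool)
        if not pool or not test_samples:
            continue
        model = build_model(cfg, seed=seed + fold_i)
        model, _ = train(model, pool, cfg, seed=seed + 1000 + fold_i)
        X_test = np.stack([flatten(s)[0] for s in test_samples])
        pred = model.predict(X_test)
        for s, p in zip(test_samples, pred):
            _, curves = unflatten(target_vec=p)
            predictions.setdefault(s.subject_id, []).append((curves, s.targets))
    return predictions
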