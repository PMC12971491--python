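"""Supervised Hebbian readout of a neural code on random linear tasks.

Tasks are binary shatterings of the latent space: each task is a hyperplane
through the origin with Gaussian normal vector T, and the label of a sample
with latents z is sign(T . z). The readout weight for a task is the
label-weighted mean of the training responses,

    w = (1/p) sum_mu y_mu x_mu,

and predictions are sign(w . x). For balanced labels this is exactly the
difference-of-means classifier. ``monte_carlo_error`` estimates the
task-averaged generalization error of this rule under a Gaussian code, the
empirical counterpart of :func:`latentgeom.metrics.theoretical_error`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .code import GaussianCode

__all__ = [
    "TaskBattery",
    "LabeledDataset",
    "sample_tasks",
    "make_labels",
    "hebbian_weights",
    "predict",
    "empirical_task_error",
    "monte_carlo_error",
    "MonteCarloResult",
]


@dataclass(frozen=True)
class TaskBattery:
    """A batch of random linear tasks: rows are hyperplane normals T."""

    teachers: np.ndarray  # (n_tasks, d)
    seed: int | None = None

    @property
    def n_tasks(self) -> int:
        return self.teachers.shape[0]

    @property
    def d(self) -> int:
        return self.teachers.shape[1]


@dataclass(frozen=True)
class LabeledDataset:
    """Paired responses X (p x n), latents Z (p x d) and labels Y (p x n_tasks)."""

    X: np.ndarray
    Z: np.ndarray
    Y: np.ndarray

    @property
    def p(self) -> int:
        return self.X.shape[0]

    def class_balance(self) -> np.ndarray:
        """Fraction of +1 labels per task (diagnostic; the rule never rebalances)."""
        return np.mean(self.Y > 0, axis=0)


def sample_tasks(d: int, n_tasks: int, rng: np.random.Generator) -> TaskBattery:
    """Draw n_tasks hyperplane normals i.i.d. standard Gaussian in d dims."""
    if d < 1 or n_tasks < 1:
        raise ValueError("d and n_tasks must be >= 1")
    teachers = rng.standard_normal((n_tasks, d))
    # an exactly-zero row has probability zero but would make a task undefined
    bad = ~np.any(teachers != 0.0, axis=1)
    while np.any(bad):  # pragma: no cover - probability-zero branch
        teachers[bad] = rng.standard_normal((bad.sum(), d))
        bad = ~np.any(teachers != 0.0, axis=1)
    return TaskBattery(teachers=teachers)


def _sign(a: np.ndarray) -> np.ndarray:
    """sign with the deterministic tie rule sign(0) = +1."""
    return np.where(a >= 0.0, 1.0, -1.0)


def make_labels(Z: np.ndarray, battery: TaskBattery) -> np.ndarray:
    """Labels Y[mu, t] = sign(T_t . z_mu), entries in {-1, +1}."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != battery.d:
        raise ValueError(
            f"latent dimension {Z.shape[1]} != task dimension {battery.d}"
        )
    return _sign(Z @ battery.teachers.T)


def hebbian_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Supervised Hebbian weights w = (1/p) sum_mu y_mu x_mu.

    ``y`` may be a vector (one task) or a (p, n_tasks) matrix, in which case
    one weight column per task is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if y.shape[0] != X.shape[0]:
        raise ValueError("label count does not match sample count")
    if y.ndim == 1:
        return X.T @ y / X.shape[0]
    return X.T @ y / X.shape[0]


def predict(w: np.ndarray, X_test: np.ndarray) -> np.ndarray:
    """Readout predictions sign(w . x), entries in {-1, +1}."""
    return _sign(np.asarray(X_test, dtype=float) @ np.asarray(w, dtype=float))


def empirical_task_error(
    train: LabeledDataset, test: LabeledDataset
) -> tuple[np.ndarray, float, float]:
    """Per-task test error of the Hebbian rule, its mean and SEM over tasks.

    Train and test must share the same task battery (matching label columns).
    """
    if test.p == 0:
        raise ValueError("empty test set")
    if train.Y.shape[1] != test.Y.shape[1]:
        raise ValueError("train and test label matrices use different batteries")
    W = hebbian_weights(train.X, train.Y)  # (n, n_tasks)
    preds = predict(W, test.X)  # (p_test, n_tasks)
    per_task = np.mean(preds != test.Y, axis=0)
    mean = float(per_task.mean())
    sem_tasks = float(per_task.std(ddof=1) / np.sqrt(per_task.size)) \
        if per_task.size > 1 else float("nan")
    return per_task, mean, sem_tasks


@dataclass(frozen=True)
class MonteCarloResult:
    """Monte-Carlo estimate of the task-averaged generalization error."""

    mean: float
    sem: float          # over repeats (acceptance comparisons use this one)
    per_repeat: np.ndarray
    sem_tasks: float    # average over repeats of the across-task SEM
    class_balance: float  # mean fraction of +1 labels (diagnostic)


def sample_joint(
    code: GaussianCode, p: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw p paired (x, z) samples from the zero-mean Gaussian model."""
    joint = code.joint_covariance()
    # eigendecomposition handles the (common) rank-deficient noiseless case
    w, v = np.linalg.eigh(joint)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    draws = rng.standard_normal((p, joint.shape[0])) @ root.T
    Z = draws[:, : code.d]
    X = draws[:, code.d:]
    return X, Z


def monte_carlo_error(
    code: GaussianCode,
    p: int,
    n_tasks: int = 300,
    n_test: int = 1000,
    n_repeats: int = 30,
    rng: np.random.Generator | None = None,
) -> MonteCarloResult:
    """Empirical task-averaged Hebbian error under a Gaussian code.

    Each repeat draws a fresh task battery, fresh training pairs and fresh
    test pairs from the model, trains the Hebbian rule per task and measures
    the mean test error over tasks. The mean and SEM over repeats are
    returned; the across-task SEM is reported as a secondary diagnostic.
    """
    if rng is None:
        rng = np.random.default_rng()
    if min(p, n_tasks, n_test, n_repeats) < 1:
        raise ValueError("all counts must be >= 1")
    errors = np.empty(n_repeats)
    task_sems = np.empty(n_repeats)
    balances = np.empty(n_repeats)
    for r in range(n_repeats):
        battery = sample_tasks(code.d, n_tasks, rng)
        X_tr, Z_tr = sample_joint(code, p, rng)
        X_te, Z_te = sample_joint(code, n_test, rng)
        train = LabeledDataset(X=X_tr, Z=Z_tr, Y=make_labels(Z_tr, battery))
        test = LabeledDataset(X=X_te, Z=Z_te, Y=make_labels(Z_te, battery))
        _, errors[r], task_sems[r] = empirical_task_error(train, test)
        balances[r] = train.class_balance().mean()
    sem = float(errors.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 \
        else float("nan")
    return MonteCarloResult(
        mean=float(errors.mean()),
        sem=sem,
        per_repeat=errors,
        sem_tasks=float(np.nanmean(task_sems)),
        class_balance=float(balances.mean()),
    )
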