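"""Training objective: frame-aligned point error, Gaussian KL, staged weights, data split.

The reconstruction loss is the backbone frame-aligned point error (FAPE):
every backbone atom of the prediction and of the ground truth is expressed
in every residue's local frame, and the mean Euclidean distance between
the two local-coordinate sets is taken over all (frame, atom) pairs.
Because both sides are expressed in their own local frames, the loss is
invariant to rigid motion of either structure.

The KL regularizer is the standard closed-form divergence between the
per-residue posterior N(mu, sigma^2) and the unit normal, averaged over
entries.  Its weight follows a staged annealing schedule (small early to
avoid posterior collapse, large late to shape the latent space for
sampling), while the reconstruction weight is stepped down once the
backbone is mostly learned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .ensemble import BackboneConformation, Ensemble

__all__ = [
    "TrainingSchedule",
    "SplitSpec",
    "fape_loss",
    "kl_loss",
    "loss_weights",
    "total_loss",
    "split_dataset",
]

_FRAME_EPS = 1e-12


def _frames_and_points(coords: Tensor, eps: float) -> tuple[Tensor, Tensor, Tensor]:
    """Residue frames (rotations + origins) and flat atom points from (B, L, 3, 3)."""
    B, L = coords.shape[0], coords.shape[1]
    n = coords[:, :, 0, :]
    ca = coords[:, :, 1, :]
    c = coords[:, :, 2, :]
    ab = ca - n
    bc = c - ca
    nz = ag.cross(ab, bc)
    nz = nz / ((nz * nz).sum(axis=-1, keepdims=True) + eps).sqrt()
    nx = bc / ((bc * bc).sum(axis=-1, keepdims=True) + eps).sqrt()
    ny = ag.cross(nz, nx)
    rot = ag.concat(
        [nx.reshape(B, L, 1, 3), ny.reshape(B, L, 1, 3), nz.reshape(B, L, 1, 3)],
        axis=2,
    )  # rows are the axes: rot @ v projects v into the frame
    points = coords.reshape(B, 3 * L, 3)
    return rot, ca, points


def local_coordinates(coords: Tensor | np.ndarray, eps: float = _FRAME_EPS) -> Tensor:
    """All atoms of each conformation expressed in all of its residue frames.

    Input (B, L, 3, 3); output (B, L, 3L, 3): entry [b, i, j] is atom j of
    conformation b in the frame of residue i.
    """
    coords = ag.as_tensor(coords)
    B, L = coords.shape[0], coords.shape[1]
    rot, origin, points = _frames_and_points(coords, eps)
    diff = points.reshape(B, 1, 3 * L, 3) - origin.reshape(B, L, 1, 3)
    return diff @ rot.transpose(0, 1, 3, 2)


def fape_tensor(
    pred: Tensor,
    truth_local: np.ndarray,
    clamp: float | None = None,
    eps: float = _FRAME_EPS,
) -> Tensor:
    """Differentiable FAPE of predicted coordinates against precomputed
    ground-truth local coordinates (B, L, 3L, 3)."""
    delta = local_coordinates(pred, eps) - Tensor(truth_local)
    dist = ((delta * delta).sum(axis=-1) + eps).sqrt()
    if clamp is not None:
        # min(d, clamp) = clamp - relu(clamp - d)
        dist = clamp - (clamp - dist).relu()
    return dist.mean()


def fape_loss(
    pred: BackboneConformation,
    truth: BackboneConformation,
    clamp: float | None = None,
) -> float:
    """Backbone FAPE between two conformations, Å (non-negative, SE(3)-invariant)."""
    if pred.sequence != truth.sequence:
        raise ValueError("pred and truth must share one sequence")
    p = Tensor(pred.coords[None])
    t = np.asarray(local_coordinates(truth.coords[None], eps=0.0).value)
    return float(fape_tensor(p, t, clamp=clamp, eps=0.0).item())


def kl_loss(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Entry-mean Gaussian KL divergence to the standard normal.

    KL(N(mu, sigma^2) || N(0, 1)) per entry = (mu^2 + sigma^2 - 1 - log sigma^2)/2.
    """
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar must share a shape")
    return float(0.5 * np.mean(mu**2 + np.exp(logvar) - 1.0 - logvar))


def kl_tensor(mu: Tensor, logvar: Tensor) -> Tensor:
    """Differentiable counterpart of :func:`kl_loss`."""
    return ((mu * mu + logvar.exp() - 1.0 - logvar) * 0.5).mean()


@dataclass(frozen=True)
class TrainingSchedule:
    """Staged loss weights, iteration budget and optimizer settings.

    Stage lengths are fractions of ``total_iterations``, so the staging
    shape is preserved when the budget is rescaled from the full-size run
    (reconstruction 10.0 for the first 3/4 then 1.0; KL annealed
    1e-4 -> 0.1 over six equal stages plus a final double-length stage).
    """

    recon_stages: tuple = ((10.0, 0.75), (1.0, 0.25))
    kl_stages: tuple = (
        (1e-4, 0.125), (5e-4, 0.125), (1e-3, 0.125), (5e-3, 0.125),
        (0.01, 0.125), (0.05, 0.125), (0.1, 0.25),
    )
    total_iterations: int = 400_000
    batch_size: int = 32
    learning_rate: float = 1e-4
    lr_decay: str = "constant"  # "constant" or "cosine" (to 5% of the base step)
    seed: int = 0

    def __post_init__(self):
        for name, stages in (("recon", self.recon_stages), ("kl", self.kl_stages)):
            fracs = [f for _, f in stages]
            weights = [w for w, _ in stages]
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError(f"{name} stage fractions must sum to 1")
            if any(w <= 0 for w in weights):
                raise ValueError(f"{name} weights must be positive")
        kl_w = [w for w, _ in self.kl_stages]
        if any(b < a for a, b in zip(kl_w, kl_w[1:])):
            raise ValueError("KL weights must be non-decreasing")
        if self.total_iterations < 1 or self.batch_size < 1:
            raise ValueError("iteration budget and batch size must be positive")
        if self.lr_decay not in ("constant", "cosine"):
            raise ValueError("lr_decay must be 'constant' or 'cosine'")

    def step_size(self, iteration: int) -> float:
        """Learning rate at a global iteration under the step-size rule."""
        if self.lr_decay == "constant":
            return self.learning_rate
        frac = iteration / max(1, self.total_iterations - 1)
        floor = 0.05 * self.learning_rate
        return floor + 0.5 * (self.learning_rate - floor) * (1 + np.cos(np.pi * frac))


def _stage_lookup(stages, iteration: int, total: int) -> float:
    ends = np.floor(np.cumsum([f for _, f in stages]) * total).astype(int)
    ends[-1] = total  # last stage absorbs the rounding remainder
    idx = int(np.searchsorted(ends, iteration, side="right"))
    return stages[idx][0]


def loss_weights(iteration: int, schedule: TrainingSchedule) -> tuple[float, float]:
    """Piecewise-constant (w_recon, w_kl) at a global iteration index."""
    if not 0 <= iteration < schedule.total_iterations:
        raise ValueError(
            f"iteration {iteration} outside [0, {schedule.total_iterations})"
        )
    return (
        _stage_lookup(schedule.recon_stages, iteration, schedule.total_iterations),
        _stage_lookup(schedule.kl_stages, iteration, schedule.total_iterations),
    )


def total_loss(
    pred: BackboneConformation,
    truth: BackboneConformation,
    mu: np.ndarray,
    logvar: np.ndarray,
    iteration: int,
    schedule: TrainingSchedule,
    clamp: float | None = None,
) -> float:
    """w_recon * FAPE + w_kl * KL at the scheduled weights."""
    w_recon, w_kl = loss_weights(iteration, schedule)
    return w_recon * fape_loss(pred, truth, clamp=clamp) + w_kl * kl_loss(mu, logvar)


@dataclass(frozen=True)
class SplitSpec:
    """Shuffled train/validation/test proportions (default 50/25/25)."""

    train_fraction: float = 0.5
    valid_fraction: float = 0.25
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        fracs = (self.train_fraction, self.valid_fraction, self.test_fraction)
        if any(f <= 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")


def split_dataset(
    ensemble: Ensemble, spec: SplitSpec = SplitSpec()
) -> tuple[Ensemble, Ensemble, Ensemble]:
    """Seeded uniform shuffle, then contiguous train/valid/test slices.

    Slice sizes are floor(fraction * n) with the remainder assigned to the
    training slice; the three parts are disjoint and cover the input.
    """
    n = len(ensemble)
    if n < 4:
        raise ValueError("need at least 4 conformations to split")
    perm = np.random.default_rng(spec.seed).permutation(n)
    n_valid = int(np.floor(spec.valid_fraction * n))
    n_test = int(np.floor(spec.test_fraction * n))
    n_train = n - n_valid - n_test
    train = ensemble.subset(perm[:n_train], label=f"{ensemble.label}/train")
    valid = ensemble.subset(perm[n_train:n_train + n_valid], label=f"{ensemble.label}/valid")
    test = ensemble.subset(perm[n_train + n_valid:], label=f"{ensemble.label}/test")
    return train, valid, test
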