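"""Mini-batch gradient training of the backbone graph VAE.

Graphs and ground-truth frame-local coordinates are featurized once per
conformation and cached; each iteration assembles a disjoint-union batch
graph, runs the full encode -> reparameterize -> decode pass, and takes an
Adam step on the scheduled loss.  Training is fully deterministic given
the master seed (one seed sequence is split into independent streams for
initialization, batch selection and latent noise).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .autograd import Tensor
from .ensemble import Ensemble
from .features import build_graph
from .losses import TrainingSchedule, fape_tensor, kl_tensor, local_coordinates, loss_weights
from .model import (
    ModelConfig,
    _decode_tensors,
    _encode_tensors,
    as_tensors,
    init_params,
    save_checkpoint,
)

__all__ = ["train", "Adam", "GraphCache"]

logger = logging.getLogger(__name__)


class Adam:
    """Adam optimizer over a named-parameter dict (flat internal buffers)."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.slices = {}
        offset = 0
        for k, p in params.items():
            self.slices[k] = (offset, offset + p.size, p.shape)
            offset += p.size
        self.m = np.zeros(offset)
        self.v = np.zeros(offset)
        self._g = np.zeros(offset)
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        g = self._g
        g[:] = 0.0
        for k, grad in grads.items():
            lo, hi, _ = self.slices[k]
            g[lo:hi] = grad.ravel()
        self.m *= self.beta1
        self.m += (1 - self.beta1) * g
        self.v *= self.beta2
        self.v += (1 - self.beta2) * g**2
        update = (-self.lr) * (self.m / b1t) / (np.sqrt(self.v / b2t) + self.eps)
        for k, p in params.items():
            lo, hi, shape = self.slices[k]
            p += update[lo:hi].reshape(shape)


class GraphCache:
    """Featurized graphs and FAPE targets for every conformation of one ensemble."""

    def __init__(self, ensemble: Ensemble, k_neighbors: int):
        self.L = ensemble.n_residues
        self.n = len(ensemble)
        graphs = [build_graph(conf, k=k_neighbors) for conf in ensemble]
        self.node_types = graphs[0].node_types
        self.edge_src = [g.edge_src for g in graphs]
        self.edge_dst = [g.edge_dst for g in graphs]
        self.edge_features = [g.edge_features for g in graphs]
        coords = ensemble.coords_array()
        self.coords = coords
        # ground-truth atoms in ground-truth residue frames, (n, L, 3L, 3)
        self.truth_local = np.asarray(local_coordinates(coords, eps=0.0).value)
        self.sequence = ensemble.sequence

    def batch(self, indices: np.ndarray):
        """Disjoint-union graph over the selected conformations."""
        m = 3 * self.L
        node_types = np.tile(self.node_types, len(indices))
        src = np.concatenate([self.edge_src[i] + g * m for g, i in enumerate(indices)])
        dst = np.concatenate([self.edge_dst[i] + g * m for g, i in enumerate(indices)])
        feats = np.concatenate([self.edge_features[i] for i in indices])
        return node_types, src, dst, feats


def _forward(tp, config, cache: GraphCache, indices, eps_noise, train_temperature,
             clamp=None):
    """Full differentiable pass; returns (fape, kl) loss tensors."""
    B, L = len(indices), cache.L
    node_types, src, dst, feats = cache.batch(indices)
    mu, logvar = _encode_tensors(tp, config, node_types, src, dst, feats)
    z = mu + (logvar * 0.5).exp() * (eps_noise * train_temperature)
    coords = _decode_tensors(tp, config, z.reshape(B, L, config.latent_dim), cache.sequence)
    fape = fape_tensor(coords, cache.truth_local[indices], clamp=clamp)
    kl = kl_tensor(mu, logvar)
    return fape, kl


def train(
    ensemble: Ensemble,
    config: ModelConfig = ModelConfig(),
    schedule: TrainingSchedule = None,
    *,
    valid_ensemble: Ensemble | None = None,
    train_temperature: float = 1.0,
    fape_clamp: float | None = None,
    initial_params: dict | None = None,
    checkpoint_dir: str | None = None,
    checkpoint_every: int | None = None,
    callback=None,
) -> tuple[dict, pd.DataFrame]:
    """Train on an ensemble; returns (parameters, per-iteration history).

    The history records iteration, unweighted FAPE (Å) and KL, the
    scheduled weights, wall time, and — once per epoch when a validation
    ensemble is given — the validation FAPE at temperature 0.  Per-epoch
    summaries go to the ``bbvae.training`` logger; checkpoints are written
    every ``checkpoint_every`` iterations when a directory is given.
    """
    if schedule is None:
        schedule = TrainingSchedule(total_iterations=2000, batch_size=8)
    master = np.random.SeedSequence(schedule.seed)
    init_ss, data_ss, eps_ss = master.spawn(3)
    params = (
        {k: np.array(v, dtype=np.float64) for k, v in initial_params.items()}
        if initial_params is not None
        else init_params(config, seed=init_ss)
    )
    cache = GraphCache(ensemble, config.k_neighbors)
    valid_cache = (
        GraphCache(valid_ensemble, config.k_neighbors) if valid_ensemble is not None else None
    )
    data_rng = np.random.default_rng(data_ss)
    eps_rng = np.random.default_rng(eps_ss)
    opt = Adam(params, learning_rate=schedule.learning_rate)

    B = min(schedule.batch_size, cache.n)
    iters_per_epoch = max(1, cache.n // B)
    rows = []
    t0 = time.perf_counter()
    for it in range(schedule.total_iterations):
        w_recon, w_kl = loss_weights(it, schedule)
        opt.lr = schedule.step_size(it)
        indices = data_rng.choice(cache.n, size=B, replace=False)
        eps_noise = Tensor(eps_rng.standard_normal((B * cache.L, config.latent_dim)))
        tp = as_tensors(params)
        fape, kl = _forward(tp, config, cache, indices, eps_noise, train_temperature,
                            clamp=fape_clamp)
        loss = fape * w_recon + kl * w_kl
        if not np.isfinite(loss.value):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        loss.backward()
        grads = {k: t.grad for k, t in tp.items() if t.grad is not None}
        opt.step(params, grads)

        row = {
            "iteration": it,
            "fape": fape.item(),
            "kl": kl.item(),
            "w_recon": w_recon,
            "w_kl": w_kl,
            "wall_time": time.perf_counter() - t0,
            "val_fape": np.nan,
        }
        if (it + 1) % iters_per_epoch == 0:
            if valid_cache is not None:
                row["val_fape"] = _validation_fape(params, config, valid_cache)
            logger.info(
                "epoch %d (iteration %d): fape=%.4f kl=%.4f w_recon=%.3g w_kl=%.3g val_fape=%s",
                (it + 1) // iters_per_epoch, it, row["fape"], row["kl"],
                w_recon, w_kl, f"{row['val_fape']:.4f}" if np.isfinite(row["val_fape"]) else "-",
            )
        if checkpoint_dir is not None and checkpoint_every and (it + 1) % checkpoint_every == 0:
            path = Path(checkpoint_dir)
            path.mkdir(parents=True, exist_ok=True)
            save_checkpoint(path / f"checkpoint_{it + 1:07d}.npz", params, config, it + 1)
        rows.append(row)
        if callback is not None:
            callback(it, row, params)
    history = pd.DataFrame(rows)
    return params, history


def _validation_fape(params, config, cache: GraphCache) -> float:
    """Mean deterministic (T=0) reconstruction FAPE over a cached ensemble."""
    tp = as_tensors(params)
    indices = np.arange(cache.n)
    eps = Tensor(np.zeros((cache.n * cache.L, config.latent_dim)))
    fape, _ = _forward(tp, config, cache, indices, eps, 0.0)
    return float(fape.item())
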