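"""Scikit-learn-style estimator wrapping the full train/sample workflow.

:class:`BackboneEnsembleVAE` is a system-specific generative model: it is
fitted to the conformational ensemble of ONE protein and afterwards
reconstructs, samples and interpolates conformations of that same
sequence.  It follows scikit-learn conventions (keyword constructor
mirrored by ``get_params``/``set_params``, fitted attributes with a
trailing underscore, ``fit``/``transform``/``score``), so it composes
with sklearn model-selection utilities where that makes sense.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .ensemble import BackboneConformation, Ensemble
from .features import build_graph
from .geometry import kabsch_rmsd
from .losses import TrainingSchedule
from .model import (
    ModelConfig,
    count_parameters,
    decode,
    encode,
    load_checkpoint,
    sample_latent,
    save_checkpoint,
)
from .training import train as _train_loop

__all__ = ["BackboneEnsembleVAE"]


def _as_ensemble(X) -> Ensemble:
    if isinstance(X, Ensemble):
        return X
    if isinstance(X, BackboneConformation):
        return Ensemble([X])
    return Ensemble(list(X))


class BackboneEnsembleVAE(BaseEstimator, TransformerMixin):
    """Graph variational autoencoder over backbone conformations of one protein.

    Parameters mirror the compact architecture defaults; ``temperature``
    is the default sampling temperature used by :meth:`sample`.
    ``sample_mode`` selects how generation seeds the latent space:
    ``"posterior"`` re-encodes fitted training conformations and samples
    their reparameterized neighborhoods (z = mu + sigma * eps * T), while
    ``"prior"`` draws z = T * eps around the origin of the latent prior.

    Attributes set by :meth:`fit`: ``params_`` (named weight arrays),
    ``config_``, ``schedule_``, ``history_`` (training curve),
    ``sequence_``, ``n_iter_``, ``train_mu_`` / ``train_logvar_`` (cached
    posterior parameters of the training set, used by posterior sampling).
    """

    def __init__(
        self,
        *,
        embed_dim: int = 64,
        gcn_layers: int = 3,
        gcn_hidden: int = 64,
        reduce_dim: int = 32,
        latent_dim: int = 32,
        decoder_blocks: int = 3,
        decoder_width: int = 64,
        attention_heads: int = 4,
        feedforward_width: int = 128,
        k_neighbors: int = 30,
        positional_encoding: bool = True,
        residue_embedding: bool = True,
        total_iterations: int = 2000,
        batch_size: int = 8,
        learning_rate: float = 1e-4,
        lr_decay: str = "constant",
        train_temperature: float = 1.0,
        fape_clamp: float | None = None,
        temperature: float = 0.02,
        sample_mode: str = "posterior",
        schedule: TrainingSchedule | None = None,
        random_state: int | None = 0,
    ):
        self.embed_dim = embed_dim
        self.gcn_layers = gcn_layers
        self.gcn_hidden = gcn_hidden
        self.reduce_dim = reduce_dim
        self.latent_dim = latent_dim
        self.decoder_blocks = decoder_blocks
        self.decoder_width = decoder_width
        self.attention_heads = attention_heads
        self.feedforward_width = feedforward_width
        self.k_neighbors = k_neighbors
        self.positional_encoding = positional_encoding
        self.residue_embedding = residue_embedding
        self.total_iterations = total_iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.train_temperature = train_temperature
        self.fape_clamp = fape_clamp
        self.temperature = temperature
        self.sample_mode = sample_mode
        self.schedule = schedule
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _make_config(self) -> ModelConfig:
        return ModelConfig(
            embed_dim=self.embed_dim,
            gcn_layers=self.gcn_layers,
            gcn_hidden=self.gcn_hidden,
            reduce_dim=self.reduce_dim,
            latent_dim=self.latent_dim,
            decoder_blocks=self.decoder_blocks,
            decoder_width=self.decoder_width,
            attention_heads=self.attention_heads,
            feedforward_width=self.feedforward_width,
            k_neighbors=self.k_neighbors,
            positional_encoding=self.positional_encoding,
            residue_embedding=self.residue_embedding,
        )

    def fit(self, X, y=None, *, validation=None):
        """Train on an ensemble (or list of conformations) of one sequence."""
        ensemble = _as_ensemble(X)
        self.config_ = self._make_config()
        seed = 0 if self.random_state is None else int(self.random_state)
        self.schedule_ = self.schedule or TrainingSchedule(
            total_iterations=self.total_iterations,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            lr_decay=self.lr_decay,
            seed=seed,
        )
        self.params_, self.history_ = _train_loop(
            ensemble,
            self.config_,
            self.schedule_,
            valid_ensemble=None if validation is None else _as_ensemble(validation),
            train_temperature=self.train_temperature,
            fape_clamp=self.fape_clamp,
        )
        self.sequence_ = ensemble.sequence
        self.n_iter_ = self.schedule_.total_iterations
        self.train_mu_, self.train_logvar_ = self._encode_arrays(ensemble)
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("this BackboneEnsembleVAE instance is not fitted yet")

    def _check_sequence(self, sequence: str):
        if sequence != self.sequence_:
            raise ValueError(
                "sequence does not match the training sequence; the model is system-specific"
            )

    # ------------------------------------------------------------- encoding
    def _encode_arrays(self, ensemble: Ensemble) -> tuple[np.ndarray, np.ndarray]:
        mus, logvars = [], []
        for conf in ensemble:
            graph = build_graph(conf, k=self.config_.k_neighbors)
            mu, logvar = encode(graph, self.params_, self.config_)
            mus.append(mu)
            logvars.append(logvar)
        return np.stack(mus), np.stack(logvars)

    def encode_ensemble(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mu, logvar) for each member, each (n, L, d_z)."""
        self._check_fitted()
        ensemble = _as_ensemble(X)
        self._check_sequence(ensemble.sequence)
        return self._encode_arrays(ensemble)

    def transform(self, X) -> np.ndarray:
        """Latent means flattened to (n, L * d_z) — the sklearn feature view."""
        mu, _ = self.encode_ensemble(X)
        return mu.reshape(mu.shape[0], -1)

    # ------------------------------------------------------------- sampling
    def _decode_batch(self, z: np.ndarray, label: str) -> Ensemble:
        coords = decode(z, self.sequence_, self.params_, self.config_)
        return Ensemble(
            [BackboneConformation(self.sequence_, c) for c in coords], label=label
        )

    def reconstruct(self, X, temperature: float = 0.0, random_state=None) -> Ensemble:
        """Encode and decode each member in order (T = 0: deterministic means)."""
        self._check_fitted()
        ensemble = _as_ensemble(X)
        self._check_sequence(ensemble.sequence)
        mu, logvar = self._encode_arrays(ensemble)
        rng = np.random.default_rng(random_state)
        z = sample_latent(mu, logvar, temperature=temperature, rng=rng)
        return self._decode_batch(z, label=f"{ensemble.label}/reconstructed")

    def sample(
        self,
        n_samples: int,
        temperature: float | None = None,
        mode: str | None = None,
        random_state=None,
    ) -> Ensemble:
        """Generate new conformations of the fitted sequence.

        ``posterior`` mode resamples the latent neighborhoods of training
        conformations (drawn with replacement); ``prior`` mode decodes
        z = T * eps around the latent origin.
        """
        self._check_fitted()
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        T = self.temperature if temperature is None else temperature
        mode = self.sample_mode if mode is None else mode
        rng = np.random.default_rng(random_state)
        L = len(self.sequence_)
        if mode == "posterior":
            pick = rng.integers(0, self.train_mu_.shape[0], size=n_samples)
            z = sample_latent(self.train_mu_[pick], self.train_logvar_[pick], T, rng)
        elif mode == "prior":
            z = T * rng.standard_normal((n_samples, L, self.config_.latent_dim))
        else:
            raise ValueError(f"unknown sample mode {mode!r}")
        return self._decode_batch(z, label=f"generated/{mode}/T={T}")

    def interpolate(self, conf_a: BackboneConformation, conf_b: BackboneConformation,
                    steps: int) -> Ensemble:
        """Decode the straight latent line between two conformations.

        Endpoints use the posterior means (T = 0), so step 0 and the last
        step equal the deterministic reconstructions of the endpoints.
        """
        self._check_fitted()
        if steps < 2:
            raise ValueError("steps must be >= 2")
        for conf in (conf_a, conf_b):
            self._check_sequence(conf.sequence)
        mu, _ = self._encode_arrays(Ensemble([conf_a, conf_b]))
        z_a, z_b = mu[0], mu[1]
        t = np.linspace(0.0, 1.0, steps)[:, None, None]
        path = (1.0 - t) * z_a[None] + t * z_b[None]
        return self._decode_batch(path, label="interpolation")

    # -------------------------------------------------------------- scoring
    def score(self, X, y=None) -> float:
        """Negative mean backbone reconstruction RMSD (Å); higher is better."""
        ensemble = _as_ensemble(X)
        recon = self.reconstruct(ensemble, temperature=0.0)
        rmsds = [
            kabsch_rmsd(a.atoms(), b.atoms()) for a, b in zip(ensemble, recon)
        ]
        return -float(np.mean(rmsds))

    @property
    def n_parameters_(self) -> int:
        self._check_fitted()
        return count_parameters(self.params_)

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Write a checkpoint: weights, config, iteration counter and the
        cached training-posterior arrays needed for posterior sampling."""
        self._check_fitted()
        extra = {
            "__train_mu__": self.train_mu_,
            "__train_logvar__": self.train_logvar_,
            "__sequence__": np.frombuffer(self.sequence_.encode(), dtype=np.uint8),
        }
        save_checkpoint(path, {**self.params_, **extra}, self.config_, self.n_iter_)

    @classmethod
    def load(cls, path) -> "BackboneEnsembleVAE":
        params, config, iteration = load_checkpoint(path)
        est = cls(**{
            k: getattr(config, k)
            for k in (
                "embed_dim", "gcn_layers", "gcn_hidden", "reduce_dim", "latent_dim",
                "decoder_blocks", "decoder_width", "attention_heads",
                "feedforward_width", "k_neighbors", "positional_encoding",
                "residue_embedding",
            )
        })
        est.config_ = config
        est.train_mu_ = params.pop("__train_mu__")
        est.train_logvar_ = params.pop("__train_logvar__")
        est.sequence_ = bytes(params.pop("__sequence__")).decode()
        est.params_ = params
        est.n_iter_ = iteration
        est.history_ = None
        est.schedule_ = None
        return est
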