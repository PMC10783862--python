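"""Thin functional interface over a fitted model's three inference modes.

All three are pure functions of (fitted parameters, inputs, seed):
reconstruction of an existing ensemble, generation of new conformations at
a sampling temperature, and linear latent-space interpolation between two
conformations.
"""

from __future__ import annotations

from .ensemble import BackboneConformation, Ensemble
from .estimator import BackboneEnsembleVAE

__all__ = ["reconstruct", "generate", "interpolate"]


def reconstruct(
    model: BackboneEnsembleVAE,
    ensemble: Ensemble,
    temperature: float = 0.0,
    random_state=None,
) -> Ensemble:
    """Encode and decode every member in order; T = 0 is deterministic."""
    return model.reconstruct(ensemble, temperature=temperature, random_state=random_state)


def generate(
    model: BackboneEnsembleVAE,
    sequence: str,
    n: int,
    temperature: float = 0.02,
    seed=None,
    mode: str | None = None,
) -> Ensemble:
    """Generate ``n`` conformations of the fitted sequence at temperature T."""
    if sequence != model.sequence_:
        raise ValueError("sequence does not match the fitted model's sequence")
    return model.sample(n, temperature=temperature, mode=mode, random_state=seed)


def interpolate(
    model: BackboneEnsembleVAE,
    conf_a: BackboneConformation,
    conf_b: BackboneConformation,
    steps: int,
) -> Ensemble:
    """Decode the straight line between the two posterior means."""
    return model.interpolate(conf_a, conf_b, steps)
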