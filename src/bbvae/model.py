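"""The trainable network: edge-gated GCN encoder, per-residue variational
bottleneck, transformer decoder emitting backbone coordinates.

The encoder embeds 60-way atom types to ``embed_dim``, runs three
edge-gated graph convolutions with residual updates

    v_i <- v_i + sum_{j in N(i)} sigmoid(h_ij W_g + b_g) * relu(h_ij W_c + b_c),
    h_ij = v_i (+) e_ij (+) v_j,

reduces dimension with a nonlinear FC layer, concatenates each residue's
(N, CA, C) atom vectors, and maps through a shared FC layer to separate
mean and log-variance heads — one d_z-dimensional Gaussian per residue.

The decoder turns latent codes into tokens (linear + sinusoidal positional
encoding + learned residue-type embedding) and applies three pre-norm
transformer blocks (multi-head self-attention and a position-wise
feed-forward update module, each with residual connection and layer
normalization) followed by a linear head to 9 coordinates per residue.
The output lives in an arbitrary global frame; the frame-aligned
reconstruction loss supplies the rigid-motion invariance.

All parameters are plain named NumPy arrays; none of the shapes depend on
the protein length, so the parameter count is length-independent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .features import N_ATOM_TYPES, ProteinGraph

__all__ = [
    "ModelConfig",
    "init_params",
    "embed_nodes",
    "gcn_layer",
    "pool_to_residues",
    "encode",
    "sample_latent",
    "decode",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_LN_EPS = 1e-5
_LOGVAR_BOUND = 8.0
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (compact defaults, all configurable)."""

    embed_dim: int = 64
    gcn_layers: int = 3
    gcn_hidden: int = 64
    reduce_dim: int = 32
    latent_dim: int = 32
    decoder_blocks: int = 3
    decoder_width: int = 64
    attention_heads: int = 4
    feedforward_width: int = 128
    k_neighbors: int = 30
    gaussian_count: int = 16
    gaussian_range: tuple = (0.0, 20.0)
    positional_encoding: bool = True
    residue_embedding: bool = True

    def __post_init__(self):
        ints = (
            self.embed_dim, self.gcn_layers, self.gcn_hidden, self.reduce_dim,
            self.latent_dim, self.decoder_blocks, self.decoder_width,
            self.attention_heads, self.feedforward_width, self.k_neighbors,
            self.gaussian_count,
        )
        if any(int(v) != v or v <= 0 for v in ints):
            raise ValueError("all ModelConfig size fields must be positive integers")
        if self.decoder_width % self.attention_heads:
            raise ValueError("decoder_width must be divisible by attention_heads")
        if self.embed_dim != self.gcn_hidden:
            raise ValueError("residual GCN updates require embed_dim == gcn_hidden")


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def init_params(config: ModelConfig, seed: int | None = None) -> dict[str, np.ndarray]:
    """Initialize all trainable arrays (Glorot weights, zero biases)."""
    rng = np.random.default_rng(seed)
    c = config
    p: dict[str, np.ndarray] = {}
    p["embed.W"] = rng.normal(0.0, 0.05, size=(N_ATOM_TYPES, c.embed_dim))
    h_in = c.gcn_hidden + 23 + c.gcn_hidden
    for l in range(c.gcn_layers):
        p[f"gcn{l}.Wg"] = _glorot(rng, h_in, c.gcn_hidden)
        p[f"gcn{l}.bg"] = np.zeros(c.gcn_hidden)
        p[f"gcn{l}.Wc"] = _glorot(rng, h_in, c.gcn_hidden)
        p[f"gcn{l}.bc"] = np.zeros(c.gcn_hidden)
    p["enc_ln.g"] = np.ones(c.gcn_hidden)
    p["enc_ln.b"] = np.zeros(c.gcn_hidden)
    p["reduce.W"] = _glorot(rng, c.gcn_hidden, c.reduce_dim)
    p["reduce.b"] = np.zeros(c.reduce_dim)
    p["shared.W"] = _glorot(rng, 3 * c.reduce_dim, c.decoder_width)
    p["shared.b"] = np.zeros(c.decoder_width)
    p["mu.W"] = _glorot(rng, c.decoder_width, c.latent_dim)
    p["mu.b"] = np.zeros(c.latent_dim)
    p["logvar.W"] = _glorot(rng, c.decoder_width, c.latent_dim)
    # start with modest posterior noise (sigma ~ 0.22) instead of sigma = 1:
    # reconstruction learning is not drowned early and the KL anneal widens
    # the posterior later as its weight grows
    p["logvar.b"] = np.full(c.latent_dim, -3.0)

    d = c.decoder_width
    p["dec_in.W"] = _glorot(rng, c.latent_dim, d)
    p["dec_in.b"] = np.zeros(d)
    if c.residue_embedding:
        p["restype.W"] = rng.normal(0.0, 0.05, size=(20, d))
    for l in range(c.decoder_blocks):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"block{l}.{name}"] = _glorot(rng, d, d)
            p[f"block{l}.{name[0]}b{name[1]}"] = np.zeros(d)
        p[f"block{l}.ln1.g"] = np.ones(d)
        p[f"block{l}.ln1.b"] = np.zeros(d)
        p[f"block{l}.ln2.g"] = np.ones(d)
        p[f"block{l}.ln2.b"] = np.zeros(d)
        p[f"block{l}.ff1.W"] = _glorot(rng, d, c.feedforward_width)
        p[f"block{l}.ff1.b"] = np.zeros(c.feedforward_width)
        p[f"block{l}.ff2.W"] = _glorot(rng, c.feedforward_width, d)
        p[f"block{l}.ff2.b"] = np.zeros(d)
    p["final_ln.g"] = np.ones(d)
    p["final_ln.b"] = np.zeros(d)
    p["out.W"] = _glorot(rng, d, 9)
    p["out.b"] = np.zeros(9)
    return p


def as_tensors(params: dict[str, np.ndarray]) -> dict[str, Tensor]:
    """Wrap a parameter dict for differentiation."""
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


def count_parameters(params: dict[str, np.ndarray]) -> int:
    """Total trainable scalar count (independent of protein length)."""
    return int(sum(np.asarray(v).size for v in params.values()))


# --------------------------------------------------------------------------
# encoder
# --------------------------------------------------------------------------

def embed_nodes(node_features: np.ndarray, params: dict) -> np.ndarray:
    """Map node one-hots (m, 60) to continuous embeddings (m, embed_dim)."""
    onehot = np.asarray(node_features, dtype=np.float64)
    rows_ok = (
        onehot.ndim == 2
        and onehot.shape[1] == N_ATOM_TYPES
        and np.all((onehot == 0) | (onehot == 1))
        and np.all(onehot.sum(axis=1) == 1)
    )
    if not rows_ok:
        raise ValueError("node features must be rows of 60-way one-hots")
    W = params["embed.W"]
    W = W.value if isinstance(W, Tensor) else W
    return onehot @ W


def gcn_layer(
    v: Tensor | np.ndarray,
    edge_features: Tensor | np.ndarray,
    edge_src: np.ndarray,
    edge_dst: np.ndarray,
    Wg, bg, Wc, bc,
    ops: tuple | None = None,
) -> Tensor:
    """One residual edge-gated graph convolution at the receiver nodes.

    The per-edge pre-activation [v_i ⊕ e_ij ⊕ v_j] @ W is evaluated as the
    mathematically identical sum  (v @ W_recv)_i + e_ij @ W_edge +
    (v @ W_send)_j,  which turns one wide per-edge product into two small
    per-node products plus a narrow per-edge one.  ``ops`` optionally
    carries precomputed (gather_dst, gather_src, scatter_dst) sparse
    operators so the edge index matrices are built once per batch.
    """
    v = ag.as_tensor(v)
    e = ag.as_tensor(edge_features)
    Wg, bg, Wc, bc = map(ag.as_tensor, (Wg, bg, Wc, bc))
    m = v.shape[0]
    h_dim = v.shape[1]
    if ops is None:
        ops = (
            ag.SparseOp.gather(edge_dst, m),
            ag.SparseOp.gather(edge_src, m),
            ag.SparseOp.scatter(edge_dst, m),
        )
    g_dst, g_src, s_dst = ops

    def edge_preact(W, b):
        recv = g_dst(v @ W[:h_dim])
        edge = e @ W[h_dim:-h_dim]
        send = g_src(v @ W[-h_dim:])
        return recv + edge + send + b

    gate = edge_preact(Wg, bg).sigmoid()
    message = gate * edge_preact(Wc, bc).relu()
    return v + s_dst(message)


def pool_to_residues(atom_features: Tensor | np.ndarray, L: int) -> Tensor:
    """Concatenate each residue's (N, CA, C) atom vectors: (m, d) -> (L, 3d).

    For a batch of B equally sized graphs stacked along axis 0 the same
    reshape yields (B*L, 3d); callers reshape further as needed.
    """
    x = ag.as_tensor(atom_features)
    m, d = x.shape
    if m % 3 or (L and m != 3 * L):
        raise ValueError(f"atom count {m} is not 3 x residue count {L}")
    return x.reshape(m // 3, 3 * d)


def _encode_tensors(
    tp: dict[str, Tensor],
    config: ModelConfig,
    node_types: np.ndarray,
    edge_src: np.ndarray,
    edge_dst: np.ndarray,
    edge_features: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """Differentiable encoder over one graph or a disjoint union of graphs."""
    v = ag.gather(tp["embed.W"], node_types)
    e = Tensor(edge_features)
    m = len(node_types)
    ops = (
        ag.SparseOp.gather(edge_dst, m),
        ag.SparseOp.gather(edge_src, m),
        ag.SparseOp.scatter(edge_dst, m),
    )
    for l in range(config.gcn_layers):
        v = gcn_layer(
            v, e, edge_src, edge_dst,
            tp[f"gcn{l}.Wg"], tp[f"gcn{l}.bg"], tp[f"gcn{l}.Wc"], tp[f"gcn{l}.bc"],
            ops=ops,
        )
    # scale control: the residual message sums are unnormalized and grow with
    # the neighbor count, so the stack output is layer-normalized before the
    # dimension-reduction layer
    v = _layer_norm(v, tp["enc_ln.g"], tp["enc_ln.b"])
    reduced = (v @ tp["reduce.W"] + tp["reduce.b"]).relu()
    pooled = pool_to_residues(reduced, reduced.shape[0] // 3)
    shared = (pooled @ tp["shared.W"] + tp["shared.b"]).relu()
    mu = shared @ tp["mu.W"] + tp["mu.b"]
    raw = shared @ tp["logvar.W"] + tp["logvar.b"]
    # soft-bound the log-variance to (-_LOGVAR_BOUND, _LOGVAR_BOUND) so the
    # KL term and sigma = exp(logvar/2) stay finite for any activations
    logvar = (raw * (1.0 / _LOGVAR_BOUND)).tanh() * _LOGVAR_BOUND
    return mu, logvar


def encode(graph: ProteinGraph, params: dict, config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue posterior parameters (mu, logvar), each (L, d_z)."""
    tp = {k: ag.as_tensor(v) for k, v in params.items()}
    mu, logvar = _encode_tensors(
        tp, config, graph.node_types, graph.edge_src, graph.edge_dst, graph.edge_features
    )
    return mu.value, logvar.value


def sample_latent(
    mu: np.ndarray,
    logvar: np.ndarray,
    temperature: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Reparameterized draw z = mu + sigma * eps * T with sigma = exp(logvar / 2)."""
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar must share a shape")
    if temperature == 0:
        return mu.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps = rng.standard_normal(mu.shape)
    return mu + np.exp(0.5 * logvar) * eps * temperature


# --------------------------------------------------------------------------
# decoder
# --------------------------------------------------------------------------

def sinusoidal_positions(L: int, d: int) -> np.ndarray:
    """Standard sinusoidal positional encoding table (L, d)."""
    pos = np.arange(L)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / d)
    table = np.zeros((L, d))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + _LN_EPS).sqrt() * g + b


def _attention(x: Tensor, tp: dict, prefix: str, heads: int) -> Tensor:
    B, L, D = x.shape
    dh = D // heads

    def heads_split(t):
        return t.reshape(B, L, heads, dh).transpose(0, 2, 1, 3)

    q = heads_split(x @ tp[f"{prefix}.Wq"] + tp[f"{prefix}.Wbq"])
    k = heads_split(x @ tp[f"{prefix}.Wk"] + tp[f"{prefix}.Wbk"])
    v = heads_split(x @ tp[f"{prefix}.Wv"] + tp[f"{prefix}.Wbv"])
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    att = scores.softmax(axis=-1)
    out = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
    return out @ tp[f"{prefix}.Wo"] + tp[f"{prefix}.Wbo"]


_RESTYPE_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_RESTYPE_INDEX = {aa: i for i, aa in enumerate(_RESTYPE_ORDER)}


def _decode_tensors(
    tp: dict[str, Tensor],
    config: ModelConfig,
    z: Tensor,
    sequence: str,
) -> Tensor:
    """Differentiable decoder: (B, L, d_z) latents -> (B, L, 3, 3) coordinates."""
    B, L, _ = z.shape
    x = z @ tp["dec_in.W"] + tp["dec_in.b"]
    if config.positional_encoding:
        x = x + Tensor(sinusoidal_positions(L, config.decoder_width)[None])
    if config.residue_embedding:
        seq_idx = np.array([_RESTYPE_INDEX[aa] for aa in sequence])
        x = x + ag.gather(tp["restype.W"], seq_idx).reshape(1, L, config.decoder_width)
    for l in range(config.decoder_blocks):
        x = x + _attention(
            _layer_norm(x, tp[f"block{l}.ln1.g"], tp[f"block{l}.ln1.b"]),
            tp, f"block{l}", config.attention_heads,
        )
        h = _layer_norm(x, tp[f"block{l}.ln2.g"], tp[f"block{l}.ln2.b"])
        h = (h @ tp[f"block{l}.ff1.W"] + tp[f"block{l}.ff1.b"]).relu()
        x = x + (h @ tp[f"block{l}.ff2.W"] + tp[f"block{l}.ff2.b"])
    x = _layer_norm(x, tp["final_ln.g"], tp["final_ln.b"])
    out = x @ tp["out.W"] + tp["out.b"]
    return out.reshape(B, L, 3, 3)


def decode(z: np.ndarray, sequence: str, params: dict, config: ModelConfig) -> np.ndarray:
    """Decode latent codes to backbone coordinates in an arbitrary global frame.

    Accepts (L, d_z) for a single conformation or (B, L, d_z) for a batch.
    """
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 2
    if single:
        z = z[None]
    if z.shape[1] != len(sequence):
        raise ValueError("latent length does not match sequence length")
    tp = {k: ag.as_tensor(v) for k, v in params.items()}
    coords = _decode_tensors(tp, config, Tensor(z), sequence).value
    return coords[0] if single else coords


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, params: dict, config: ModelConfig, iteration: int = 0) -> None:
    """Serialize named parameter arrays + config + iteration (versioned)."""
    header = json.dumps(
        {"format_version": CHECKPOINT_VERSION, "config": asdict(config), "iteration": iteration}
    )
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **params)


def load_checkpoint(path) -> tuple[dict, ModelConfig, int]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('format_version')}")
        params = {k: data[k] for k in data.files if k != "__header__"}
    cfg = header["config"]
    cfg["gaussian_range"] = tuple(cfg["gaussian_range"])
    return params, ModelConfig(**cfg), int(header["iteration"])
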