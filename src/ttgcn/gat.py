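"""Per-metapath multi-head graph attention encoder.

For each metapath neighbor graph, edge logits are
``w_ij = LeakyReLU(g' . [W x_i || W x_j])``, softmax-normalized over each
node's neighborhood into attention coefficients ``a_ij``, and node i's next
embedding is ``act(sum_j a_ij W x_j)``. K independent heads are concatenated,
so one layer maps width d_in to K*d_head. The per-metapath outputs form the
connectivity channel that the fusion stage reweights.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, concat, masked_row_softmax, parameter

__all__ = ["GATHead", "GATLayerParams", "GATEncoder",
           "attention_logits", "attention_coefficients", "gat_layer", "gat_encode"]

_ACTIVATIONS = {
    "tanh": lambda t: t.tanh(),
    "identity": lambda t: t,
    "leaky_relu": lambda t: t.leaky_relu(0.2),
}


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return parameter(rng.uniform(-bound, bound, size=shape))


class GATHead:
    """One attention head: projection W (stored transposed) and the two
    halves of the length-2d attention vector g = [g_src; g_dst]."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.Wt = _uniform_init(rng, (d_in, d_out), d_in)      # x -> x W^T as H @ Wt
        self.g_src = _uniform_init(rng, (d_out, 1), 2 * d_out)
        self.g_dst = _uniform_init(rng, (d_out, 1), 2 * d_out)

    def parameters(self):
        return [self.Wt, self.g_src, self.g_dst]


class GATLayerParams:
    """K independently initialized heads for one metapath and one layer."""

    def __init__(self, d_in: int, d_head: int, n_heads: int = 4,
                 activation: str = "tanh", leaky_slope: float = 0.2,
                 dropout_rate: float = 0.4, rng: np.random.Generator | None = None):
        if not 0 <= dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0,1)")
        if leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        rng = rng or np.random.default_rng()
        self.d_in, self.d_head, self.n_heads = d_in, d_head, n_heads
        self.activation = activation
        self.leaky_slope = leaky_slope
        self.dropout_rate = dropout_rate
        self.heads = [GATHead(d_in, d_head, rng) for _ in range(n_heads)]

    @property
    def d_out(self) -> int:
        return self.d_head * self.n_heads

    def parameters(self):
        return [p for h in self.heads for p in h.parameters()]


def attention_logits(head: GATHead, x_i, x_j, leaky_slope: float = 0.2) -> float:
    """Edge logit w_ij = LeakyReLU(g'.[W x_i || W x_j]); asymmetric in general."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape[0] != head.Wt.shape[0] or x_j.shape[0] != head.Wt.shape[0]:
        raise ValueError(f"embedding dimension {x_i.shape[0]} does not match "
                         f"layer input dimension {head.Wt.shape[0]}")
    pi = x_i @ head.Wt.data
    pj = x_j @ head.Wt.data
    z = float(pi @ head.g_src.data[:, 0] + pj @ head.g_dst.data[:, 0])
    return z if z > 0 else leaky_slope * z


def attention_coefficients(logits) -> np.ndarray:
    """Softmax over one node's neighborhood, overflow-safe (max subtraction)."""
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0:
        raise ValueError("empty neighborhood: self-loops should guarantee >=1 neighbor")
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _dropout(t: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    keep = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * keep


def gat_layer(params: GATLayerParams, graph, H_in, training: bool = False,
              rng: np.random.Generator | None = None) -> Tensor:
    """One multi-head attention layer over a metapath neighbor graph.

    Aggregation runs over the graph's adjacency (self-loops included, so
    every neighborhood is nonempty). Dropout on inputs and attention
    coefficients is applied only when `training` is true.
    """
    H = as_tensor(H_in)
    adj = graph.adjacency if hasattr(graph, "adjacency") else np.asarray(graph)
    mask = adj > 0
    if H.shape[0] != mask.shape[0]:
        raise ValueError(f"features have {H.shape[0]} rows, graph has {mask.shape[0]} nodes")
    if training and params.dropout_rate > 0:
        H = _dropout(H, params.dropout_rate, rng)
    act = _ACTIVATIONS[params.activation]
    outs = []
    for head in params.heads:
        Hp = H @ head.Wt                         # n x d_head
        f_src = Hp @ head.g_src                  # n x 1
        f_dst = Hp @ head.g_dst                  # n x 1
        logits = (f_src + f_dst.T).leaky_relu(params.leaky_slope)
        A = masked_row_softmax(logits, mask)
        if training and params.dropout_rate > 0:
            A = _dropout(A, params.dropout_rate, rng)
        outs.append(act(A @ Hp))
    out = outs[0] if len(outs) == 1 else concat(outs, axis=1)
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("NaN/Inf in graph attention layer output")
    return out


class GATEncoder:
    """Stack of attention layers per metapath, sharing hyperparameters."""

    def __init__(self, in_dim: int, metapath_names, n_layers: int = 1,
                 n_heads: int = 4, d_head: int = 64, activation: str = "tanh",
                 leaky_slope: float = 0.2, dropout_rate: float = 0.4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.layers = {}
        for name in metapath_names:
            stack, d = [], in_dim
            for _ in range(n_layers):
                lp = GATLayerParams(d, d_head, n_heads, activation,
                                    leaky_slope, dropout_rate, rng)
                stack.append(lp)
                d = lp.d_out
            self.layers[name] = stack
        self.out_dim = in_dim if n_layers == 0 else n_heads * d_head

    def parameters(self):
        return [p for stack in self.layers.values() for lp in stack for p in lp.parameters()]

    def encode(self, graphs: dict, features, training: bool = False,
               rng: np.random.Generator | None = None) -> dict:
        """Per-metapath embeddings {G_a^rho} from the initial features."""
        out = {}
        for name, stack in self.layers.items():
            H = as_tensor(features)
            for lp in stack:
                H = gat_layer(lp, graphs[name], H, training=training, rng=rng)
            out[name] = H
        return out


def gat_encode(encoder: GATEncoder, graphs: dict, features, **kw) -> dict:
    return encoder.encode(graphs, features, **kw)
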