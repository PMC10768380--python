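"""Per-metapath residual graph convolution encoder.

Each layer propagates ``H <- act(D^{-1/2} (A + I) D^{-1/2} H W)`` with the
symmetric degree normalization; residual blocks add the identity shortcut
``G(l+1) = F(G(l)) + G(l)`` so depth does not erase the input signal. The
first layer projects the raw [similarity | interaction] features to the
hidden width; subsequent residual blocks keep that width. The per-metapath
outputs form the topology-consistency channel fused with the attention
channel downstream.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, parameter

__all__ = ["GCNLayerParams", "RGCNEncoder", "normalize_adjacency",
           "gcn_layer", "residual_block", "rgcn_encode"]

_ACTIVATIONS = {
    "tanh": lambda t: t.tanh(),
    "identity": lambda t: t,
    "leaky_relu": lambda t: t.leaky_relu(0.2),
}


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} (A + I) D^{-1/2}.

    Self-loops are added before computing degrees, so a fully isolated node
    keeps a unit self-entry. If A already carries self-loops the diagonal is
    reset first rather than doubled.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    A_tilde = A.copy()
    np.fill_diagonal(A_tilde, 0.0)
    A_tilde = A_tilde + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


class GCNLayerParams:
    """Trainable weight of one convolution layer."""

    def __init__(self, d_in: int, d_out: int, activation: str = "tanh",
                 use_residual: bool = False, rng: np.random.Generator | None = None):
        if use_residual and d_in != d_out:
            raise ValueError("residual blocks need equal input/output widths")
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(max(d_in, 1))
        self.W = parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.activation = activation
        self.use_residual = use_residual

    def parameters(self):
        return [self.W]


def gcn_layer(params: GCNLayerParams, A_norm: np.ndarray, H_in) -> Tensor:
    """One propagation step: act(A_norm H W)."""
    H = as_tensor(H_in)
    if H.shape[0] != A_norm.shape[0]:
        raise ValueError(f"features have {H.shape[0]} rows, adjacency is {A_norm.shape}")
    if H.shape[1] != params.W.shape[0]:
        raise ValueError(f"features have width {H.shape[1]}, weight expects {params.W.shape[0]}")
    out = _ACTIVATIONS[params.activation](as_tensor(A_norm) @ H @ params.W)
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("NaN/Inf in graph convolution layer output")
    return out


def residual_block(params: GCNLayerParams, A_norm: np.ndarray, G_in) -> Tensor:
    """Identity-shortcut block: G_out = gcn_layer(G_in) + G_in."""
    G = as_tensor(G_in)
    if params.W.shape[0] != params.W.shape[1] or G.shape[1] != params.W.shape[0]:
        raise ValueError("residual block requires equal input/output widths")
    return gcn_layer(params, A_norm, G) + G


class RGCNEncoder:
    """Per metapath: one projection layer then n_residual residual blocks."""

    def __init__(self, in_dim: int, metapath_names, hidden_dim: int = 64,
                 n_residual: int = 2, activation: str = "tanh",
                 dropout_rate: float = 0.4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.dropout_rate = dropout_rate
        self.layers = {}
        for name in metapath_names:
            proj = GCNLayerParams(in_dim, hidden_dim, activation, rng=rng)
            blocks = [GCNLayerParams(hidden_dim, hidden_dim, activation,
                                     use_residual=True, rng=rng)
                      for _ in range(n_residual)]
            self.layers[name] = (proj, blocks)
        self.out_dim = hidden_dim

    def parameters(self):
        out = []
        for proj, blocks in self.layers.values():
            out.extend(proj.parameters())
            for b in blocks:
                out.extend(b.parameters())
        return out

    def encode(self, graphs: dict, features, training: bool = False,
               rng: np.random.Generator | None = None) -> dict:
        """Per-metapath embeddings {G_c^rho} from the initial features.

        Input dropout is applied during training only, mirroring the
        attention channel, so neither channel can simply memorize the
        interaction profile embedded in the raw features.
        """
        out = {}
        for name, (proj, blocks) in self.layers.items():
            A_norm = normalize_adjacency(graphs[name].adjacency
                                         if hasattr(graphs[name], "adjacency")
                                         else graphs[name])
            H = as_tensor(features)
            if training and self.dropout_rate > 0:
                keep = (rng.random(H.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
                H = H * keep
            H = gcn_layer(proj, A_norm, H)
            for b in blocks:
                H = residual_block(b, A_norm, H)
            out[name] = H
        return out


def rgcn_encode(encoder: RGCNEncoder, graphs: dict, features) -> dict:
    return encoder.encode(graphs, features)
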