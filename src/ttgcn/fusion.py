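"""Metapath-level attention fusion of the two encoder channels.

Each metapath gets a global score ``s = (1/n) sum_j q'.tanh(W x_j + b)``
computed over all anchor nodes; a softmax over metapaths turns scores into
weights; the final embedding is the weighted sum of the channel mean,
``X = sum_rho a_rho (G_a^rho + G_c^rho) / 2``. One parameter set (W, b, q)
is shared across all metapaths of a node type, and drugs and targets carry
separate parameter sets. Scores are computed on the attention-channel
embeddings and the same weights reweight both channels.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, parameter

__all__ = ["FusionParams", "metapath_score", "metapath_weights", "fuse", "fuse_channels"]


class FusionParams:
    """Shared semantic-attention parameters W_f, b_f, q for one node type."""

    def __init__(self, in_dim: int, att_dim: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(max(in_dim, 1))
        self.W_f = parameter(rng.uniform(-bound, bound, size=(in_dim, att_dim)))
        self.b_f = parameter(np.zeros((1, att_dim)))
        self.q = parameter(rng.uniform(-bound, bound, size=(att_dim, 1)))

    def parameters(self):
        return [self.W_f, self.b_f, self.q]


def metapath_score(params: FusionParams, X_rho) -> Tensor:
    """Scalar semantic score of one metapath, averaged over all nodes."""
    X = as_tensor(X_rho)
    if X.shape[0] == 0:
        raise ValueError("metapath_score needs a nonempty node set")
    per_node = (X @ params.W_f + params.b_f).tanh() @ params.q   # n x 1
    return per_node.sum() * (1.0 / X.shape[0])


def metapath_weights(scores: dict) -> dict:
    """Softmax over metapath scores; returns scalar weights summing to 1.

    Accepts plain floats or autodiff scalars; a constant max-shift keeps the
    exponentials overflow-safe without changing values or gradients.
    """
    if not scores:
        raise ValueError("need at least one metapath")
    ts = {k: as_tensor(v) for k, v in scores.items()}
    shift = max(float(t.data) for t in ts.values())
    exps = {k: (t - shift).exp() for k, t in ts.items()}
    total = None
    for e in exps.values():
        total = e if total is None else total + e
    inv = total.pow(-1.0)
    return {k: e * inv for k, e in exps.items()}


def fuse(weights: dict, gat_embs: dict, gcn_embs: dict) -> Tensor:
    """X = sum_rho a_rho (G_a^rho + G_c^rho) / 2 over the shared weights."""
    out = None
    for name, a in weights.items():
        ga, gc = as_tensor(gat_embs[name]), as_tensor(gcn_embs[name])
        if ga.shape != gc.shape:
            raise ValueError(f"channel width mismatch on metapath {name!r}: "
                             f"{ga.shape} vs {gc.shape}")
        term = as_tensor(a) * ((ga + gc) * 0.5)
        out = term if out is None else out + term
    return out


def fuse_channels(params: FusionParams, gat_embs: dict, gcn_embs: dict | None = None):
    """Score on the attention channel, softmax, and fuse; returns (X, weights).

    With `gcn_embs` None (single-channel ablation) the weighted sum runs over
    the one available channel without halving.
    """
    ref = gat_embs if gat_embs else gcn_embs
    scores = {name: metapath_score(params, emb) for name, emb in ref.items()}
    weights = metapath_weights(scores)
    if gat_embs and gcn_embs:
        X = fuse(weights, gat_embs, gcn_embs)
    else:
        chan = gat_embs or gcn_embs
        X = None
        for name, a in weights.items():
            term = as_tensor(a) * as_tensor(chan[name])
            X = term if X is None else X + term
    return X, {k: float(v.data) for k, v in weights.items()}
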