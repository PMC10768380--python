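"""Inductive matrix completion head and end-to-end training.

All drug-target pairs are scored as ``S = X Z1 Z2' Y'`` where X and Y are
the fused drug and target embeddings and Z1, Z2 are low-rank projection
factors (rank k << feature widths). Training minimizes the imbalance-weighted
squared reconstruction loss

    (1-alpha)/2 ||P_Omega(T - S)||_F^2 + alpha*mu/2 ||P_Omegabar(T - S)||_F^2

with Omega the observed positive pairs, mu = |Omega|/|Omegabar| computed on
the training split, and alpha in (0,1) balancing the two terms. Gradients
flow through both encoder channels, the fusion attention, and the factors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, as_tensor, parameter
from .fusion import FusionParams, fuse_channels
from .gat import GATEncoder
from .hetnet import HeteroNetwork, compose_metapath, default_metapaths, initial_features
from .rgcn import RGCNEncoder

__all__ = ["IMCModel", "score_matrix", "imc_loss", "imbalance_weight",
           "TTGCN", "TrainResult", "train"]


@dataclass
class IMCModel:
    """Low-rank projection factors and loss weights."""

    Z1: Tensor
    Z2: Tensor
    alpha: float
    mu: float
    k: int

    @classmethod
    def init(cls, f_r: int, f_t: int, k: int, alpha: float, mu: float,
             rng: np.random.Generator) -> "IMCModel":
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        b1, b2 = 1.0 / np.sqrt(f_r), 1.0 / np.sqrt(f_t)
        return cls(Z1=parameter(rng.uniform(-b1, b1, size=(f_r, k))),
                   Z2=parameter(rng.uniform(-b2, b2, size=(f_t, k))),
                   alpha=alpha, mu=mu, k=k)

    def parameters(self):
        return [self.Z1, self.Z2]


def score_matrix(X, Y, model: IMCModel) -> Tensor:
    """S = X Z1 Z2' Y'; rank(S) <= k."""
    X, Y = as_tensor(X), as_tensor(Y)
    if X.shape[1] != model.Z1.shape[0]:
        raise ValueError(f"drug features width {X.shape[1]} != Z1 rows {model.Z1.shape[0]}")
    if Y.shape[1] != model.Z2.shape[0]:
        raise ValueError(f"target features width {Y.shape[1]} != Z2 rows {model.Z2.shape[0]}")
    return X @ model.Z1 @ model.Z2.T @ Y.T


def imbalance_weight(T: np.ndarray, row_mask: np.ndarray | None = None) -> float:
    """mu = |Omega| / |Omegabar| over the training rows only."""
    T = np.asarray(T)
    if row_mask is not None:
        T = T[np.asarray(row_mask, dtype=bool)]
    n_pos = int(T.sum())
    n_neg = T.size - n_pos
    if n_neg == 0:
        raise ValueError("no negative pairs: mu undefined")
    return n_pos / n_neg


def imc_loss(T, S, alpha: float, mu: float, row_mask: np.ndarray | None = None):
    """Weighted squared reconstruction loss over observed/unobserved pairs.

    `row_mask` (boolean over drugs) restricts both terms to training rows,
    which is how drug-wise cross-validation hides held-out drugs.
    Returns an autodiff scalar when S is a Tensor, else a float.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    T = np.asarray(T, dtype=float)
    S_t = as_tensor(S)
    if T.shape != S_t.shape:
        raise ValueError(f"T has shape {T.shape}, S has shape {S_t.shape}")
    w = np.where(T == 1, (1.0 - alpha), alpha * mu)
    if row_mask is not None:
        w = w * np.asarray(row_mask, dtype=float)[:, None]
    loss = ((T - S_t).square() * w).sum() * 0.5
    return loss if isinstance(S, Tensor) else float(loss.data)


# ---------------------------------------------------------------------------
# End-to-end model
# ---------------------------------------------------------------------------

class TTGCN:
    """The full two-channel predictor: per-metapath encoders for drugs and
    targets, metapath-level fusion, and the low-rank completion head."""

    def __init__(self, net: HeteroNetwork, cfg, train_row_mask: np.ndarray | None = None):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.train_row_mask = (np.ones(net.n_drugs, dtype=bool)
                               if train_row_mask is None
                               else np.asarray(train_row_mask, dtype=bool))
        self.T_full = net.relation_or_zero("drug-target")

        # Hide held-out drugs' interactions from everything the model sees:
        # the drug-target relation feeds features and the r-t-r / t-r-t graphs.
        dt_train = self.T_full * self.train_row_mask[:, None]
        net_train = HeteroNetwork(
            net.n_drugs, net.n_targets, net.n_diseases, net.n_sideeffects,
            relations={**net.relations, "drug-target": dt_train},
            similarities=dict(net.similarities), node_ids=dict(net.node_ids))

        self.metapaths = {
            "drug": cfg.drug_metapaths or default_metapaths("drug", cfg.sim_threshold),
            "target": cfg.target_metapaths or default_metapaths("target", cfg.sim_threshold),
        }
        self.graphs = {t: {mp.name: compose_metapath(net_train, mp)
                           for mp in self.metapaths[t]}
                       for t in ("drug", "target")}
        self.features = {t: initial_features(net_train, t) for t in ("drug", "target")}

        width = cfg.n_heads * cfg.d_head if cfg.gat_layers > 0 else None
        gcn_hidden = cfg.gcn_hidden or width or 64
        if cfg.channels == "both" and cfg.gat_layers > 0 and width != gcn_hidden:
            raise ValueError("channel widths must match: set gcn_hidden = n_heads*d_head")

        self.encoders = {}
        for t in ("drug", "target"):
            names = [mp.name for mp in self.metapaths[t]]
            in_dim = self.features[t].shape[1]
            gat = (GATEncoder(in_dim, names, cfg.gat_layers, cfg.n_heads, cfg.d_head,
                              cfg.activation, cfg.leaky_slope, cfg.dropout, self.rng)
                   if cfg.channels in ("both", "gat") else None)
            gcn = (RGCNEncoder(in_dim, names, gcn_hidden, cfg.n_residual,
                               cfg.activation, cfg.dropout, self.rng)
                   if cfg.channels in ("both", "gcn") else None)
            out_dim = gat.out_dim if gat is not None else gcn.out_dim
            fus = FusionParams(out_dim, cfg.fusion_att_dim, self.rng)
            self.encoders[t] = (gat, gcn, fus, out_dim)

        mu = imbalance_weight(self.T_full, self.train_row_mask)
        self.imc = IMCModel.init(self.encoders["drug"][3], self.encoders["target"][3],
                                 cfg.rank_k, cfg.alpha, mu, self.rng)

    def parameters(self):
        ps = []
        for gat, gcn, fus, _ in self.encoders.values():
            if gat is not None:
                ps.extend(gat.parameters())
            if gcn is not None:
                ps.extend(gcn.parameters())
            ps.extend(fus.parameters())
        ps.extend(self.imc.parameters())
        return ps

    def forward(self, training: bool = False, rng: np.random.Generator | None = None):
        """Returns (S, X, Y, attention weights per node type)."""
        embs, att = {}, {}
        for t in ("drug", "target"):
            gat, gcn, fus, _ = self.encoders[t]
            ga = (gat.encode(self.graphs[t], self.features[t], training=training, rng=rng)
                  if gat is not None else None)
            gc = (gcn.encode(self.graphs[t], self.features[t], training=training, rng=rng)
                  if gcn is not None else None)
            embs[t], att[t] = fuse_channels(fus, ga or {}, gc)
        S = score_matrix(embs["drug"], embs["target"], self.imc)
        return S, embs["drug"], embs["target"], att


@dataclass
class TrainResult:
    model: TTGCN
    X: np.ndarray
    Y: np.ndarray
    S: np.ndarray
    loss_history: list = field(default_factory=list)
    attention_history: list = field(default_factory=list)
    mu: float = 0.0


def train(net: HeteroNetwork, cfg, train_row_mask: np.ndarray | None = None,
          T_override: np.ndarray | None = None) -> TrainResult:
    """Full-batch end-to-end training against the weighted completion loss.

    `train_row_mask` hides held-out drugs (drug-wise CV); `T_override`
    substitutes the supervision matrix (e.g. label-shuffled controls) without
    touching the network used for graphs and features. Deterministic given
    cfg.seed.
    """
    model = TTGCN(net, cfg, train_row_mask)
    if T_override is not None:
        model.T_full = np.asarray(T_override, dtype=float)
        model.imc.mu = imbalance_weight(model.T_full, model.train_row_mask)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    drop_rng = np.random.default_rng(model.rng.integers(2**31))
    losses, att_log = [], []
    for epoch in range(cfg.epochs):
        S, _, _, att = model.forward(training=True, rng=drop_rng)
        loss = imc_loss(model.T_full, S, model.imc.alpha, model.imc.mu,
                        row_mask=model.train_row_mask)
        val = float(loss.data)
        if not np.isfinite(val):
            raise FloatingPointError(f"loss diverged at epoch {epoch}")
        loss.backward()
        opt.step()
        losses.append(val)
        att_log.append(att)
    S, X, Y, att = model.forward(training=False)
    return TrainResult(model=model, X=X.data, Y=Y.data, S=S.data,
                       loss_history=losses, attention_history=att_log,
                       mu=model.imc.mu)
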