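"""Run configuration: hyperparameters, CV settings, file paths.

Defaults follow the published final configuration where one is printed
(Tanh activation, learning rate 0.001, 1000 epochs, dropout 0.4); the
remaining knobs carry documented package defaults. `batch_size` is retained
for config compatibility but training is full-batch (the completion loss is
defined over the whole matrix), so the field is currently reserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

__all__ = ["ModelConfig", "CVConfig", "RunConfig", "load_config", "save_config"]


@dataclass
class ModelConfig:
    n_heads: int = 4
    d_head: int = 64
    gat_layers: int = 1
    gcn_hidden: int | None = None      # defaults to n_heads * d_head
    n_residual: int = 2
    fusion_att_dim: int = 32
    rank_k: int = 64
    alpha: float = 0.5
    activation: str = "tanh"
    leaky_slope: float = 0.2
    dropout: float = 0.4
    learning_rate: float = 0.001
    epochs: int = 1000
    batch_size: int = 64               # reserved; training is full-batch
    channels: str = "both"             # both | gat | gcn
    sim_threshold: float = 0.5
    seed: int = 0
    drug_metapaths: list | None = None
    target_metapaths: list | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0,1)")
        if self.channels not in ("both", "gat", "gcn"):
            raise ValueError("channels must be 'both', 'gat' or 'gcn'")
        if self.epochs < 0 or self.rank_k < 1:
            raise ValueError("epochs must be >= 0 and rank_k >= 1")


@dataclass
class CVConfig:
    n_folds: int = 10
    seed: int = 0
    mode: str = "drug"                 # drug-wise row holdout (pair-wise off by default)
    mcc_threshold: float = 0.5
    recall_k_percents: tuple = (5, 10, 15, 20, 30)


@dataclass
class RunConfig:
    network_dir: str = "network"
    output_dir: str = "out"
    model: ModelConfig = field(default_factory=ModelConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cv"]["recall_k_percents"] = list(d["cv"]["recall_k_percents"])
        return d


def _from_dict(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = _from_dict(ModelConfig, raw.pop("model", {}))
    cv_raw = raw.pop("cv", {})
    if "recall_k_percents" in cv_raw:
        cv_raw["recall_k_percents"] = tuple(cv_raw["recall_k_percents"])
    cv = _from_dict(CVConfig, cv_raw)
    cfg = RunConfig(model=model, cv=cv, **raw)
    cfg.model.validate()
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
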