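"""Seeded synthetic heterogeneous networks with planted low-rank structure.

The generator emulates the regime of the reference drug-target benchmark:
sparse binary relations over four node types and a severely imbalanced
interaction matrix whose positives are exactly the top entries of a low-rank
latent score matrix (thresholding, not Bernoulli draws, so the signal is
sharply low-rank and recovery is a crisp test). Auxiliary relations carry
genuine signal — nodes with similar latent factors share neighbors — with a
pure-noise mode for ablation-style controls. Similarity matrices are the
rescaled latent cosine similarities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hetnet import HeteroNetwork

__all__ = ["SynthConfig", "GroundTruth", "generate", "luo_scale_counts"]

_DEFAULT_DENSITIES = {
    "drug-drug": 0.05,
    "drug-disease": 0.05,
    "drug-sideeffect": 0.05,
    "target-target": 0.05,
    "target-disease": 0.05,
}


@dataclass
class SynthConfig:
    """Default scale: 60 drugs x 90 targets with ~1:100 imbalance, the
    package's scaled-down stand-in for the benchmark's 1:555 regime."""

    n_drugs: int = 60
    n_targets: int = 90
    n_diseases: int = 30
    n_sideeffects: int = 20
    latent_rank: int = 4
    positive_rate: float = 0.01
    relation_densities: dict = field(default_factory=lambda: dict(_DEFAULT_DENSITIES))
    noise_flip_rate: float = 0.0
    noisy_auxiliaries: bool = False
    seed: int = 0

    def validate(self) -> None:
        probs = [self.positive_rate, self.noise_flip_rate,
                 *self.relation_densities.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        if round(self.positive_rate * self.n_drugs * self.n_targets) < 1:
            raise ValueError("positive_rate yields zero planted interactions")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")


@dataclass
class GroundTruth:
    drug_factors: np.ndarray
    target_factors: np.ndarray
    latent_scores: np.ndarray
    clean_T: np.ndarray


def _cosine01(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cosine similarity rescaled to [0,1]."""
    an = A / np.linalg.norm(A, axis=1, keepdims=True)
    bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    return np.clip((an @ bn.T + 1.0) / 2.0, 0.0, 1.0)


def _signal_edges(lat_a, lat_b, density, rng, noisy=False) -> np.ndarray:
    """Bernoulli edges with probability increasing in latent similarity,
    rescaled so the expected density matches the configured one."""
    if noisy:
        p = np.full((lat_a.shape[0], lat_b.shape[0]), density)
    else:
        aff = _cosine01(lat_a, lat_b)
        p = np.clip(density * aff / max(aff.mean(), 1e-12), 0.0, 1.0)
    return (rng.random(p.shape) < p).astype(float)


def generate(cfg: SynthConfig):
    """Returns (HeteroNetwork, GroundTruth); bit-identical for a given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m, n, k = cfg.n_drugs, cfg.n_targets, cfg.latent_rank
    U = rng.normal(size=(m, k))
    V = rng.normal(size=(n, k))
    D = rng.normal(size=(cfg.n_diseases, k))
    E = rng.normal(size=(cfg.n_sideeffects, k))

    scores = U @ V.T
    n_pos = int(round(cfg.positive_rate * m * n))
    cut = np.sort(scores.ravel())[-n_pos]
    clean_T = (scores >= cut).astype(float)
    T = clean_T.copy()
    if cfg.noise_flip_rate > 0:
        flip = rng.random(T.shape) < cfg.noise_flip_rate
        T = np.where(flip, 1.0 - T, T)
    if T.sum() == 0:
        raise ValueError("noise flipped away every positive; adjust rates")

    dens = {**_DEFAULT_DENSITIES, **cfg.relation_densities}
    noisy = cfg.noisy_auxiliaries

    def within(lat, density):
        A = _signal_edges(lat, lat, density, rng, noisy)
        A = np.triu(A, k=1)
        return A + A.T

    relations = {
        "drug-drug": within(U, dens["drug-drug"]),
        "drug-target": T,
        "drug-disease": _signal_edges(U, D, dens["drug-disease"], rng, noisy),
        "drug-sideeffect": _signal_edges(U, E, dens["drug-sideeffect"], rng, noisy),
        "target-target": within(V, dens["target-target"]),
        "target-disease": _signal_edges(V, D, dens["target-disease"], rng, noisy),
    }
    sim_d = _cosine01(U, U)
    sim_t = _cosine01(V, V)
    np.fill_diagonal(sim_d, 1.0)
    np.fill_diagonal(sim_t, 1.0)
    sim_d = (sim_d + sim_d.T) / 2.0
    sim_t = (sim_t + sim_t.T) / 2.0
    net = HeteroNetwork(m, n, cfg.n_diseases, cfg.n_sideeffects,
                        relations=relations,
                        similarities={"drug-sim": sim_d, "target-sim": sim_t})
    net.validate()
    return net, GroundTruth(U, V, scores, clean_T)


def luo_scale_counts(drugs: int = 708, targets: int = 1512, positives: int = 1923,
                     diseases: int = 5603, drug_disease_assocs: int = 199214) -> dict:
    """Reference-benchmark profile and its implied class imbalance."""
    if positives <= 0:
        raise ValueError("imbalance ratio undefined without positives")
    total = drugs * targets
    negatives = total - positives
    return {
        "drugs": drugs, "targets": targets, "positives": positives,
        "diseases": diseases, "drug_disease_assocs": drug_disease_assocs,
        "total_pairs": total, "negatives": negatives,
        "neg_pos_ratio": negatives / positives,
        "neg_pos_ratio_floor": negatives // positives,
        "mu": positives / negatives,
    }
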