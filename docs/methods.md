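# Methods note

## Model

`ttgcn` predicts drug–target interactions (DTIs) from a heterogeneous
biomedical network with four node types (drug, target/protein, disease, side
effect), six binary relation types and two similarity matrices. The model has
four stages.

**Metapath neighbor graphs.** For each node type, a set of metapaths (e.g.
drug–disease–drug) is composed by boolean chaining of the relation matrices;
the diagonal is zeroed and self-loops are added so every neighborhood is
non-empty. Similarity matrices enter a chain after binarization at a
threshold (default 0.5 for target sequence similarity). Defaults: drugs use
{r–r, r–d–r, r–se–r, r–t–r}; targets use {t–t, t–d–t, t–r–t, t–sim–t}.

**Connectivity channel (GAT).** Per metapath graph, a multi-head graph
attention layer: per head, features are projected by `W_t`, per-edge logits
are `LeakyReLU(g^T [Wh_i || Wh_j])`, softmax-normalized over each node's
metapath neighborhood, and used to average the projected neighbors; heads are
concatenated and passed through Tanh. Dropout is applied to inputs and
attention coefficients during training.

**Topology channel (R-GCN).** Per metapath graph, a projection GCN layer
followed by residual blocks `G_{l+1} = act(Â G_l W) + G_l`, where
`Â = D̃^{-1/2}(A+I)D̃^{-1/2}` is the symmetric normalization (used in every
layer). Input dropout is applied during training; without it this channel
memorizes the interaction block embedded in the initial features through the
residual/self-loop shortcut and the combined model generalizes worse than
either channel alone.

**Fusion and completion.** Per-metapath embeddings from both channels are
fused with metapath-level (semantic) attention: each metapath gets the score
`mean_i q^T tanh(W x_i + b)`, softmax over metapaths gives weights `a_ρ`, and
the final embedding is `X = Σ_ρ a_ρ (G^GAT_ρ + G^GCN_ρ)/2` (channel mean, so
single-channel ablations use the same scale). Scores are the inductive
matrix completion bilinear form `S = X Z1 Z2^T Y^T` with rank-`k` factors
`Z1, Z2`, trained end-to-end with the weighted reconstruction loss

```
L = (1-α)/2 · ‖P_Ω(T - S)‖²_F  +  α·μ/2 · ‖P_Ω̄(T - S)‖²_F,
```

where `Ω` is the observed positive set and `μ = |Ω|/|Ω̄|` is the imbalance
weight computed on the training rows only. At the benchmark scale printed in
the literature (708 drugs, 1512 proteins, 1923 interactions) the
negative:positive ratio floors to 555.

## Initial features

Drug features are `[drug-similarity | T]` and target features are
`[target-similarity | T^T]`, where `T` is the training interaction matrix.
Held-out drugs' rows of `T` are zeroed **before** building features, metapath
graphs, the loss mask, and `μ`, so no information about test interactions
reaches training.

## Optimization and numerics

- Gradients come from a small reverse-mode autodiff engine (NumPy); every
  primitive's gradient is verified against central finite differences in the
  test suite, and the completion-loss gradient is checked to 1e-4.
- Adam, full-batch: the loss couples every matrix entry, so mini-batching is
  not implemented; `batch_size` is a reserved config field.
- Softmaxes subtract the row maximum before exponentiation; masked rows with
  no neighbors are rejected rather than silently zeroed.
- Ranking metrics use the pessimistic tie order (ties sorted positives-last);
  AUROC uses the rank-sum identity on midranks, AUPR is step-wise average
  precision without interpolation, and the paired Wilcoxon test uses an exact
  tie-aware rank-sum distribution for n ≤ 25 and a tie/continuity-corrected
  normal approximation above that.
- All randomness flows from `numpy.random.default_rng` seeds; identical seeds
  give byte-identical loss logs and evaluation reports.

## Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| `n_heads`, `d_head` | 4, 64 | literature-scale width |
| `gcn_hidden` | `n_heads·d_head` | channels must fuse at equal width |
| `n_residual` | 2 | two residual blocks |
| `fusion_att_dim` | 32 | semantic-attention hidden width |
| `rank_k` | 64 | IMC factor rank |
| `alpha` | 0.5 | balances the two loss terms |
| `activation` | tanh | as printed |
| `dropout` | 0.4 | as printed; applied in both channels |
| `learning_rate` | 0.001 | as printed |
| `epochs` | 1000 | as printed |
| `sim_threshold` | 0.5 | target-similarity binarization |

## Scaled-down reference experiment

`ttgcn.experiments` freezes the fixture-scale protocol used by the tests, the
acceptance script, and the README: the synthetic fixture (60 drugs × 90
targets, latent rank 4, ~1:100 imbalance, seed 0), pooled 3-fold drug-wise
cross-validation, model width 16 (`n_heads=2, d_head=8, gcn_hidden=16,
rank_k=8, fusion_att_dim=16, n_residual=1`), learning rate 0.005, 300
epochs, seeds 1–3. Width 16 is used because at width 32 the combined model
is still converging at 300 epochs while the single-channel ablations have
already converged, which would confound the channel comparison with an
optimization budget artifact. Under this protocol the full model reaches
mean pooled AUROC 0.844 and beats both ablations (GAT-only 0.808, GCN-only
0.806); with shuffled labels the AUROC stays in [0.51, 0.56].

## Synthetic generator: scope and limits

The generator plants an exactly rank-4 signal: latent factors
`U ∈ R^{60×4}, V ∈ R^{90×4}` with standard normal entries; the positives are
exactly the top `positive_rate` quantile of `U V^T`. Auxiliary relations
(drug–drug, drug–disease, drug–side-effect, target–target, target–disease)
are Bernoulli with probabilities proportional to rescaled cosine affinities
of the latent factors, and similarity matrices are `(cos+1)/2`. An optional
`noise_flip_rate` flips labels. This tests *recoverability of a planted
low-rank signal through the heterogeneous channels*, nothing more: it has no
chemistry, no realistic degree distributions, and its auxiliary relations are
conditionally independent given the latent factors, unlike real biomedical
networks. Published benchmark numbers (AUROC ≈ 0.975 on the Luo dataset) are
out of scope; they need the external dataset.

## Limitations

- Dense NumPy matrices throughout: fine to a few thousand nodes per type,
  not intended for genome-scale networks.
- Full-batch optimization only; the printed batch size 64 is not reproduced.
- The 10-fold CV is drug-wise (rows held out); pair-wise and cold-target
  splits are not implemented.
- The generator's positives are noiseless by default; `noise_flip_rate`
  exists but the reference experiment does not use it.
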