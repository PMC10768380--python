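"""Evaluation protocol: drug-wise 10-fold CV, ranking metrics, paired tests.

Held-out drugs have their whole interaction row hidden from training (the
loss masks, the imbalance weight mu, the drug-target graphs and the feature
matrices). Pooled (micro) AUROC/AUPR over all held-out pairs are the headline
numbers; per-drug metrics feed the threshold table, recall@top-k, coverage
and the paired Wilcoxon signed-rank comparisons.

Tie handling is conservative: at equal score, positives rank after negatives
for recall@k and coverage, while AUROC uses midranks via the rank-sum
(Mann-Whitney) identity.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from . import imc
from .hetnet import HeteroNetwork

__all__ = ["CVFolds", "EvalReport", "make_folds", "confusion_metrics",
           "ranking_curves", "recall_at_topk", "coverage", "wilcoxon_paired",
           "run_cv", "write_report"]


@dataclass
class CVFolds:
    n_folds: int
    assignment: np.ndarray   # drug index -> fold id
    seed: int


def make_folds(m: int, n_folds: int, seed: int) -> CVFolds:
    """Seeded uniform permutation chunked into near-equal groups."""
    if n_folds <= 0:
        raise ValueError("n_folds must be positive")
    if n_folds > m:
        raise ValueError(f"cannot make {n_folds} folds from {m} drugs")
    perm = np.random.default_rng(seed).permutation(m)
    assignment = np.empty(m, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        assignment[chunk] = f
    return CVFolds(n_folds=n_folds, assignment=assignment, seed=seed)


@dataclass
class ConfusionMetrics:
    tpr: float
    fpr: float
    precision: float
    recall: float
    mcc: float


def confusion_metrics(labels, predictions) -> ConfusionMetrics:
    """TPR/FPR/precision/recall/MCC from binary labels and binary predictions.

    An MCC denominator of zero yields MCC = 0 by convention.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.size == 0:
        raise ValueError("empty input")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(den) if den else 0.0
    return ConfusionMetrics(tpr, fpr, prec, tpr, float(mcc))


def ranking_curves(labels, scores) -> tuple:
    """(AUROC, AUPR): rank-sum identity with midranks; step-wise AP."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ranking metrics need at least one positive and one negative")
    r = rankdata(s)
    auroc = (r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    aupr = float(average_precision_score(y, s))
    return float(auroc), aupr


def _pessimistic_order(labels, scores) -> np.ndarray:
    """Descending score; within a tie, negatives before positives."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    return np.lexsort((y, -s))


def recall_at_topk(labels, scores, k_percents=(5, 10, 15, 20, 30)) -> dict:
    """Recall among the ceil(k% * N) top-scored items, pessimistic ties."""
    y = np.asarray(labels).astype(int)
    if y.sum() == 0:
        raise ValueError("recall@k undefined without positives")
    order = _pessimistic_order(y, scores)
    n = y.size
    out = {}
    for k in k_percents:
        top = int(np.ceil(k / 100.0 * n))
        out[k] = float(y[order[:top]].sum() / y.sum())
    return out


def coverage(labels, scores) -> int:
    """1-based rank of the last positive in the pessimistic descending order."""
    y = np.asarray(labels).astype(int)
    if y.sum() == 0:
        raise ValueError("coverage undefined without positives")
    order = _pessimistic_order(y, scores)
    return int(np.nonzero(y[order])[0][-1] + 1)


def wilcoxon_paired(metric_a, metric_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-drug metrics.

    Zero differences are dropped; tied absolute differences get midranks.
    The null distribution is exact (rank-sum convolution over all 2^n sign
    patterns) for n <= 25 and a normal approximation with tie and continuity
    corrections otherwise. All-zero differences give p = 1.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    r = rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    if n <= 25:
        r2 = np.rint(2 * r).astype(int)      # doubled midranks are integers
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for v in r2:
            nxt = counts.copy()
            nxt[v:] += counts[:total + 1 - v]
            counts = nxt
        counts /= 2.0 ** n
        w2 = int(np.rint(2 * w_plus))
        p_le = counts[:w2 + 1].sum()
        p_ge = counts[w2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = n * (n + 1) / 4.0
    _, t_counts = np.unique(r, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (t_counts**3 - t_counts).sum() / 48.0
    cc = 0.5 * np.sign(w_plus - mean)
    z = (w_plus - mean - cc) / np.sqrt(var)
    from scipy.stats import norm
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


@dataclass
class EvalReport:
    auroc: float
    aupr: float
    mcc: float
    auroc_macro: float
    aupr_macro: float
    per_drug: pd.DataFrame
    recall_at_k: dict
    coverage_mean: float
    threshold_table: dict
    n_drugs_skipped: int
    loss_histories: list = field(default_factory=list)
    pooled_labels: np.ndarray | None = None
    pooled_scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"auroc": self.auroc, "aupr": self.aupr, "mcc": self.mcc,
                "auroc_macro": self.auroc_macro, "aupr_macro": self.aupr_macro,
                "recall_at_k": {str(k): v for k, v in self.recall_at_k.items()},
                "coverage_mean": self.coverage_mean,
                "threshold_table": self.threshold_table,
                "n_drugs_skipped": self.n_drugs_skipped}


def run_cv(net: HeteroNetwork, model_cfg, cv_cfg) -> EvalReport:
    """Drug-wise cross-validation of the full pipeline.

    Each fold hides its drugs' interaction rows, trains end-to-end, and
    scores the hidden rows; metrics pool all held-out pairs (micro) and
    average per drug (macro). Deterministic given the config seeds.
    """
    m, n = net.n_drugs, net.n_targets
    T = net.relation_or_zero("drug-target")
    folds = make_folds(m, cv_cfg.n_folds, cv_cfg.seed)
    S_heldout = np.zeros((m, n))
    losses = []
    for f in range(folds.n_folds):
        test = folds.assignment == f
        fold_cfg = dataclasses.replace(
            model_cfg, seed=int((model_cfg.seed + 7919 * (f + 1)) % 2**31))
        res = imc.train(net, fold_cfg, train_row_mask=~test)
        S_heldout[test] = res.S[test]
        losses.append(res.loss_history)

    labels, scores = T.ravel(), S_heldout.ravel()
    auroc, aupr = ranking_curves(labels, scores)
    mcc = confusion_metrics(labels, scores >= cv_cfg.mcc_threshold).mcc

    rows, rec_acc, cov_acc, skipped = [], [], [], 0
    for i in range(m):
        y, s = T[i], S_heldout[i]
        if y.sum() == 0 or y.sum() == y.size:
            skipped += 1
            continue
        a, p = ranking_curves(y, s)
        rows.append({"drug": net.ids("drug")[i], "auroc": a, "aupr": p})
        rec_acc.append(recall_at_topk(y, s, cv_cfg.recall_k_percents))
        cov_acc.append(coverage(y, s))
    per_drug = pd.DataFrame(rows, columns=["drug", "auroc", "aupr"])
    recall_mean = {k: float(np.mean([r[k] for r in rec_acc])) if rec_acc else float("nan")
                   for k in cv_cfg.recall_k_percents}
    table = {}
    if len(per_drug):
        for delta in (0.9, 0.8, 0.7):
            table[f"auroc>{delta}"] = float((per_drug["auroc"] > delta).mean())
        for delta in (0.8, 0.5, 0.3):
            table[f"aupr>{delta}"] = float((per_drug["aupr"] > delta).mean())
    return EvalReport(
        auroc=auroc, aupr=aupr, mcc=mcc,
        auroc_macro=float(per_drug["auroc"].mean()) if len(per_drug) else float("nan"),
        aupr_macro=float(per_drug["aupr"].mean()) if len(per_drug) else float("nan"),
        per_drug=per_drug, recall_at_k=recall_mean,
        coverage_mean=float(np.mean(cov_acc)) if cov_acc else float("nan"),
        threshold_table=table, n_drugs_skipped=skipped, loss_histories=losses,
        pooled_labels=labels, pooled_scores=scores)


def write_report(report: EvalReport, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    report.per_drug.to_csv(os.path.join(outdir, "per_drug.tsv"), sep="\t", index=False)
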