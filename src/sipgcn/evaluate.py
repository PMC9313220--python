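"""Evaluation protocol: confusion metrics, ROC/AUC and repeated five-fold CV.

Metrics are the confusion-matrix formulas

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Spe = TN / (TN + FP)
    F1  = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

with SIP as the positive class and a documented zero-denominator
convention (the metric is 0).  Cross-validation shuffles the data into
five disjoint, approximately equal subsets, uses each subset once as the
test set, and reports the mean and sample standard deviation over the five
folds; the whole procedure can be repeated (100 repetitions for a full
run) and aggregated across repetitions to damp the split randomness.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from sipgcn import classifiers as _clf
from sipgcn import featurize as _feat
from sipgcn import graph_fastgcn as _gcn
from sipgcn.io_formats import ProteinRecord, PSSMMatrix

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Acc", "Spe", "F1", "MCC", "AUC")


@dataclass
class ConfusionCounts:
    """2x2 confusion tabulation with SIP (label 1) as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Tabulate TP/TN/FP/FN from true labels and binary predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def classification_metrics(c: ConfusionCounts) -> Dict[str, float]:
    """Accuracy, specificity, F1 and Matthews correlation from counts.

    Any metric whose denominator is zero is defined as 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")

    def ratio(num: float, den: float) -> float:
        if den == 0:
            logger.debug("zero denominator; metric defined as 0")
            return 0.0
        return num / den

    mcc_den = math.sqrt(
        float(c.TP + c.FP) * float(c.TN + c.FN) * float(c.TP + c.FN) * float(c.TN + c.FP)
    )
    return {
        "Acc": ratio(c.TP + c.TN, c.total),
        "Spe": ratio(c.TN, c.TN + c.FP),
        "F1": ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
        "MCC": ratio(c.TP * c.TN - c.FP * c.FN, mcc_den),
    }


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> Tuple[float, List[Tuple[float, float]]]:
    """ROC curve by threshold sweep and its trapezoidal area.

    Ties are grouped at a single threshold, so the area equals the
    Mann-Whitney statistic P(score+ > score-) + 1/2 P(tie).  Returns
    ``(auc, [(fpr, tpr), ...])`` with points from (0, 0) to (1, 1).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last index of each tie block (one ROC point per threshold)
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def five_fold_split(
    n: int,
    seed: int,
    *,
    n_folds: int = 5,
    stratify_labels: Optional[Sequence[int]] = None,
) -> List[np.ndarray]:
    """Shuffle indices 0..n-1 into five disjoint folds of size within 1.

    Folds are not stratified by default (``stratify_labels`` enables
    per-class balancing).  Reproducible from ``seed``.
    """
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {n}")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        perm = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(perm, n_folds)]
    y = np.asarray(stratify_labels, dtype=int)
    folds: List[List[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for i, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[i].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


@dataclass
class EvalReport:
    """Per-fold metric rows with mean +/- std aggregates.

    ``rows`` holds one dict per (repetition, fold) with the confusion
    counts and the five metrics; the aggregate mean is the arithmetic mean
    of the fold values and ``std`` the sample (n-1) standard deviation,
    matching the "Average +/- std" rows of a five-fold table.  AUC on a
    degenerate single-class fold is recorded as NaN and excluded from its
    aggregate.
    """

    rows: List[Dict[str, float]]
    fold_assignments: List[List[np.ndarray]]
    repetitions: int
    seed: int
    config: Dict[str, object] = field(default_factory=dict)
    #: pooled held-out (index, label, score) triples from the first
    #: repetition, for ROC export; filled when collect_scores is requested.
    pooled_scores: Optional[List[Tuple[int, int, float]]] = None

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([row[name] for row in self.rows], dtype=float)

    @property
    def mean(self) -> Dict[str, float]:
        return {m: float(np.nanmean(self.metric_values(m))) for m in METRIC_NAMES}

    @property
    def std(self) -> Dict[str, float]:
        out = {}
        for m in METRIC_NAMES:
            vals = self.metric_values(m)
            vals = vals[~np.isnan(vals)]
            out[m] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return out

    def to_dict(self) -> Dict[str, object]:
        return {
            "seed": self.seed,
            "repetitions": self.repetitions,
            "config": self.config,
            "rows": self.rows,
            "mean": self.mean,
            "std": self.std,
            "fold_assignments": [
                [fold.tolist() for fold in rep] for rep in self.fold_assignments
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def table(self) -> str:
        """Render per-fold rows plus the Average +/- std line."""
        header = "rep fold  " + "  ".join(f"{m:>7s}" for m in METRIC_NAMES)
        lines = [header]
        for row in self.rows:
            lines.append(
                f"{int(row['repetition']):3d} {int(row['fold']):4d}  "
                + "  ".join(f"{row[m]:7.4f}" for m in METRIC_NAMES)
            )
        mean, std = self.mean, self.std
        lines.append(
            "Average   "
            + "  ".join(f"{mean[m]:.4f}±{std[m]:.4f}" for m in METRIC_NAMES)
        )
        return "\n".join(lines)


def _derive_seed(master: int, *parts: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    h = np.uint64(master)
    for p in parts:
        h = (h * np.uint64(1000003) + np.uint64(p) + np.uint64(0x9E3779B9)) % np.uint64(
            2**31 - 1
        )
    return int(h)


def _fold_scores(
    X_base: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config,
    fold_seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit the configured pipeline on the training fold, score the test fold."""
    if config.feature_scheme == "gcn":
        graph = _gcn.build_knn_graph(
            X_base, k=config.graph_k, sampling=config.graph_sampling, labels=y
        )
        train_cfg = config.gcn
        model = _gcn.train_fastgcn(
            graph,
            _replace_seed(train_cfg, fold_seed),
            train_nodes=train_idx,
        )
        emb = _gcn.extract_embeddings(model, graph)
        Xtr, Xte = emb[train_idx], emb[test_idx]
    else:  # feature ablation: descriptors go straight to the classifier
        Xtr, Xte = X_base[train_idx], X_base[test_idx]
    return _clf.fit_predict(
        config.classifier,
        Xtr,
        y[train_idx],
        Xte,
        seed=fold_seed,
        n_trees=config.n_trees,
        knn_k=config.knn_k,
        elm_hidden=config.elm_hidden,
    )


def _replace_seed(train_cfg, seed: int):
    from dataclasses import replace

    return replace(train_cfg, seed=seed)


def base_features(
    records: Sequence[ProteinRecord],
    pssms: Dict[str, PSSMMatrix],
    config,
) -> np.ndarray:
    """Per-protein descriptors before any graph stage (fold-independent)."""
    scheme = "pssm_composition" if config.feature_scheme == "gcn" else config.feature_scheme
    ids = [r.id for r in records]
    return _feat.feature_matrix(pssms, ids, scheme=scheme, ac_lag=config.ac_lag)


def cross_validate(
    records: Sequence[ProteinRecord],
    pssms: Dict[str, PSSMMatrix],
    config,
    repetitions: int = 1,
    seed: int = 0,
) -> EvalReport:
    """Repeated five-fold cross-validation of the full pipeline.

    For every repetition the data are re-shuffled into five disjoint
    folds; for every fold the pipeline (descriptors -> protein graph ->
    sampled GCN embeddings -> classifier, or descriptors -> classifier for
    the feature ablation) is fitted on the four training folds and scored
    on the held-out fold.  The similarity graph spans all nodes
    (transductive) but the network's loss and the classifier only ever see
    training-fold labels.  All randomness derives from the master seed.
    """
    y = np.array([r.label for r in records], dtype=object)
    if any(v is None for v in y):
        raise ValueError("all records need labels for cross-validation")
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    X_base = base_features(records, pssms, config)
    return cross_validate_features(X_base, y, config, repetitions=repetitions, seed=seed)


def cross_validate_features(
    X_base: np.ndarray,
    y: np.ndarray,
    config,
    repetitions: int = 1,
    seed: int = 0,
    collect_scores: bool = False,
) -> EvalReport:
    """Cross-validate from precomputed per-protein descriptors."""
    n = X_base.shape[0]
    rows: List[Dict[str, float]] = []
    assignments: List[List[np.ndarray]] = []
    pooled: Optional[List[Tuple[int, int, float]]] = [] if collect_scores else None
    for rep in range(repetitions):
        split_seed = _derive_seed(seed, rep, 0)
        folds = five_fold_split(
            n,
            split_seed,
            stratify_labels=y if getattr(config, "stratified", False) else None,
        )
        assignments.append(folds)
        all_idx = np.arange(n)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            fold_seed = _derive_seed(seed, rep, f + 1)
            scores, preds = _fold_scores(
                X_base, y, train_idx, test_idx, config, fold_seed
            )
            if pooled is not None and rep == 0:
                pooled.extend(
                    (int(i), int(y[i]), float(s)) for i, s in zip(test_idx, scores)
                )
            counts = confusion(y[test_idx], preds)
            metrics = classification_metrics(counts)
            if len(np.unique(y[test_idx])) < 2:
                logger.warning(
                    "fold %d (rep %d) has a single class; AUC undefined", f, rep
                )
                metrics["AUC"] = float("nan")
            else:
                metrics["AUC"] = roc_auc(y[test_idx], scores)[0]
            rows.append(
                {
                    "repetition": rep,
                    "fold": f,
                    "TP": counts.TP,
                    "TN": counts.TN,
                    "FP": counts.FP,
                    "FN": counts.FN,
                    **metrics,
                }
            )
    return EvalReport(
        rows=rows,
        fold_assignments=assignments,
        repetitions=repetitions,
        seed=seed,
        config=_config_summary(config),
        pooled_scores=pooled,
    )


def _config_summary(config) -> Dict[str, object]:
    from dataclasses import asdict, is_dataclass

    if is_dataclass(config):
        # round-trip through json (default=str) so Path and tuple fields stay serialisable
        return json.loads(json.dumps(asdict(config), default=str))
    return {"repr": repr(config)}
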