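"""Cross-validation harness: negative sampling, stratified folds, metrics,
dimension sweeps and per-disease candidate ranking.

Protocol: negatives are drawn once from the zero cells of the association
matrix at a fixed ratio to positives, folded together with the positives,
and per fold the adjacency is rebuilt with the held-out positives masked
so no stage of training ever sees a test edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, f1_score
from sklearn.model_selection import StratifiedKFold

from .eoe import EOEState, EOETrainConfig, train_eoe
from .graph import assemble_graph, bipartite_adjacency
from .sgc import PredictorConfig, PredictorState, predict_scores, train_predictor
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledPairSet",
    "CVReport",
    "TrainedModel",
    "sample_negatives",
    "kfold_split",
    "auc",
    "auprc",
    "f1",
    "run_cv",
    "train_full",
    "rank_candidates",
    "sweep_dimension",
]


@dataclass
class LabeledPairSet:
    """(miRNA index, disease index, label) triples with provenance."""

    pairs: np.ndarray  # (n, 2) int
    labels: np.ndarray  # (n,) {0,1}
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.pairs.shape[0] != self.labels.shape[0]:
            raise ValueError("pairs and labels length mismatch")
        uniq = {tuple(p) for p in self.pairs}
        if len(uniq) != len(self.pairs):
            raise ValueError("duplicate pairs in labeled set")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class CVReport:
    fold_auc: List[float]
    fold_aupr: List[float]
    fold_f1: List[float]
    seed: int
    config: Dict[str, object] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    def to_dict(self) -> Dict[str, object]:
        return {
            "fold_auc": self.fold_auc,
            "fold_aupr": self.fold_aupr,
            "fold_f1": self.fold_f1,
            "mean_auc": self.mean_auc,
            "mean_aupr": self.mean_aupr,
            "mean_f1": self.mean_f1,
            "seed": self.seed,
            "config": self.config,
        }


# ---------------------------------------------------------------------------
# Sampling and splitting
# ---------------------------------------------------------------------------


def sample_negatives(a: np.ndarray, ratio: int, seed: int) -> LabeledPairSet:
    """Positives plus ratio-times-as-many uniform zero-cell negatives."""
    a = np.asarray(a)
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    pos = np.argwhere(a > 0)
    zeros = np.argwhere(a == 0)
    n_neg = ratio * len(pos)
    if len(zeros) < n_neg:
        raise ValueError(
            f"need {n_neg} negatives but only {len(zeros)} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zeros), size=n_neg, replace=False)
    neg = zeros[chosen]
    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(n_neg, int)])
    return LabeledPairSet(pairs=pairs, labels=labels, provenance="global")


def kfold_split(
    pair_set: LabeledPairSet, k: int, seed: int
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition; returns (train_idx, test_idx) per fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pair_set) < k:
        raise ValueError("fewer pairs than folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, test) for train, test in skf.split(pair_set.pairs, pair_set.labels)
    ]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _check_two_class(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("metrics need at least one positive and one negative")


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability that a random positive outscores a random negative
    (ties count 1/2); Mann-Whitney midrank formulation."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    _check_two_class(labels)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def f1(labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> float:
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    preds = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return float(f1_score(labels, preds, zero_division=0))


# ---------------------------------------------------------------------------
# Cross-validation pipeline
# ---------------------------------------------------------------------------


def _eoe_state_from_similarity(
    graph_w_m: np.ndarray, graph_w_d: np.ndarray
) -> EOEState:
    """Raw similarity rows as features — the SGC-only ablation input."""
    n_d = graph_w_d.shape[0]
    n_m = graph_w_m.shape[0]
    return EOEState(
        disease_vecs=graph_w_d + np.eye(n_d),
        mirna_vecs=graph_w_m + np.eye(n_m),
        harmony=np.zeros((n_d, n_m)),
    )


def run_cv(
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    a: np.ndarray,
    folds: int = 5,
    ratio: int = 5,
    seed: int = 0,
    use_eoe: bool = True,
    eoe_config: Optional[EOETrainConfig] = None,
    predictor_config: Optional[PredictorConfig] = None,
    shuffle_labels: bool = False,
    pair_set: Optional[LabeledPairSet] = None,
) -> CVReport:
    """Full leak-free cross-validation of the pipeline.

    Per fold: held-out positives are masked out of the association matrix
    before the coupled graph and propagation operator are built, the EOE
    stage (or its similarity-only ablation) and the predictor are trained
    on the training pairs only, and metrics are computed on the test fold.
    ``shuffle_labels`` permutes labels (null-model control).
    """
    a = (np.asarray(a) > 0).astype(float)
    if pair_set is None:
        pair_set = sample_negatives(a, ratio, seed)
    labels = pair_set.labels.copy()
    if shuffle_labels:
        rng = np.random.default_rng(seed + 7919)
        labels = rng.permutation(labels)
    threshold = (predictor_config or PredictorConfig()).threshold

    fold_auc: List[float] = []
    fold_aupr: List[float] = []
    fold_f1: List[float] = []
    for fold_id, (train_idx, test_idx) in enumerate(
        kfold_split(LabeledPairSet(pair_set.pairs, labels), folds, seed)
    ):
        train_pairs = pair_set.pairs[train_idx]
        test_pairs = pair_set.pairs[test_idx]
        train_labels = labels[train_idx]
        test_labels = labels[test_idx]

        # Mask held-out positive cells (the true positives of A, not the
        # possibly shuffled labels) so propagation never sees test edges.
        mask = np.zeros_like(a, dtype=bool)
        held_pos = test_pairs[a[test_pairs[:, 0], test_pairs[:, 1]] > 0]
        mask[held_pos[:, 0], held_pos[:, 1]] = True
        a_train = a * (~mask)

        # Instrumented leak checks.
        assert not np.any(a_train[mask]), "masked cell survived in training A"
        test_set = {tuple(p) for p in test_pairs}
        assert not test_set & {tuple(p) for p in train_pairs}, "fold overlap"

        graph = assemble_graph(ms, ds, a_train)
        if use_eoe:
            cfg = eoe_config or EOETrainConfig()
            cfg = EOETrainConfig(
                **{**cfg.__dict__, "seed": cfg.seed + 1000 * (fold_id + 1)}
            )
            eoe_state = train_eoe(graph, cfg)
        else:
            eoe_state = _eoe_state_from_similarity(graph.w_m, graph.w_d)

        adjacency = bipartite_adjacency(a, mask=mask)
        pcfg = predictor_config or PredictorConfig()
        pcfg = PredictorConfig(**{**pcfg.__dict__, "seed": pcfg.seed + 1000 * (fold_id + 1)})
        predictor = train_predictor(
            eoe_state, adjacency, train_pairs, train_labels, pcfg
        )
        scores = predict_scores(eoe_state, adjacency, predictor, test_pairs)
        fold_auc.append(auc(test_labels, scores))
        fold_aupr.append(auprc(test_labels, scores))
        fold_f1.append(f1(test_labels, scores, threshold))
        logger.info(
            "fold %d: AUC %.4f AUPR %.4f F1 %.4f",
            fold_id,
            fold_auc[-1],
            fold_aupr[-1],
            fold_f1[-1],
        )

    return CVReport(
        fold_auc=fold_auc,
        fold_aupr=fold_aupr,
        fold_f1=fold_f1,
        seed=seed,
        config={
            "folds": folds,
            "ratio": ratio,
            "use_eoe": use_eoe,
            "shuffle_labels": shuffle_labels,
        },
    )


# ---------------------------------------------------------------------------
# Full-data model and ranking
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Everything needed to score new pairs against the full data."""

    eoe_state: EOEState
    predictor: PredictorState
    adjacency: np.ndarray
    a: np.ndarray
    mirna_labels: List[str]
    disease_labels: List[str]


def train_full(
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    a: np.ndarray,
    ratio: int = 5,
    seed: int = 0,
    use_eoe: bool = True,
    eoe_config: Optional[EOETrainConfig] = None,
    predictor_config: Optional[PredictorConfig] = None,
) -> TrainedModel:
    """Train on all known associations (for candidate ranking)."""
    a = (np.asarray(a) > 0).astype(float)
    pair_set = sample_negatives(a, ratio, seed)
    graph = assemble_graph(ms, ds, a)
    if use_eoe:
        eoe_state = train_eoe(graph, eoe_config or EOETrainConfig(seed=seed))
    else:
        eoe_state = _eoe_state_from_similarity(graph.w_m, graph.w_d)
    adjacency = bipartite_adjacency(a)
    predictor = train_predictor(
        eoe_state,
        adjacency,
        pair_set.pairs,
        pair_set.labels,
        predictor_config or PredictorConfig(seed=seed),
    )
    return TrainedModel(
        eoe_state=eoe_state,
        predictor=predictor,
        adjacency=adjacency,
        a=a,
        mirna_labels=list(ms.labels),
        disease_labels=list(ds.labels),
    )


def rank_candidates(
    model: TrainedModel, disease: str, top_k: int = 20
) -> List[Tuple[str, float]]:
    """Top-k unassociated miRNAs for a disease, by descending score.

    Ties break by miRNA label (ascending) for reproducibility.
    """
    try:
        j = model.disease_labels.index(disease)
    except ValueError:
        raise KeyError(f"unknown disease {disease!r}") from None
    candidates = np.flatnonzero(model.a[:, j] == 0)
    if candidates.size == 0:
        return []
    pairs = np.column_stack([candidates, np.full(candidates.size, j)])
    scores = predict_scores(model.eoe_state, model.adjacency, model.predictor, pairs)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], model.mirna_labels[candidates[i]]),
    )
    return [
        (model.mirna_labels[candidates[i]], float(scores[i]))
        for i in order[:top_k]
    ]


def sweep_dimension(
    dims: Sequence[int],
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    a: np.ndarray,
    folds: int = 5,
    ratio: int = 5,
    seed: int = 0,
    use_eoe: bool = True,
    eoe_config: Optional[EOETrainConfig] = None,
    predictor_config: Optional[PredictorConfig] = None,
) -> pd.DataFrame:
    """Cross-validate once per embedding dimension; tidy table out."""
    if not dims:
        raise ValueError("dims must be nonempty")
    base = predictor_config or PredictorConfig()
    rows = []
    for z in dims:
        pcfg = PredictorConfig(**{**base.__dict__, "z": int(z)})
        report = run_cv(
            ms,
            ds,
            a,
            folds=folds,
            ratio=ratio,
            seed=seed,
            use_eoe=use_eoe,
            eoe_config=eoe_config,
            predictor_config=pcfg,
        )
        rows.append(
            {
                "dimension": int(z),
                "auc": report.mean_auc,
                "aupr": report.mean_aupr,
                "f1": report.mean_f1,
            }
        )
    return pd.DataFrame(rows)
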