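"""Simplified graph convolution over the bipartite association graph,
followed by an MLP link scorer.

Embeddings from the EOE stage live in two different spaces, so they are
first mapped into a shared Z-dimensional space.  Each convolution layer
applies a learned linear transform and then K hops of the symmetric
normalized operator S = D^{-1/2}(A+I)D^{-1/2}; there is no nonlinearity
between layers by default (the defining SGC simplification).  Pair
scoring concatenates the two node embeddings and feeds a two-layer MLP
with a sigmoid output.  Everything trains end-to-end on cross-entropy
with hand-derived gradients and Adam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .eoe import AdamOptimizer, EOEState, _log_sigmoid, _sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorState",
    "PredictorConfig",
    "PropagationOperator",
    "build_operator",
    "propagate",
    "map_features",
    "sgc_forward",
    "score_pair",
    "bce_loss",
    "train_predictor",
    "predict_scores",
]

_EPS = 1e-12


@dataclass
class PropagationOperator:
    """S = D~^{-1/2} (A + I) D~^{-1/2} with the augmented degree vector."""

    s: np.ndarray
    degrees: np.ndarray


@dataclass(frozen=True)
class PredictorConfig:
    layers: int = 2
    k: int = 2  # hops per layer
    z: int = 64  # shared embedding dimension
    mlp_hidden: int = 64
    interlayer_activation: str = "none"  # "none" | "relu"
    learning_rate: float = 1e-3
    epochs: int = 100
    seed: int = 0
    early_stopping: bool = False
    patience: int = 10
    val_fraction: float = 0.1
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("z must be >= 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.interlayer_activation not in ("none", "relu"):
            raise ValueError("interlayer_activation must be 'none' or 'relu'")


@dataclass
class PredictorState:
    """All trainable parameters of the mapping + SGC + MLP stack."""

    w_map_m: np.ndarray  # (p_m, Z)
    w_map_d: np.ndarray  # (p_d, Z)
    transforms: List[np.ndarray]  # layers x (Z, Z)
    mlp_w1: np.ndarray  # (2Z, hidden)
    mlp_b1: np.ndarray  # (hidden,)
    mlp_w2: np.ndarray  # (hidden,)
    mlp_b2: float
    k: int
    z: int
    interlayer_activation: str = "none"
    loss_history: List[float] = field(default_factory=list)


def build_operator(adj: np.ndarray) -> PropagationOperator:
    """Symmetric normalization of the self-looped adjacency."""
    adj = np.asarray(adj, dtype=float)
    if adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    a_tilde = adj + np.eye(adj.shape[0])
    degrees = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degrees)
    s = a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return PropagationOperator(s=s, degrees=degrees)


def propagate(x: np.ndarray, s: np.ndarray, k: int) -> np.ndarray:
    """k successive multiplications by the propagation operator."""
    if k < 0:
        raise ValueError("k must be >= 0")
    out = np.asarray(x, dtype=float)
    for _ in range(k):
        out = s @ out
    return out


def map_features(
    eoe_state: EOEState, w_map_m: np.ndarray, w_map_d: np.ndarray
) -> np.ndarray:
    """Project both node types into the shared space; miRNAs first."""
    x_m = eoe_state.mirna_vecs @ w_map_m
    x_d = eoe_state.disease_vecs @ w_map_d
    if x_m.shape[1] != x_d.shape[1]:
        raise ValueError("mapping matrices target different dimensions")
    return np.vstack([x_m, x_d])


def _forward_embeddings(
    eoe_state: EOEState, operator: PropagationOperator, state: PredictorState
) -> Tuple[np.ndarray, List[Tuple[np.ndarray, np.ndarray]]]:
    """Returns final embeddings and per-layer (input, pre-activation) caches."""
    sk = np.linalg.matrix_power(operator.s, state.k)
    h = map_features(eoe_state, state.w_map_m, state.w_map_d)
    caches: List[Tuple[np.ndarray, np.ndarray]] = []
    n_layers = len(state.transforms)
    for idx, t in enumerate(state.transforms):
        pre = sk @ (h @ t)
        caches.append((h, pre))
        if state.interlayer_activation == "relu" and idx < n_layers - 1:
            h = np.maximum(pre, 0.0)
        else:
            h = pre
    return h, caches


def sgc_forward(
    eoe_state: EOEState, operator: PropagationOperator, state: PredictorState
) -> np.ndarray:
    """Final (m+n) x Z node embeddings."""
    emb, _ = _forward_embeddings(eoe_state, operator, state)
    return emb


def _mlp_forward(
    z_pair: np.ndarray, state: PredictorState
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    pre1 = z_pair @ state.mlp_w1 + state.mlp_b1
    hidden = np.maximum(pre1, 0.0)
    logit = hidden @ state.mlp_w2 + state.mlp_b2
    return pre1, hidden, _sigmoid(logit)


def score_pair(
    emb_mirna: np.ndarray, emb_disease: np.ndarray, state: PredictorState
) -> float:
    """Score one (miRNA, disease) pair through the MLP head."""
    z_pair = np.concatenate([emb_mirna, emb_disease])[None, :]
    _, _, p = _mlp_forward(z_pair, state)
    return float(p[0])


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy, clamped away from log(0)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.clip(np.asarray(y_hat, dtype=float), _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(y_hat) + (1 - y) * np.log(1 - y_hat)))


def _init_state(
    p_m: int, p_d: int, config: PredictorConfig, rng: np.random.Generator
) -> PredictorState:
    def glorot(shape: Tuple[int, ...]) -> np.ndarray:
        fan = sum(shape) if len(shape) > 1 else shape[0]
        return rng.normal(scale=np.sqrt(2.0 / fan), size=shape)

    return PredictorState(
        w_map_m=glorot((p_m, config.z)),
        w_map_d=glorot((p_d, config.z)),
        transforms=[glorot((config.z, config.z)) for _ in range(config.layers)],
        mlp_w1=glorot((2 * config.z, config.mlp_hidden)),
        mlp_b1=np.zeros(config.mlp_hidden),
        mlp_w2=glorot((config.mlp_hidden,)),
        mlp_b2=0.0,
        k=config.k,
        z=config.z,
        interlayer_activation=config.interlayer_activation,
    )


def _loss_and_grads(
    eoe_state: EOEState,
    operator: PropagationOperator,
    state: PredictorState,
    mirna_idx: np.ndarray,
    disease_idx: np.ndarray,
    labels: np.ndarray,
) -> Tuple[float, Dict[str, object]]:
    n_m = eoe_state.mirna_vecs.shape[0]
    sk = np.linalg.matrix_power(operator.s, state.k)
    emb, caches = _forward_embeddings(eoe_state, operator, state)
    z = state.z

    z_pair = np.hstack([emb[mirna_idx], emb[n_m + disease_idx]])
    pre1, hidden, p = _mlp_forward(z_pair, state)
    p_c = np.clip(p, _EPS, 1.0 - _EPS)
    loss = float(-np.mean(labels * np.log(p_c) + (1 - labels) * np.log(1 - p_c)))

    batch = len(labels)
    dlogit = (p - labels) / batch
    grad_b2 = float(dlogit.sum())
    grad_w2 = hidden.T @ dlogit
    dhidden = np.outer(dlogit, state.mlp_w2)
    dpre1 = dhidden * (pre1 > 0)
    grad_w1 = z_pair.T @ dpre1
    grad_b1 = dpre1.sum(axis=0)
    dz_pair = dpre1 @ state.mlp_w1.T

    demb = np.zeros_like(emb)
    np.add.at(demb, mirna_idx, dz_pair[:, :z])
    np.add.at(demb, n_m + disease_idx, dz_pair[:, z:])

    grad_transforms: List[np.ndarray] = [np.empty(0)] * len(state.transforms)
    n_layers = len(state.transforms)
    for idx in range(n_layers - 1, -1, -1):
        h_in, pre = caches[idx]
        if state.interlayer_activation == "relu" and idx < n_layers - 1:
            demb = demb * (pre > 0)
        dy = sk @ demb  # S^k is symmetric
        grad_transforms[idx] = h_in.T @ dy
        demb = dy @ state.transforms[idx].T

    grad_map_m = eoe_state.mirna_vecs.T @ demb[:n_m]
    grad_map_d = eoe_state.disease_vecs.T @ demb[n_m:]
    grads: Dict[str, object] = {
        "w_map_m": grad_map_m,
        "w_map_d": grad_map_d,
        "transforms": grad_transforms,
        "mlp_w1": grad_w1,
        "mlp_b1": grad_b1,
        "mlp_w2": grad_w2,
        "mlp_b2": grad_b2,
    }
    return loss, grads


def train_predictor(
    eoe_state: EOEState,
    adjacency: np.ndarray,
    pairs: np.ndarray,
    labels: np.ndarray,
    config: Optional[PredictorConfig] = None,
) -> PredictorState:
    """End-to-end training of the mapping, SGC transforms and MLP.

    ``pairs`` holds (miRNA index, disease index) rows; ``adjacency`` is
    the fold-masked bipartite block matrix.  Deterministic per seed.
    """
    config = config or PredictorConfig()
    rng = np.random.default_rng(config.seed)
    operator = build_operator(adjacency)
    p_m = eoe_state.mirna_vecs.shape[1]
    p_d = eoe_state.disease_vecs.shape[1]
    state = _init_state(p_m, p_d, config, rng)

    pairs = np.asarray(pairs, dtype=int)
    labels = np.asarray(labels, dtype=float)
    mirna_idx, disease_idx = pairs[:, 0], pairs[:, 1]

    val_m = val_d = val_y = None
    if config.early_stopping and len(labels) >= 20:
        n_val = max(int(round(config.val_fraction * len(labels))), 2)
        perm = rng.permutation(len(labels))
        val_sel, train_sel = perm[:n_val], perm[n_val:]
        if len(set(labels[val_sel])) == 2:
            val_m, val_d, val_y = (
                mirna_idx[val_sel],
                disease_idx[val_sel],
                labels[val_sel],
            )
            mirna_idx, disease_idx, labels = (
                mirna_idx[train_sel],
                disease_idx[train_sel],
                labels[train_sel],
            )

    param_keys = ["w_map_m", "w_map_d", "mlp_w1", "mlp_b1", "mlp_w2", "mlp_b2"]
    opts = {key: AdamOptimizer(config.learning_rate) for key in param_keys}
    t_opts = [AdamOptimizer(config.learning_rate) for _ in range(config.layers)]

    best_val = -np.inf
    best_params = None
    stale = 0
    for epoch in range(config.epochs):
        loss, grads = _loss_and_grads(
            eoe_state, operator, state, mirna_idx, disease_idx, labels
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"predictor training diverged at epoch {epoch}: loss={loss}"
            )
        state.loss_history.append(loss)
        state.w_map_m = opts["w_map_m"].step(state.w_map_m, grads["w_map_m"])
        state.w_map_d = opts["w_map_d"].step(state.w_map_d, grads["w_map_d"])
        for i, (t, g) in enumerate(zip(state.transforms, grads["transforms"])):
            state.transforms[i] = t_opts[i].step(t, g)
        state.mlp_w1 = opts["mlp_w1"].step(state.mlp_w1, grads["mlp_w1"])
        state.mlp_b1 = opts["mlp_b1"].step(state.mlp_b1, grads["mlp_b1"])
        state.mlp_w2 = opts["mlp_w2"].step(state.mlp_w2, grads["mlp_w2"])
        state.mlp_b2 = float(
            opts["mlp_b2"].step(np.array(state.mlp_b2), np.array(grads["mlp_b2"]))
        )

        if val_m is not None:
            scores = predict_scores(
                eoe_state, adjacency, state, np.column_stack([val_m, val_d])
            )
            val_auc = _rank_auc(val_y, scores)
            if val_auc > best_val + 1e-9:
                best_val = val_auc
                best_params = _snapshot(state)
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    logger.debug("early stop at epoch %d (val AUC %.4f)", epoch, best_val)
                    break
    if best_params is not None:
        _restore(state, best_params)
    return state


def _snapshot(state: PredictorState) -> Dict[str, object]:
    return {
        "w_map_m": state.w_map_m.copy(),
        "w_map_d": state.w_map_d.copy(),
        "transforms": [t.copy() for t in state.transforms],
        "mlp_w1": state.mlp_w1.copy(),
        "mlp_b1": state.mlp_b1.copy(),
        "mlp_w2": state.mlp_w2.copy(),
        "mlp_b2": state.mlp_b2,
    }


def _restore(state: PredictorState, params: Dict[str, object]) -> None:
    state.w_map_m = params["w_map_m"]
    state.w_map_d = params["w_map_d"]
    state.transforms = params["transforms"]
    state.mlp_w1 = params["mlp_w1"]
    state.mlp_b1 = params["mlp_b1"]
    state.mlp_w2 = params["mlp_w2"]
    state.mlp_b2 = params["mlp_b2"]


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    # Mann-Whitney formulation with midranks (ties count 1/2).
    from scipy.stats import rankdata

    labels = np.asarray(labels, dtype=bool)
    ranks = rankdata(scores)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def predict_scores(
    eoe_state: EOEState,
    adjacency: np.ndarray,
    state: PredictorState,
    pairs: np.ndarray,
) -> np.ndarray:
    """Scores for (miRNA index, disease index) rows in one forward pass."""
    operator = build_operator(adjacency)
    emb = sgc_forward(eoe_state, operator, state)
    n_m = eoe_state.mirna_vecs.shape[0]
    pairs = np.asarray(pairs, dtype=int)
    z_pair = np.hstack([emb[pairs[:, 0]], emb[n_m + pairs[:, 1]]])
    _, _, p = _mlp_forward(z_pair, state)
    return p
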