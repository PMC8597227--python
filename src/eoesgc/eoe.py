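"""Link-based node embedding on the coupled heterogeneous graph.

Two node types (miRNAs, diseases) are embedded in their own spaces; a
learned harmony matrix provides a bilinear form for cross-type proximity.
The loss pulls linked nodes together (weighted by edge similarity) and
pushes every unlinked pair apart.  Training is plain NumPy with manually
derived gradients and an Adam update, which keeps runs bit-reproducible
for a given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .graph import CoupledGraph

logger = logging.getLogger(__name__)

__all__ = [
    "EOEState",
    "EOETrainConfig",
    "proximity_same",
    "proximity_cross",
    "eoe_loss",
    "train_eoe",
]


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    """log(1/(1+exp(-x))), stable for large |x|."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = -np.log1p(np.exp(-x[pos]))
    out[~pos] = x[~pos] - np.log1p(np.exp(x[~pos]))
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.exp(_log_sigmoid(np.asarray(x, dtype=float)))


@dataclass
class EOEState:
    """Trainable embeddings: disease vectors, miRNA vectors, harmony matrix."""

    disease_vecs: np.ndarray  # (n_d, p_d)
    mirna_vecs: np.ndarray  # (n_m, p_m)
    harmony: np.ndarray  # (p_d, p_m)
    loss_history: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.harmony.shape != (self.disease_vecs.shape[1], self.mirna_vecs.shape[1]):
            raise ValueError(
                "harmony matrix must be (disease dim) x (miRNA dim): "
                f"got {self.harmony.shape}"
            )
        for name, arr in (
            ("disease_vecs", self.disease_vecs),
            ("mirna_vecs", self.mirna_vecs),
            ("harmony", self.harmony),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class EOETrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    negative_strategy: str = "all_pairs"  # "all_pairs" | "sampled"
    negative_k: int = 5  # negatives per edge under "sampled"
    seed: int = 0
    init: str = "similarity"  # "similarity" | "spectral"
    spectral_rank: int = 32
    harmony_init_scale: float = 0.01
    log_every: int = 50

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.negative_strategy not in ("all_pairs", "sampled"):
            raise ValueError(f"unknown negative strategy {self.negative_strategy!r}")


def proximity_same(u: np.ndarray, v: np.ndarray) -> float:
    """Sigmoid of the inner product of two same-type embeddings."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(_sigmoid(np.array(u @ v)))


def proximity_cross(d: np.ndarray, m: np.ndarray, harmony: np.ndarray) -> float:
    """Sigmoid of the harmony-mediated bilinear form d^T M m."""
    d = np.asarray(d, dtype=float)
    m = np.asarray(m, dtype=float)
    if harmony.shape != (d.shape[0], m.shape[0]):
        raise ValueError(
            f"harmony {harmony.shape} incompatible with d {d.shape}, m {m.shape}"
        )
    return float(_sigmoid(np.array(d @ harmony @ m)))


# ---------------------------------------------------------------------------
# Masks: positive weights and negative-pair indicators
# ---------------------------------------------------------------------------


def _negative_masks(
    graph: CoupledGraph,
    strategy: str,
    k: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """0/1 masks of non-edge pairs (dd, mm symmetric zero-diag; cross n_d x n_m)."""
    neg_d = ((graph.w_d == 0).astype(float))
    np.fill_diagonal(neg_d, 0.0)
    neg_m = ((graph.w_m == 0).astype(float))
    np.fill_diagonal(neg_m, 0.0)
    neg_c = (graph.a.T == 0).astype(float)
    if strategy == "sampled":
        neg_d = _subsample_symmetric(neg_d, k * max(len(graph.e_d), 1), rng)
        neg_m = _subsample_symmetric(neg_m, k * max(len(graph.e_m), 1), rng)
        neg_c = _subsample_dense(neg_c, k * max(len(graph.e_dm), 1), rng)
    return neg_d, neg_m, neg_c


def _subsample_symmetric(
    mask: np.ndarray, n_keep: int, rng: np.random.Generator
) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(mask, 1))
    if iu.size <= n_keep:
        return mask
    keep = rng.choice(iu.size, size=n_keep, replace=False)
    out = np.zeros_like(mask)
    out[iu[keep], ju[keep]] = 1.0
    return out + out.T


def _subsample_dense(
    mask: np.ndarray, n_keep: int, rng: np.random.Generator
) -> np.ndarray:
    ii, jj = np.nonzero(mask)
    if ii.size <= n_keep:
        return mask
    keep = rng.choice(ii.size, size=n_keep, replace=False)
    out = np.zeros_like(mask)
    out[ii[keep], jj[keep]] = 1.0
    return out


def _loss_and_grads(
    state: EOEState,
    graph: CoupledGraph,
    neg_masks: Tuple[np.ndarray, np.ndarray, np.ndarray],
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Full loss plus analytic gradients w.r.t. D, Mi and the harmony matrix.

    Same-type pair sums run over unordered pairs (i < j); cross-type sums
    run over all (disease, miRNA) pairs.
    """
    D = state.disease_vecs
    Mi = state.mirna_vecs
    H = state.harmony
    neg_d, neg_m, neg_c = neg_masks

    s_dd = D @ D.T
    s_mm = Mi @ Mi.T
    s_c = D @ H @ Mi.T  # (n_d, n_m)

    pos_d = graph.w_d  # symmetric weights, zero diagonal
    pos_m = graph.w_m
    pos_c = graph.a.T * graph.w_dm

    # Symmetric same-type matrices count each unordered pair twice -> 0.5.
    loss = (
        -0.5 * np.sum(pos_d * _log_sigmoid(s_dd))
        - 0.5 * np.sum(pos_m * _log_sigmoid(s_mm))
        - np.sum(pos_c * _log_sigmoid(s_c))
        - 0.5 * np.sum(neg_d * _log_sigmoid(-s_dd))
        - 0.5 * np.sum(neg_m * _log_sigmoid(-s_mm))
        - np.sum(neg_c * _log_sigmoid(-s_c))
    )

    p_dd = _sigmoid(s_dd)
    p_mm = _sigmoid(s_mm)
    p_c = _sigmoid(s_c)

    # d(loss)/d(score) per pair: -w*(1-p) on edges, +p on negative pairs.
    f_dd = -pos_d * (1.0 - p_dd) + neg_d * p_dd
    f_mm = -pos_m * (1.0 - p_mm) + neg_m * p_mm
    f_c = -pos_c * (1.0 - p_c) + neg_c * p_c

    grad_d = f_dd @ D + f_c @ (Mi @ H.T)
    grad_m = f_mm @ Mi + f_c.T @ (D @ H)
    grad_h = D.T @ f_c @ Mi
    return float(loss), {"D": grad_d, "Mi": grad_m, "H": grad_h}


def eoe_loss(
    state: EOEState,
    graph: CoupledGraph,
    negative_strategy: str = "all_pairs",
    negative_k: int = 5,
    seed: int = 0,
) -> float:
    """Six-term positive/negative log-loss over the coupled graph."""
    rng = np.random.default_rng(seed)
    masks = _negative_masks(graph, negative_strategy, negative_k, rng)
    loss, _ = _loss_and_grads(state, graph, masks)
    return loss


class AdamOptimizer:
    """Minimal Adam; one instance per parameter tensor."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: Optional[np.ndarray] = None
        self.v: Optional[np.ndarray] = None
        self.t = 0

    def step(self, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(param)
            self.v = np.zeros_like(param)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        return param - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _initial_vectors(
    graph: CoupledGraph, config: EOETrainConfig
) -> Tuple[np.ndarray, np.ndarray]:
    # Thresholded similarity rows (diagonal restored to 1) are the raw
    # node features; the spectral option trades fidelity for dimension.
    w_d = graph.w_d + np.eye(graph.n_diseases)
    w_m = graph.w_m + np.eye(graph.n_mirnas)
    if config.init == "similarity":
        return w_d.copy(), w_m.copy()
    if config.init == "spectral":
        return (
            _spectral_factor(w_d, config.spectral_rank),
            _spectral_factor(w_m, config.spectral_rank),
        )
    raise ValueError(f"unknown init strategy {config.init!r}")


def _spectral_factor(sym: np.ndarray, rank: int) -> np.ndarray:
    rank = min(rank, sym.shape[0])
    vals, vecs = np.linalg.eigh(sym)
    order = np.argsort(np.abs(vals))[::-1][:rank]
    return vecs[:, order] * np.sqrt(np.abs(vals[order]))


def train_eoe(graph: CoupledGraph, config: Optional[EOETrainConfig] = None) -> EOEState:
    """Fit embeddings and the harmony matrix by gradient descent on the loss.

    Deterministic for a given config seed; raises on divergence.
    """
    config = config or EOETrainConfig()
    rng = np.random.default_rng(config.seed)
    d0, m0 = _initial_vectors(graph, config)
    harmony = rng.normal(
        scale=config.harmony_init_scale, size=(d0.shape[1], m0.shape[1])
    )
    state = EOEState(disease_vecs=d0, mirna_vecs=m0, harmony=harmony)
    masks = _negative_masks(graph, config.negative_strategy, config.negative_k, rng)

    opts = {key: AdamOptimizer(config.learning_rate) for key in ("D", "Mi", "H")}
    for epoch in range(config.epochs):
        loss, grads = _loss_and_grads(state, graph, masks)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"EOE training diverged at epoch {epoch}: loss={loss}"
            )
        state.loss_history.append(loss)
        state.disease_vecs = opts["D"].step(state.disease_vecs, grads["D"])
        state.mirna_vecs = opts["Mi"].step(state.mirna_vecs, grads["Mi"])
        state.harmony = opts["H"].step(state.harmony, grads["H"])
        if config.log_every and epoch % config.log_every == 0:
            logger.debug("EOE epoch %d loss %.6f", epoch, loss)
    return state
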