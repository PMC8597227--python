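"""Coupled heterogeneous graph assembly and the bipartite adjacency.

Node order convention used everywhere downstream: miRNAs occupy indices
0..m-1 and diseases occupy m..m+n-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["CoupledGraph", "assemble_graph", "bipartite_adjacency"]


@dataclass
class CoupledGraph:
    """Two similarity sub-networks joined by association edges.

    ``w_m`` / ``w_d`` are the thresholded similarity matrices with the
    diagonal zeroed (self-similarity is not an edge); ``a`` is the binary
    miRNA-by-disease association matrix; ``w_dm`` is the scalar weight
    given to every association edge.
    """

    mirna_labels: List[str]
    disease_labels: List[str]
    w_m: np.ndarray
    w_d: np.ndarray
    a: np.ndarray
    w_dm: float = 1.0

    e_m: List[Tuple[int, int, float]] = field(init=False, repr=False)
    e_d: List[Tuple[int, int, float]] = field(init=False, repr=False)
    e_dm: List[Tuple[int, int, float]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n_m, n_d = len(self.mirna_labels), len(self.disease_labels)
        if self.w_m.shape != (n_m, n_m):
            raise ValueError("w_m shape mismatch")
        if self.w_d.shape != (n_d, n_d):
            raise ValueError("w_d shape mismatch")
        if self.a.shape != (n_m, n_d):
            raise ValueError("association matrix shape mismatch")
        self.e_m = [
            (int(i), int(j), float(self.w_m[i, j]))
            for i, j in zip(*np.nonzero(np.triu(self.w_m, 1)))
        ]
        self.e_d = [
            (int(i), int(j), float(self.w_d[i, j]))
            for i, j in zip(*np.nonzero(np.triu(self.w_d, 1)))
        ]
        self.e_dm = [
            (int(i), int(j), self.w_dm) for i, j in zip(*np.nonzero(self.a))
        ]

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_labels)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_labels)

    def edge_table(self) -> List[Tuple[str, str, float, str]]:
        """Flat (src, dst, weight, type) view for export/inspection."""
        rows: List[Tuple[str, str, float, str]] = []
        for i, j, w in self.e_m:
            rows.append((self.mirna_labels[i], self.mirna_labels[j], w, "mm"))
        for i, j, w in self.e_d:
            rows.append((self.disease_labels[i], self.disease_labels[j], w, "dd"))
        for i, j, w in self.e_dm:
            rows.append((self.mirna_labels[i], self.disease_labels[j], w, "md"))
        return rows


def assemble_graph(
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    a: np.ndarray,
    w_dm: float = 1.0,
) -> CoupledGraph:
    """Build the coupled graph from final (thresholded) MS, DS and A."""
    a = np.asarray(a)
    if a.shape != (len(ms.labels), len(ds.labels)):
        raise ValueError(
            f"association matrix {a.shape} does not match "
            f"{len(ms.labels)} miRNAs x {len(ds.labels)} diseases"
        )
    w_m = ms.values.copy()
    w_d = ds.values.copy()
    np.fill_diagonal(w_m, 0.0)
    np.fill_diagonal(w_d, 0.0)
    return CoupledGraph(
        mirna_labels=list(ms.labels),
        disease_labels=list(ds.labels),
        w_m=w_m,
        w_d=w_d,
        a=(a > 0).astype(float),
        w_dm=w_dm,
    )


def bipartite_adjacency(
    a: np.ndarray, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Symmetric (m+n) block adjacency [[0, A], [A^T, 0]].

    ``mask`` marks held-out association cells (same shape as A); they are
    zeroed before building so propagation never sees test edges.
    """
    a = (np.asarray(a) > 0).astype(float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match association matrix")
        a = a * (~mask)
    m, n = a.shape
    adj = np.zeros((m + n, m + n))
    adj[:m, m:] = a
    adj[m:, :m] = a.T
    return adj
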