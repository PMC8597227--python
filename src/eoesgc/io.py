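"""Readers/writers for the interchange formats and the YAML run config.

Pair and edge lists travel as TSV, matrices as CSV with a label header
row and column; everything is UTF-8 with LF line endings.  Entity names
match by exact string after whitespace trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .similarity import DiseaseOntology, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_associations",
    "write_associations",
    "read_matrix",
    "write_matrix",
    "read_ontology",
    "write_ontology",
    "RunConfig",
    "load_config",
]


def read_associations(path: str | Path) -> Tuple[np.ndarray, List[str], List[str]]:
    """TSV with columns (mirna, disease) -> (binary matrix, labels).

    Duplicate pairs collapse to a single association with a warning.
    Label order is first-appearance order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["mirna", "disease"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    bad = df[df[expected].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {bad.index[0] + 2}")
    df["mirna"] = df["mirna"].str.strip()
    df["disease"] = df["disease"].str.strip()
    n_dups = df.duplicated(subset=expected).sum()
    if n_dups:
        logger.warning("%s: %d duplicate pairs collapsed", path, n_dups)
        df = df.drop_duplicates(subset=expected)
    mirnas = list(dict.fromkeys(df["mirna"]))
    diseases = list(dict.fromkeys(df["disease"]))
    m_idx = {m: i for i, m in enumerate(mirnas)}
    d_idx = {d: j for j, d in enumerate(diseases)}
    a = np.zeros((len(mirnas), len(diseases)))
    for m, d in zip(df["mirna"], df["disease"]):
        a[m_idx[m], d_idx[d]] = 1.0
    return a, mirnas, diseases


def write_associations(
    a: np.ndarray,
    mirna_labels: Sequence[str],
    disease_labels: Sequence[str],
    path: str | Path,
) -> None:
    rows = [
        (mirna_labels[i], disease_labels[j]) for i, j in np.argwhere(np.asarray(a) > 0)
    ]
    df = pd.DataFrame(rows, columns=["mirna", "disease"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_matrix(path: str | Path, expect_symmetric: bool = True) -> SimilarityMatrix:
    """CSV with label header row and column -> SimilarityMatrix."""
    df = pd.read_csv(path, index_col=0)
    labels_row = [str(c).strip() for c in df.columns]
    labels_col = [str(i).strip() for i in df.index]
    if labels_row != labels_col:
        raise ValueError(f"{path}: row and column labels differ (non-square input)")
    values = df.to_numpy(dtype=float)
    mat = SimilarityMatrix(labels_row, values)
    if expect_symmetric and not np.allclose(values, values.T, atol=1e-9):
        raise ValueError(f"{path}: matrix is not symmetric")
    return mat


def write_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, lineterminator="\n")


def read_ontology(
    edges_path: str | Path, mapping_path: str | Path
) -> DiseaseOntology:
    """Edge-list TSV (child_term, parent_term) + mapping TSV (disease_name, term_id)."""
    edges_df = pd.read_csv(edges_path, sep="\t", dtype=str)
    if list(edges_df.columns[:2]) != ["child_term", "parent_term"]:
        raise ValueError(
            f"{edges_path}: expected columns child_term, parent_term"
        )
    map_df = pd.read_csv(mapping_path, sep="\t", dtype=str)
    if list(map_df.columns[:2]) != ["disease_name", "term_id"]:
        raise ValueError(f"{mapping_path}: expected columns disease_name, term_id")
    edges = {
        (c.strip(), p.strip())
        for c, p in zip(edges_df["child_term"], edges_df["parent_term"])
    }
    terms: Set[str] = {t for e in edges for t in e}
    disease_terms: Dict[str, Set[str]] = {}
    for name, term in zip(map_df["disease_name"], map_df["term_id"]):
        terms.add(term.strip())
        disease_terms.setdefault(name.strip(), set()).add(term.strip())
    return DiseaseOntology(terms=terms, edges=edges, disease_terms=disease_terms)


def write_ontology(
    ontology: DiseaseOntology, edges_path: str | Path, mapping_path: str | Path
) -> None:
    edge_rows = sorted(ontology.edges)
    pd.DataFrame(edge_rows, columns=["child_term", "parent_term"]).to_csv(
        edges_path, sep="\t", index=False, lineterminator="\n"
    )
    map_rows = [
        (d, t) for d in sorted(ontology.disease_terms) for t in sorted(ontology.disease_terms[d])
    ]
    pd.DataFrame(map_rows, columns=["disease_name", "term_id"]).to_csv(
        mapping_path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_RANGES = {
    "alpha": (0.0, 1.0),
    "h": (0.0, 1.0),
    "delta": (0.0, 1.0),
    "threshold": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Flat YAML-backed run configuration; unknown keys are rejected."""

    # similarity stage
    alpha: float = 0.5
    h: float = 0.5
    gamma_prime: float = 0.5
    delta: float = 0.5
    # EOE stage
    eoe_epochs: int = 200
    eoe_learning_rate: float = 1e-3
    eoe_negative_strategy: str = "all_pairs"
    eoe_negative_k: int = 5
    eoe_init: str = "similarity"
    eoe_spectral_rank: int = 32
    # predictor stage
    layers: int = 2
    k: int = 2
    z: int = 64
    mlp_hidden: int = 64
    interlayer_activation: str = "none"
    predictor_epochs: int = 100
    predictor_learning_rate: float = 1e-3
    early_stopping: bool = False
    patience: int = 10
    threshold: float = 0.5
    # evaluation
    folds: int = 5
    ratio: int = 5
    seed: int = 0
    use_eoe: bool = True

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be > 0")
        for name in ("eoe_epochs", "predictor_epochs", "folds", "ratio", "z", "k", "layers"):
            if getattr(self, name) < (2 if name == "folds" else 0):
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> Dict[str, object]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def load_config(path: Optional[str | Path]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
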