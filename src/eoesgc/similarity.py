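"""Pairwise similarity construction for diseases and miRNAs.

Disease similarity combines two ontology-based semantic models with a
Gaussian interaction-profile (GIP) kernel; miRNA similarity combines a
functional similarity derived from associated-disease sets with a GIP
kernel.  Integrated matrices are sparsified with a hard threshold before
any graph is built on them.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseOntology",
    "ContributionTable",
    "SimilarityMatrix",
    "KernelParams",
    "UnknownDiseaseError",
    "build_dag",
    "semantic_contribution_m1",
    "semantic_contribution_m2",
    "semantic_value",
    "semantic_similarity",
    "dag_membership_counts",
    "disease_semantic_matrices",
    "gip_similarity",
    "disease_set_similarity",
    "mirna_functional_similarity",
    "integrate_similarity",
    "threshold_filter",
]


class UnknownDiseaseError(KeyError):
    """Raised when a disease has no term mapping in the ontology."""


@dataclass(frozen=True)
class KernelParams:
    """Scalar knobs shared by the similarity stage.

    gamma_prime  bandwidth control for the GIP kernel (> 0)
    alpha        semantic/GIP mixing weight in [0, 1]
    h            threshold below which integrated similarities are zeroed
    delta        per-hop decay of the model-1 semantic contribution
    """

    gamma_prime: float = 0.5
    alpha: float = 0.5
    h: float = 0.5
    delta: float = 0.5

    def __post_init__(self) -> None:
        if not self.gamma_prime > 0:
            raise ValueError("gamma_prime must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0, 1]")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")


@dataclass
class DiseaseOntology:
    """A multi-rooted DAG of terms plus a disease-name -> term mapping.

    ``edges`` are (child, parent) pairs; a term may have several parents.
    """

    terms: Set[str]
    edges: Set[Tuple[str, str]]
    disease_terms: Dict[str, Set[str]]

    _parents: Dict[str, Set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child}, {parent}) references unknown term")
        for disease, terms in self.disease_terms.items():
            missing = set(terms) - self.terms
            if missing:
                raise ValueError(f"disease {disease!r} maps to unknown terms {missing}")
        parents: Dict[str, Set[str]] = {}
        for child, parent in self.edges:
            parents.setdefault(child, set()).add(parent)
        self._parents = parents
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        # Kahn's algorithm over child->parent edges.
        indeg = {t: 0 for t in self.terms}
        for _, parent in self.edges:
            indeg[parent] += 1
        queue = deque(t for t, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            node = queue.popleft()
            seen += 1
            for parent in self._parents.get(node, ()):
                indeg[parent] -= 1
                if indeg[parent] == 0:
                    queue.append(parent)
        if seen != len(self.terms):
            raise ValueError("ontology edge relation contains a cycle")

    def parents_of(self, term: str) -> Set[str]:
        return self._parents.get(term, set())

    def ancestors(self, term: str) -> Set[str]:
        """All terms reachable from ``term`` via parent edges (term excluded)."""
        out: Set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for parent in self.parents_of(node):
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out


@dataclass
class ContributionTable:
    """Per-term semantic contribution scores for one disease."""

    disease: str
    contributions: Dict[str, float]
    model: str  # "model1" | "model2"

    def __post_init__(self) -> None:
        if self.model not in ("model1", "model2"):
            raise ValueError(f"unknown model tag {self.model!r}")
        if any(v < 0 for v in self.contributions.values()):
            raise ValueError("contribution scores must be nonnegative")


@dataclass
class SimilarityMatrix:
    """Labeled square symmetric matrix with entries in [0, 1]."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")

    def validate(self, atol: float = 1e-9) -> None:
        if not np.allclose(self.values, self.values.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < -atol or self.values.max() > 1 + atol:
            raise ValueError("similarity entries must lie in [0, 1]")

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self.index_of(i), self.index_of(j)])


# ---------------------------------------------------------------------------
# Semantic similarity (ontology DAG based)
# ---------------------------------------------------------------------------


def build_dag(
    ontology: DiseaseOntology, disease: str
) -> Tuple[Set[str], Set[Tuple[str, str]]]:
    """Sub-DAG of a disease: its own term(s) plus all ancestors.

    Returns (nodes, edges); edges are the ontology edges induced on the
    node set.  Raises :class:`UnknownDiseaseError` when the disease has no
    term mapping, so callers can fall back to GIP-only similarity.
    """
    try:
        own = ontology.disease_terms[disease]
    except KeyError:
        raise UnknownDiseaseError(disease) from None
    if not own:
        raise UnknownDiseaseError(disease)
    nodes: Set[str] = set(own)
    for term in own:
        nodes |= ontology.ancestors(term)
    edges = {(c, p) for (c, p) in ontology.edges if c in nodes and p in nodes}
    return nodes, edges


def semantic_contribution_m1(
    dag: Tuple[Set[str], Set[Tuple[str, str]]],
    disease: str,
    own_terms: Iterable[str],
    delta: float = 0.5,
) -> ContributionTable:
    """Depth-decayed contribution of every DAG term to the disease.

    The disease's own term scores 1; any ancestor t scores
    max over children c of t (within the DAG) of delta * score(c), which
    equals delta ** (shortest hop distance from the disease's term set).
    """
    nodes, edges = dag
    if not nodes:
        raise ValueError("empty DAG")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    own = set(own_terms)
    if not own <= nodes:
        raise ValueError("own terms must be contained in the DAG")
    # BFS upward from the disease's own terms: shortest hop count realises
    # the max-over-children recursion because delta < 1.
    dist: Dict[str, int] = {t: 0 for t in own}
    parent_map: Dict[str, Set[str]] = {}
    for child, parent in edges:
        parent_map.setdefault(child, set()).add(parent)
    queue = deque(own)
    while queue:
        node = queue.popleft()
        for parent in parent_map.get(node, ()):
            if parent not in dist:
                dist[parent] = dist[node] + 1
                queue.append(parent)
    contributions = {t: delta ** dist[t] for t in nodes if t in dist}
    return ContributionTable(disease=disease, contributions=contributions, model="model1")


def dag_membership_counts(
    ontology: DiseaseOntology, diseases: Sequence[str]
) -> Dict[str, int]:
    """For each term, the number of disease DAGs that contain it."""
    counts: Dict[str, int] = {}
    for disease in diseases:
        try:
            nodes, _ = build_dag(ontology, disease)
        except UnknownDiseaseError:
            continue
        for term in nodes:
            counts[term] = counts.get(term, 0) + 1
    return counts


def semantic_contribution_m2(
    ontology: DiseaseOntology,
    disease: str,
    counts: Mapping[str, int],
    n_diseases: int,
    log_base: float | None = None,
) -> ContributionTable:
    """Rarity-weighted contribution: -log(fraction of DAGs containing t).

    ``log_base=None`` uses the natural log; the base cancels in the
    similarity ratio, so this only affects raw contribution values.
    """
    if n_diseases < 1:
        raise ValueError("n_diseases must be >= 1")
    nodes, _ = build_dag(ontology, disease)
    contributions: Dict[str, float] = {}
    for term in nodes:
        c = counts.get(term, 0)
        if c > n_diseases:
            raise ValueError(
                f"term {term!r} counted in {c} DAGs but only {n_diseases} diseases"
            )
        if c == 0:
            raise ValueError(f"term {term!r} appears in no disease DAG")
        val = -math.log(c / n_diseases)
        if log_base is not None:
            val /= math.log(log_base)
        contributions[term] = val
    return ContributionTable(disease=disease, contributions=contributions, model="model2")


def semantic_value(contribs: ContributionTable) -> float:
    """Sum of all contribution scores."""
    if not contribs.contributions:
        raise ValueError("empty contribution table")
    return float(sum(contribs.contributions.values()))


def semantic_similarity(
    contribs_i: ContributionTable, contribs_j: ContributionTable
) -> float:
    """Shared-term contribution mass normalized by the two semantic values."""
    if contribs_i.model != contribs_j.model:
        raise ValueError("contribution tables built with different models")
    shared = contribs_i.contributions.keys() & contribs_j.contributions.keys()
    if not shared:
        return 0.0
    denom = semantic_value(contribs_i) + semantic_value(contribs_j)
    if denom == 0.0:
        logger.warning(
            "both semantic values are zero for (%s, %s); returning 0",
            contribs_i.disease,
            contribs_j.disease,
        )
        return 0.0
    num = sum(
        contribs_i.contributions[t] + contribs_j.contributions[t] for t in shared
    )
    return float(num / denom)


def disease_semantic_matrices(
    ontology: DiseaseOntology,
    diseases: Sequence[str],
    delta: float = 0.5,
    log_base: float | None = None,
) -> Tuple[SimilarityMatrix, SimilarityMatrix]:
    """Both semantic similarity matrices over a disease list.

    Diseases absent from the ontology contribute 0 off-diagonal in both
    matrices (the GIP kernel supplies their similarity downstream); their
    diagonal is kept at 1 so matrix invariants hold.
    """
    n = len(diseases)
    tables1: Dict[str, ContributionTable] = {}
    tables2: Dict[str, ContributionTable] = {}
    counts = dag_membership_counts(ontology, diseases)
    missing: List[str] = []
    for d in diseases:
        try:
            dag = build_dag(ontology, d)
        except UnknownDiseaseError:
            missing.append(d)
            continue
        own = ontology.disease_terms[d]
        tables1[d] = semantic_contribution_m1(dag, d, own, delta)
        tables2[d] = semantic_contribution_m2(ontology, d, counts, n, log_base)
    if missing:
        logger.warning(
            "%d diseases missing from the ontology; semantic rows set to 0: %s",
            len(missing),
            missing[:5],
        )
    s1 = np.eye(n)
    s2 = np.eye(n)
    for i, di in enumerate(diseases):
        if di not in tables1:
            continue
        for j in range(i + 1, n):
            dj = diseases[j]
            if dj not in tables1:
                continue
            v1 = semantic_similarity(tables1[di], tables1[dj])
            v2 = semantic_similarity(tables2[di], tables2[dj])
            s1[i, j] = s1[j, i] = v1
            s2[i, j] = s2[j, i] = v2
    return (
        SimilarityMatrix(list(diseases), s1),
        SimilarityMatrix(list(diseases), s2),
    )


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernel
# ---------------------------------------------------------------------------


def gip_similarity(
    profiles: np.ndarray,
    labels: Sequence[str],
    gamma_prime: float = 0.5,
) -> SimilarityMatrix:
    """Gaussian kernel on interaction profiles (one profile per row).

    The bandwidth gamma is gamma_prime divided by the mean squared profile
    norm, so the kernel is invariant under uniform rescaling of all
    profiles.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise ValueError("profiles must be a nonempty 2-D array")
    sq_norms = np.einsum("ij,ij->i", profiles, profiles)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    gamma = gamma_prime / mean_sq
    # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y
    gram = profiles @ profiles.T
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.maximum(sq_dist, 0.0, out=sq_dist)
    values = np.exp(-gamma * sq_dist)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(labels), values)


# ---------------------------------------------------------------------------
# miRNA functional similarity
# ---------------------------------------------------------------------------


def disease_set_similarity(
    d_t: int, dt: Sequence[int], sim: np.ndarray
) -> float:
    """Best similarity between one disease and a nonempty disease set."""
    if len(dt) == 0:
        raise ValueError("disease set must be nonempty")
    return float(np.max(sim[d_t, list(dt)]))


def mirna_functional_similarity(
    associations: np.ndarray,
    mirna_labels: Sequence[str],
    disease_sim: SimilarityMatrix,
) -> SimilarityMatrix:
    """Functional similarity of miRNAs through their associated-disease sets.

    FS(m1, m2) averages, over both directions, the best-match similarity
    of each associated disease against the other miRNA's disease set.
    miRNAs without any association get an all-zero off-diagonal row.
    """
    A = np.asarray(associations, dtype=float)
    n_m = A.shape[0]
    if A.shape[1] != len(disease_sim.labels):
        raise ValueError("association columns do not match disease similarity labels")
    S = disease_sim.values
    sets: List[np.ndarray] = [np.flatnonzero(A[i] > 0) for i in range(n_m)]
    empty = [i for i, s in enumerate(sets) if s.size == 0]
    if empty:
        logger.warning(
            "%d miRNAs have no associated diseases; FS rows set to 0", len(empty)
        )
    fs = np.eye(n_m)
    for i in range(n_m):
        dt1 = sets[i]
        if dt1.size == 0:
            continue
        for j in range(i + 1, n_m):
            dt2 = sets[j]
            if dt2.size == 0:
                continue
            sub = S[np.ix_(dt1, dt2)]
            total = sub.max(axis=1).sum() + sub.max(axis=0).sum()
            fs[i, j] = fs[j, i] = total / (dt1.size + dt2.size)
    return SimilarityMatrix(list(mirna_labels), fs)


# ---------------------------------------------------------------------------
# Integration and thresholding
# ---------------------------------------------------------------------------


def integrate_similarity(
    semantic_parts: Sequence[SimilarityMatrix],
    gip_part: SimilarityMatrix,
    alpha: float,
) -> SimilarityMatrix:
    """Convex combination of averaged semantic similarity and the GIP kernel.

    Disease mode passes the two semantic models (they are averaged); miRNA
    mode passes the single functional-similarity matrix.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not semantic_parts:
        raise ValueError("at least one semantic matrix required")
    labels = gip_part.labels
    for part in semantic_parts:
        if part.labels != labels:
            raise ValueError("similarity matrices have mismatched labels")
    semantic = np.mean([p.values for p in semantic_parts], axis=0)
    values = alpha * semantic + (1.0 - alpha) * gip_part.values
    return SimilarityMatrix(list(labels), values)


def threshold_filter(s_prime: SimilarityMatrix, h: float) -> SimilarityMatrix:
    """Zero every off-diagonal entry below h; the diagonal is exempt."""
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must be in [0, 1]")
    values = s_prime.values.copy()
    mask = values < h
    np.fill_diagonal(mask, False)
    values[mask] = 0.0
    return SimilarityMatrix(list(s_prime.labels), values)
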