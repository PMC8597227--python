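"""Synthetic fixtures: random multi-rooted ontology DAGs and planted-block
bipartite association matrices.

Group structure couples miRNA groups to disease groups one-to-one, so
shared associations genuinely carry the signal (via GIP and functional
similarity) that the pipeline exploits; the fixtures therefore support
end-to-end recovery benchmarks, not just smoke tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .similarity import DiseaseOntology

__all__ = [
    "RandomDagSpec",
    "PlantedBlockSpec",
    "make_ontology",
    "make_associations",
    "make_paper_scale_fixture",
    "PRESETS",
]


@dataclass(frozen=True)
class RandomDagSpec:
    n_terms: int = 30
    n_roots: int = 2
    max_parents: int = 3
    attach_probability: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if not 1 <= self.n_roots <= self.n_terms:
            raise ValueError("n_roots must be in [1, n_terms]")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if not 0.0 < self.attach_probability <= 1.0:
            raise ValueError("attach_probability must be in (0, 1]")


@dataclass(frozen=True)
class PlantedBlockSpec:
    n_mirnas: int = 120
    n_diseases: int = 80
    n_groups: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_diseases < 1:
            raise ValueError("matrix dimensions must be positive")
        if not 1 <= self.n_groups <= min(self.n_mirnas, self.n_diseases):
            raise ValueError("n_groups must fit both entity counts")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")


def make_ontology(
    spec: RandomDagSpec, disease_names: Optional[Sequence[str]] = None
) -> DiseaseOntology:
    """Random acyclic multi-parent ontology with diseases on leaf-ish terms.

    Terms are generated in topological order (each non-root attaches to
    earlier terms), so acyclicity holds by construction.  Diseases are
    mapped to the deepest terms first; defaults to one disease per leaf.
    """
    rng = np.random.default_rng(spec.seed)
    terms = [f"T{i:04d}" for i in range(spec.n_terms)]
    edges: Set[Tuple[str, str]] = set()
    for i in range(spec.n_roots, spec.n_terms):
        n_parents = 1 + int(
            rng.binomial(spec.max_parents - 1, spec.attach_probability)
        )
        n_parents = min(n_parents, i)
        parents = rng.choice(i, size=n_parents, replace=False)
        for p in parents:
            edges.add((terms[i], terms[int(p)]))

    is_parent = {p for _, p in edges}
    leaves = [t for t in terms if t not in is_parent]
    # Deepest-first ordering: later-generated terms sit lower in the DAG.
    leaves.sort(key=lambda t: -terms.index(t))
    if disease_names is None:
        disease_names = [f"disease_{i}" for i in range(len(leaves))]
    disease_terms: Dict[str, Set[str]] = {}
    pool = leaves + [t for t in reversed(terms) if t in is_parent]
    for i, name in enumerate(disease_names):
        disease_terms[name] = {pool[i % len(pool)]}
    return DiseaseOntology(
        terms=set(terms), edges=edges, disease_terms=disease_terms
    )


def make_associations(
    spec: PlantedBlockSpec,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-block Bernoulli association matrix.

    Returns (A, mirna_groups, disease_groups); cell (i, j) is 1 with
    probability p_in when the groups match, p_out otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    mirna_groups = np.arange(spec.n_mirnas) % spec.n_groups
    disease_groups = np.arange(spec.n_diseases) % spec.n_groups
    match = mirna_groups[:, None] == disease_groups[None, :]
    probs = np.where(match, spec.p_in, spec.p_out)
    a = (rng.random((spec.n_mirnas, spec.n_diseases)) < probs).astype(float)
    return a, mirna_groups, disease_groups


@dataclass(frozen=True)
class FixtureBundle:
    mirna_labels: List[str]
    disease_labels: List[str]
    associations: np.ndarray
    ontology: DiseaseOntology
    mirna_groups: np.ndarray
    disease_groups: np.ndarray


PRESETS: Dict[str, PlantedBlockSpec] = {
    "tiny": PlantedBlockSpec(n_mirnas=12, n_diseases=9, n_groups=3, p_in=0.6, p_out=0.05),
    "bench": PlantedBlockSpec(n_mirnas=120, n_diseases=80, n_groups=4, p_in=0.3, p_out=0.02),
    "paper-scale": PlantedBlockSpec(n_mirnas=495, n_diseases=383, n_groups=20, p_in=0.3, p_out=0.005),
}


def _solve_p_in(spec: PlantedBlockSpec, target: float) -> float:
    """p_in such that the expected association count hits ``target``."""
    mirna_groups = np.arange(spec.n_mirnas) % spec.n_groups
    disease_groups = np.arange(spec.n_diseases) % spec.n_groups
    matched = int(np.sum(mirna_groups[:, None] == disease_groups[None, :]))
    unmatched = spec.n_mirnas * spec.n_diseases - matched
    p_in = (target - unmatched * spec.p_out) / matched
    if not spec.p_out < p_in <= 1.0:
        raise ValueError("target association count unreachable with this p_out")
    return p_in


def make_paper_scale_fixture(seed: int, target_associations: int = 5430) -> FixtureBundle:
    """Full-size bundle: 495 x 383 planted-block matrix with the expected
    number of associations tuned to ``target_associations``, plus a
    matching ontology over the disease labels."""
    base = PRESETS["paper-scale"]
    p_in = _solve_p_in(base, float(target_associations))
    spec = PlantedBlockSpec(
        n_mirnas=base.n_mirnas,
        n_diseases=base.n_diseases,
        n_groups=base.n_groups,
        p_in=p_in,
        p_out=base.p_out,
        seed=seed,
    )
    return make_fixture(spec)


def make_fixture(spec: PlantedBlockSpec) -> FixtureBundle:
    """Association matrix + ontology bundle for an arbitrary block spec.

    All randomness flows from spec.seed via independent spawned streams.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    a, mg, dg = make_associations(
        PlantedBlockSpec(**{**spec.__dict__, "seed": int(seeds[0].generate_state(1)[0])})
    )
    mirna_labels = [f"mirna_{i:04d}" for i in range(spec.n_mirnas)]
    disease_labels = [f"disease_{j:04d}" for j in range(spec.n_diseases)]
    dag_spec = RandomDagSpec(
        n_terms=max(2 * spec.n_diseases, 8),
        n_roots=max(spec.n_groups // 2, 1),
        seed=int(seeds[1].generate_state(1)[0]),
    )
    ontology = make_ontology(dag_spec, disease_names=disease_labels)
    return FixtureBundle(
        mirna_labels=mirna_labels,
        disease_labels=disease_labels,
        associations=a,
        ontology=ontology,
        mirna_groups=mg,
        disease_groups=dg,
    )
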