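"""High-level wiring: raw inputs -> final similarity networks.

Builds the Gaussian interaction-profile kernels from the association
matrix, the two ontology-based semantic models when an ontology is
available, integrates them, and applies the similarity threshold.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .similarity import (
    DiseaseOntology,
    KernelParams,
    SimilarityMatrix,
    disease_semantic_matrices,
    gip_similarity,
    integrate_similarity,
    mirna_functional_similarity,
    threshold_filter,
)

__all__ = ["build_similarity_networks"]


def build_similarity_networks(
    a: np.ndarray,
    mirna_labels: Sequence[str],
    disease_labels: Sequence[str],
    ontology: Optional[DiseaseOntology] = None,
    params: Optional[KernelParams] = None,
) -> Tuple[SimilarityMatrix, SimilarityMatrix, Dict[str, SimilarityMatrix]]:
    """Returns (MS, DS, intermediates) — final thresholded networks.

    Without an ontology the semantic matrices are identity (GIP is the
    paper's stated supplement for unmapped diseases), which reduces the
    disease integration to alpha-scaled GIP off-diagonal.
    """
    params = params or KernelParams()
    a = (np.asarray(a) > 0).astype(float)

    dgs = gip_similarity(a.T, disease_labels, params.gamma_prime)
    mgs = gip_similarity(a, mirna_labels, params.gamma_prime)

    if ontology is not None:
        dss1, dss2 = disease_semantic_matrices(
            ontology, list(disease_labels), params.delta
        )
    else:
        eye = np.eye(len(disease_labels))
        dss1 = SimilarityMatrix(list(disease_labels), eye.copy())
        dss2 = SimilarityMatrix(list(disease_labels), eye.copy())

    ds_prime = integrate_similarity([dss1, dss2], dgs, params.alpha)
    ds = threshold_filter(ds_prime, params.h)

    fs = mirna_functional_similarity(a, mirna_labels, ds)
    ms_prime = integrate_similarity([fs], mgs, params.alpha)
    ms = threshold_filter(ms_prime, params.h)

    intermediates = {
        "DSS1": dss1,
        "DSS2": dss2,
        "DGS": dgs,
        "MGS": mgs,
        "FS": fs,
        "DS_prime": ds_prime,
        "MS_prime": ms_prime,
    }
    return ms, ds, intermediates
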