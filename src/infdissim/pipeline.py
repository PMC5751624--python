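"""End-to-end drivers gluing the modules into the standard workflow."""

from __future__ import annotations

from dataclasses import dataclass

from .disease_similarity import SimilarityMatrix, infdissim_matrix
from .flow_network import (
    FlowConfig,
    GeneFunctionalNetwork,
    IntegratedNetwork,
    all_weight_vectors,
    build_integrated_network,
)
from .ontology import AnnotationMap, Ontology, propagate_annotations

__all__ = ["PipelineResult", "disease_similarity_pipeline"]


@dataclass
class PipelineResult:
    """Intermediate and final products of the disease-similarity pipeline."""

    ontology: Ontology
    annmap: AnnotationMap
    network: IntegratedNetwork
    weight_vectors: dict
    similarity: SimilarityMatrix


def disease_similarity_pipeline(
    ontology: Ontology,
    raw_annotations,
    gfn: GeneFunctionalNetwork,
    diseases=None,
    cfg: FlowConfig | None = None,
) -> PipelineResult:
    """Annotation propagation -> integrated network -> flow vectors -> InfDisSim.

    ``diseases`` defaults to every term carrying a raw annotation.
    """
    annmap = propagate_annotations(ontology, raw_annotations)
    if diseases is None:
        diseases = sorted(annmap.raw)
    network = build_integrated_network(gfn, annmap, diseases)
    weight_vectors, _failures = all_weight_vectors(network, cfg)
    similarity = infdissim_matrix(diseases, weight_vectors, ontology, annmap)
    return PipelineResult(ontology, annmap, network, weight_vectors, similarity)
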