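"""End-to-end glue: association table -> similarities -> network -> scores."""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import AssociationData, ScoreMatrix, SymptomData
from .network import build_heterogeneous_adjacency, column_normalize, HeteroNetwork
from .predict import CombineParams, score_all
from .similarity import (
    KernelParams,
    gip_kernel,
    integrate_disease_similarity,
    symptom_similarity,
)
from .walk import WalkParams


@dataclass
class NetworkConfig:
    """Choices left open by the method description.

    ``disease_similarity``: use the integrated SD block (default) or the
    bare KD kernel.  ``mode``: similarity edges weighted (default) or
    binarized at ``threshold``.  ``drop_self_loops`` removes the unit
    diagonal the kernels introduce.
    """

    disease_similarity: str = "sd"
    mode: str = "weighted"
    threshold: float = 0.5
    drop_self_loops: bool = False

    def __post_init__(self) -> None:
        if self.disease_similarity not in ("sd", "kd"):
            raise ValueError("disease_similarity must be 'sd' or 'kd'")


def build_network(
    assoc: AssociationData,
    symptoms: SymptomData | None = None,
    kernel: KernelParams | None = None,
    net_cfg: NetworkConfig | None = None,
) -> HeteroNetwork:
    """Compute KD/KM (and SDM when symptoms are given), assemble the
    heterogeneous block adjacency and column-normalize it."""
    kernel = kernel or KernelParams()
    net_cfg = net_cfg or NetworkConfig()
    KD = gip_kernel(assoc, "diseases", kernel)
    KM = gip_kernel(assoc, "microbes", kernel)
    if net_cfg.disease_similarity == "sd":
        SDM = None
        if symptoms is not None and not symptoms.is_degenerate:
            SDM = symptom_similarity(symptoms)
        disease_block = integrate_disease_similarity(KD, SDM)
    else:
        disease_block = KD
    net = build_heterogeneous_adjacency(
        disease_block,
        KM,
        assoc,
        mode=net_cfg.mode,
        threshold=net_cfg.threshold,
        drop_self_loops=net_cfg.drop_self_loops,
    )
    return column_normalize(net)


def pipeline_scores(
    assoc: AssociationData,
    symptoms: SymptomData | None = None,
    walk: WalkParams | None = None,
    comb: CombineParams | None = None,
    kernel: KernelParams | None = None,
    net_cfg: NetworkConfig | None = None,
    allow_nonconverged: bool = False,
) -> ScoreMatrix:
    """Full pipeline: build the network from the (training) association
    matrix and score every disease-microbe pair by the double-ended walk."""
    net = build_network(assoc, symptoms, kernel, net_cfg)
    return score_all(net, assoc, walk, comb, allow_nonconverged)
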