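"""Synthetic association and symptom tables with planted cluster structure.

The generator instantiates the structural premise the predictor
exploits — functionally related microbes associate with phenotypically
similar diseases — as a planted co-clustering: diseases and microbes
are assigned to latent clusters, associations occur with probability
``p_in`` inside a matched cluster and ``p_out`` elsewhere, and diseases
of the same cluster share elevated counts on a cluster-specific block
of symptoms.  Defaults give a sparse matrix at a scale where full
LOOCV runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationData, SymptomData


@dataclass
class SynthConfig:
    """Planted co-clustering parameters.

    ``p_in``/``p_out`` are within/between-cluster association
    probabilities; ``symptom_signal`` is the probability that a disease
    expresses each of its cluster's signature symptoms.
    """

    n_d: int = 30
    n_m: int = 100
    n_clusters: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    n_symptoms: int = 60
    symptom_signal: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_d, self.n_m, self.n_symptoms, self.n_clusters) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not (0 <= self.symptom_signal <= 1):
            raise ValueError("symptom_signal must be in [0, 1]")
        if self.n_clusters > min(self.n_d, self.n_m):
            raise ValueError("n_clusters cannot exceed min(n_d, n_m)")


def generate_dataset(
    cfg: SynthConfig | None = None,
) -> tuple[AssociationData, SymptomData, dict[str, np.ndarray]]:
    """Draw one synthetic dataset; deterministic under ``cfg.rng_seed``.

    Returns the association table, the symptom count table, and the
    ground-truth cluster labels (``disease_clusters``,
    ``microbe_clusters``) the tables were generated from.  Isolated
    diseases/microbes (all-zero profiles) may occur and are legitimate.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    d_clusters = rng.integers(cfg.n_clusters, size=cfg.n_d)
    m_clusters = rng.integers(cfg.n_clusters, size=cfg.n_m)

    same = d_clusters[:, None] == m_clusters[None, :]
    prob = np.where(same, cfg.p_in, cfg.p_out)
    A = (rng.random((cfg.n_d, cfg.n_m)) < prob).astype(float)

    # background noise plus a signature symptom block per cluster
    C = rng.poisson(0.3, size=(cfg.n_symptoms, cfg.n_d)).astype(float)
    blocks = np.array_split(np.arange(cfg.n_symptoms), cfg.n_clusters)
    for c, block in enumerate(blocks):
        members = np.flatnonzero(d_clusters == c)
        for j in members:
            expressed = rng.random(block.size) < cfg.symptom_signal
            C[block[expressed], j] += rng.poisson(5.0, size=int(expressed.sum()))

    diseases = [f"disease_{i:02d}" for i in range(cfg.n_d)]
    microbes = [f"microbe_{j:03d}" for j in range(cfg.n_m)]
    symptoms = [f"symptom_{s:02d}" for s in range(cfg.n_symptoms)]
    assoc = AssociationData(diseases, microbes, A)
    sym = SymptomData(diseases, symptoms, C)
    truth = {"disease_clusters": d_clusters, "microbe_clusters": m_clusters}
    return assoc, sym, truth
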