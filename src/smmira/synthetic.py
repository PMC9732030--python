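"""Synthetic association datasets with planted block structure.

Real small-molecule/miRNA association data is a very sparse bipartite 0/1
matrix, and the working premise of similarity-based predictors is that
similar molecules tend to share miRNA partners.  The generator reproduces
exactly that structure: entities of both types are assigned to latent
blocks, associations are dense within a block and rare across blocks, and
the similarity matrices are elevated within blocks — so every pipeline stage
has recoverable signal without any external download.

The defaults emulate the scale of a small curated association set: 40 SMs,
120 miRNAs, two blocks, and association rates (p_in=0.06, p_out=0.002)
whose expectation is about 150 known pairs, i.e. ~3% matrix density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationData
from .similarity import SimilarityMatrix


@dataclass
class SyntheticSpec:
    """Generator settings; invariants: p_in > p_out and sim_in > sim_out."""

    n_sm: int = 40
    n_mirna: int = 120
    n_blocks: int = 2
    p_in: float = 0.06
    p_out: float = 0.002
    sim_in: float = 0.8
    sim_out: float = 0.2
    sim_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sm, self.n_mirna, self.n_blocks) < 1:
            raise ValueError("n_sm, n_mirna and n_blocks must be >= 1")
        if not (0.0 < self.p_in <= 1.0) or not (0.0 <= self.p_out < 1.0):
            raise ValueError("need p_in in (0,1] and p_out in [0,1)")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.sim_in <= self.sim_out:
            raise ValueError("sim_in must exceed sim_out")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be non-negative")


def _block_similarity(blocks: np.ndarray, spec: SyntheticSpec,
                      rng: np.random.Generator) -> np.ndarray:
    n = len(blocks)
    same = blocks[:, None] == blocks[None, :]
    base = np.where(same, spec.sim_in, spec.sim_out).astype(float)
    noise = rng.normal(0.0, spec.sim_noise, size=(n, n))
    noise = np.triu(noise, 1)
    S = np.clip(base + noise + noise.T, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate(spec: SyntheticSpec) -> tuple[AssociationData, SimilarityMatrix,
                                           SimilarityMatrix, dict[str, np.ndarray]]:
    """Draw one dataset: associations, SM and miRNA similarities, block truth.

    Entities are assigned to blocks round-robin (entity i -> block i mod
    n_blocks); association (s, m) is Bernoulli(p_in) within a block and
    Bernoulli(p_out) across; similarities are sim_in/sim_out plus symmetric
    Gaussian jitter, clipped to [0, 1] with unit diagonal.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sm_blocks = np.arange(spec.n_sm) % spec.n_blocks
    mirna_blocks = np.arange(spec.n_mirna) % spec.n_blocks

    same = sm_blocks[:, None] == mirna_blocks[None, :]
    p = np.where(same, spec.p_in, spec.p_out)
    A = (rng.random((spec.n_sm, spec.n_mirna)) < p).astype(float)

    sm_ids = [f"CID {900000 + i}" for i in range(spec.n_sm)]
    mirna_ids = [f"hsa-mir-syn-{j}" for j in range(spec.n_mirna)]
    data = AssociationData(sm_ids, mirna_ids, A)
    SSM = SimilarityMatrix(_block_similarity(sm_blocks, spec, rng), sm_ids)
    SMR = SimilarityMatrix(_block_similarity(mirna_blocks, spec, rng), mirna_ids)
    truth = {"sm_blocks": sm_blocks, "mirna_blocks": mirna_blocks}
    return data, SSM, SMR, truth


def degree_filter(data: AssociationData) -> AssociationData:
    """Drop SMs and miRNAs that take part in no known association.

    The association count is preserved; applying the filter twice is the
    same as applying it once.
    """
    keep_sm = data.A.sum(axis=1) > 0
    keep_mirna = data.A.sum(axis=0) > 0
    if not keep_sm.any() or not keep_mirna.any():
        raise ValueError("degree filter would remove every SM or every miRNA")
    return AssociationData(
        [s for s, k in zip(data.sm_ids, keep_sm) if k],
        [m for m, k in zip(data.mirna_ids, keep_mirna) if k],
        data.A[np.ix_(keep_sm, keep_mirna)],
    )
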