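"""Input/output for association data, similarity matrices and run configuration.

On-disk conventions
-------------------
* association pair lists: 2+ column delimited text (TSV by default), one
  (small-molecule id, miRNA id) pair per line;
* dense matrices (associations, similarities, score matrices): TSV with the
  first row and first column holding identifiers;
* run configuration: a flat ``key = value`` text file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

logger = logging.getLogger("smmira")


@dataclass
class AssociationData:
    """A binary small-molecule x miRNA association matrix with identifiers.

    ``A[i, j] == 1`` records a curated, experimentally supported association
    between the i-th small molecule and the j-th miRNA; 0 means unknown
    (not "known absent").  Small molecules are on the rows throughout the
    package.
    """

    sm_ids: list[str]
    mirna_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.sm_ids = [str(s) for s in self.sm_ids]
        self.mirna_ids = [str(m) for m in self.mirna_ids]
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.sm_ids), len(self.mirna_ids)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match "
                f"{len(self.sm_ids)} SMs x {len(self.mirna_ids)} miRNAs"
            )
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("association entries must be 0 or 1")
        if len(set(self.sm_ids)) != len(self.sm_ids):
            raise ValueError("duplicate SM identifiers")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")

    @property
    def n_sm(self) -> int:
        return len(self.sm_ids)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def copy(self) -> "AssociationData":
        return AssociationData(list(self.sm_ids), list(self.mirna_ids), self.A.copy())


@dataclass
class RunConfig:
    """Hyperparameters of a full denoise + train run.

    Defaults are the published operating point of the model: embedding
    dimension ``k=64``, ``L=3`` graph-convolution layers, Adam learning rate
    0.00725, 600 training epochs, edge dropout 0.6, feature dropout 0.4,
    similarity-block penalty factor ``mu=6`` in the propagation graph, and
    low-rank/sparse balance ``alpha=0.1`` for the denoiser.
    """

    lrr_alpha: float = 0.1
    embed_dim: int = 64
    n_layers: int = 3
    learning_rate: float = 0.00725
    epochs: int = 600
    dropout_edge: float = 0.6
    dropout_feature: float = 0.4
    graph_penalty: float = 6.0
    seed: int = 0
    cv_seed: int = 0          # CV partition randomness, independent of weights
    norm_style: str = "sqrt"
    loss: str = "weighted_bce"
    lrr_side: str = "mirna"
    attn_init: str = "inverse_layer"

    def __post_init__(self) -> None:
        if self.lrr_alpha <= 0 or self.learning_rate <= 0 or self.graph_penalty <= 0:
            raise ValueError("lrr_alpha, learning_rate and graph_penalty must be positive")
        if self.embed_dim < 1 or self.n_layers < 1 or self.epochs < 0:
            raise ValueError("embed_dim and n_layers must be >= 1, epochs >= 0")
        for r in (self.dropout_edge, self.dropout_feature):
            if not (0.0 <= r < 1.0):
                raise ValueError("dropout rates must lie in [0, 1)")
        if self.loss not in ("weighted_bce", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.lrr_side not in ("mirna", "sm"):
            raise ValueError(f"unknown lrr_side {self.lrr_side!r}")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for raw in Path(path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            key, _, val = raw.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](val)
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def read_association_pairs(
    path: str | Path,
    sm_universe: list[str] | None = None,
    mirna_universe: list[str] | None = None,
    sep: str = "\t",
) -> AssociationData:
    """Read a (SM id, miRNA id) pair list into a binary association matrix.

    Without universes, the identifier lists are the distinct ids seen in the
    file, in order of first appearance.  With universes, the full id lists are
    used so that zero-degree rows/columns are retained, and any pair id
    missing from its universe is an error.  Duplicate pairs are kept once
    with a logged warning.
    """
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=[0, 1])
    if df.shape[1] < 2 and len(df):
        raise ValueError(f"{path}: expected at least 2 columns, got {df.shape[1]}")
    pairs = list(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))

    seen: set[tuple[str, str]] = set()
    unique_pairs = []
    for p in pairs:
        if p in seen:
            logger.warning("duplicate association pair %s, kept once", p)
            continue
        seen.add(p)
        unique_pairs.append(p)

    def _ordered_unique(values):
        out, s = [], set()
        for v in values:
            if v not in s:
                s.add(v)
                out.append(v)
        return out

    sm_ids = list(sm_universe) if sm_universe is not None else _ordered_unique(
        s for s, _ in unique_pairs)
    mirna_ids = list(mirna_universe) if mirna_universe is not None else _ordered_unique(
        m for _, m in unique_pairs)
    sm_index = {s: i for i, s in enumerate(sm_ids)}
    mirna_index = {m: j for j, m in enumerate(mirna_ids)}

    A = np.zeros((len(sm_ids), len(mirna_ids)))
    for s, m in unique_pairs:
        if s not in sm_index:
            raise ValueError(f"SM id {s!r} not in the supplied SM universe")
        if m not in mirna_index:
            raise ValueError(f"miRNA id {m!r} not in the supplied miRNA universe")
        A[sm_index[s], mirna_index[m]] = 1.0
    return AssociationData(sm_ids, mirna_ids, A)


def write_association_pairs(data: AssociationData, path: str | Path, sep: str = "\t") -> None:
    rows = [(data.sm_ids[i], data.mirna_ids[j]) for i, j in zip(*np.nonzero(data.A))]
    pd.DataFrame(rows).to_csv(path, sep=sep, header=False, index=False)


def read_association_matrix(path: str | Path, sep: str = "\t") -> AssociationData:
    """Read a dense 0/1 association matrix with SM row ids and miRNA column ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return AssociationData([str(s) for s in df.index],
                           [str(m) for m in df.columns],
                           df.to_numpy(dtype=float))


def write_matrix(M: np.ndarray, row_ids: list[str], col_ids: list[str],
                 path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(M, index=row_ids, columns=col_ids).to_csv(path, sep=sep)


def write_association_matrix(data: AssociationData, path: str | Path, sep: str = "\t") -> None:
    write_matrix(data.A, data.sm_ids, data.mirna_ids, path, sep=sep)


def read_similarity_matrix(path: str | Path, sep: str = "\t") -> SimilarityMatrix:
    """Read a square similarity matrix whose row and column ids must agree in order."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity body is {df.shape[0]}x{df.shape[1]}, not square")
    if row_ids != col_ids:
        raise ValueError(f"{path}: row ids and column ids differ in content or order")
    return SimilarityMatrix(df.to_numpy(dtype=float), row_ids)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path, sep: str = "\t") -> None:
    write_matrix(sim.S, sim.ids, sim.ids, path, sep=sep)


def rank_mirnas(scores_row: np.ndarray, mirna_ids: list[str],
                top_n: int | None = None) -> pd.DataFrame:
    """Rank miRNAs for one SM by descending score, ties broken lexicographically."""
    order = sorted(range(len(mirna_ids)), key=lambda j: (-scores_row[j], mirna_ids[j]))
    if top_n is not None:
        order = order[:top_n]
    return pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "mirna_id": [mirna_ids[j] for j in order],
        "score": [scores_row[j] for j in order],
    })


def write_rankings(scores: np.ndarray, data: AssociationData, sm_id: str,
                   path: str | Path, top_n: int | None = None, sep: str = "\t") -> None:
    """Write the per-miRNA ranking of ``sm_id`` from a dense SM x miRNA score matrix."""
    if sm_id not in data.sm_ids:
        raise ValueError(f"unknown SM id {sm_id!r}")
    i = data.sm_ids.index(sm_id)
    rank_mirnas(np.asarray(scores, dtype=float)[i], data.mirna_ids, top_n).to_csv(
        path, sep=sep, index=False)
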