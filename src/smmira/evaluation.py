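"""Ranking-based cross-validation, case studies and controls.

All evaluation is ranking-based: a held-out known association ("test
sample") is scored by a model retrained without it, and its score is ranked
against the scores of candidate pairs (pairs with no known association).
Sweeping a rank threshold traces a ROC curve whose area equals the
Mann-Whitney probability that a random test sample outranks a random
candidate; 0.5 is chance level, 1.0 perfect ranking.

Four modes are provided:

* global LOOCV     — every known pair held out in turn, candidates are all
                     unknown pairs;
* miRNA-fixed LOOCV — candidates restricted to unknown pairs sharing the
                     held-out pair's miRNA;
* SM-fixed LOOCV   — candidates restricted to unknown pairs sharing the SM;
* repeated k-fold  — known pairs split into k near-equal folds, one AUC per
                     fold, mean +/- std over folds x repeats.

The model never sees a held-out label: the entry is zeroed in the training
copy *before* low-rank denoising and training.  Scorers are pluggable
callables ``scorer(train_data, SSM, SMR, cfg, rng) -> SM x miRNA score
matrix`` so that calibration scorers (uniform-random, oracle) can exercise
the same harnesses as the full model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import AssociationData, RunConfig, rank_mirnas
from .gcn import train_model
from .similarity import SimilarityMatrix

logger = logging.getLogger("smmira")


@dataclass
class CVResult:
    auc_mean: float
    auc_std: float
    per_repeat_aucs: list[float]
    mode: str
    n_test_samples: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc_mean <= 1.0):
            raise ValueError("auc_mean must lie in [0, 1]")


# ---------------------------------------------------------------------------
# AUC


def rank_auc(test_scores, candidate_scores) -> float:
    """Ranking AUC of test samples against candidate samples.

    Equals the Mann-Whitney statistic
    ``(#{test > cand} + 0.5 #{test == cand}) / (n_test * n_cand)`` — the area
    under the ROC traced by sweeping a rank threshold, with tied scores
    contributing one half (midranks).
    """
    t = np.asarray(test_scores, dtype=float).ravel()
    c = np.asarray(candidate_scores, dtype=float).ravel()
    if t.size == 0 or c.size == 0:
        raise ValueError("test and candidate score lists must be non-empty")
    ranks = rankdata(np.concatenate([t, c]))
    u = ranks[: t.size].sum() - t.size * (t.size + 1) / 2.0
    return float(u / (t.size * c.size))


# ---------------------------------------------------------------------------
# scorers


def model_scorer(train_data: AssociationData, SSM: SimilarityMatrix,
                 SMR: SimilarityMatrix, cfg: RunConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Full pipeline scorer: denoise + train + decode, SM x miRNA scores."""
    _, A_prime = train_model(train_data, SSM, SMR, cfg)
    return A_prime.T


def random_scorer(train_data: AssociationData, SSM, SMR, cfg,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform(0, 1) score for every pair — the chance-level calibration."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return rng.random((train_data.n_sm, train_data.n_mirna))


def make_oracle_scorer(full_data: AssociationData, invert: bool = False):
    """Scorer that gives held-out known pairs score 1 and everything else 0.

    Held-out pairs are recognized as entries known in ``full_data`` but
    zeroed in the training copy.  ``invert=True`` flips the two scores
    (worst possible ranking).
    """
    def scorer(train_data, SSM, SMR, cfg, rng=None):
        held_out = (full_data.A == 1) & (train_data.A == 0)
        hi, lo = (0.0, 1.0) if invert else (1.0, 0.0)
        return np.where(held_out, hi, lo)
    return scorer


# ---------------------------------------------------------------------------
# LOOCV


def _candidate_mask(data: AssociationData) -> np.ndarray:
    return data.A == 0


def global_loocv(data: AssociationData, SSM: SimilarityMatrix, SMR: SimilarityMatrix,
                 cfg: RunConfig, scorer=model_scorer,
                 rng: np.random.Generator | None = None) -> CVResult:
    """Hold out each known association in turn; candidates = all unknown pairs.

    One pooled AUC is computed over all held-out samples together with the
    candidate scores produced by each retrained model.
    """
    known = np.argwhere(data.A == 1)
    if len(known) < 2:
        raise ValueError("global LOOCV needs at least 2 known associations")
    cand_mask = _candidate_mask(data)
    rng = rng if rng is not None else np.random.default_rng(cfg.cv_seed)

    test_scores, cand_scores = [], []
    for i, j in known:
        train = data.copy()
        train.A[i, j] = 0.0
        S = scorer(train, SSM, SMR, cfg, rng)
        test_scores.append(S[i, j])
        cand_scores.append(S[cand_mask])
    auc = rank_auc(test_scores, np.concatenate(cand_scores))
    return CVResult(auc, 0.0, [auc], "global_loocv", len(known))


def local_loocv(data: AssociationData, SSM: SimilarityMatrix, SMR: SimilarityMatrix,
                cfg: RunConfig, mode: str, scorer=model_scorer,
                rng: np.random.Generator | None = None) -> CVResult:
    """LOOCV with candidates restricted to pairs sharing the held-out miRNA or SM.

    ``mode`` is ``"mirna_fixed"`` (candidates share the miRNA column) or
    ``"sm_fixed"`` (candidates share the SM row).  Held-out pairs with an
    empty restricted candidate set are skipped with a warning and counted.
    """
    if mode not in ("mirna_fixed", "sm_fixed"):
        raise ValueError(f"unknown local LOOCV mode {mode!r}")
    known = np.argwhere(data.A == 1)
    if len(known) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    cand_mask = _candidate_mask(data)
    rng = rng if rng is not None else np.random.default_rng(cfg.cv_seed)

    test_scores, cand_scores, n_skipped = [], [], 0
    for i, j in known:
        local = cand_mask[:, j] if mode == "mirna_fixed" else cand_mask[i, :]
        if not local.any():
            logger.warning("no candidates share the held-out pair (%d, %d); skipped", i, j)
            n_skipped += 1
            continue
        train = data.copy()
        train.A[i, j] = 0.0
        S = scorer(train, SSM, SMR, cfg, rng)
        test_scores.append(S[i, j])
        cand_scores.append(S[:, j][local] if mode == "mirna_fixed" else S[i, :][local])
    if not test_scores:
        raise ValueError("every held-out pair had an empty candidate set")
    auc = rank_auc(test_scores, np.concatenate(cand_scores))
    return CVResult(auc, 0.0, [auc], mode, len(test_scores), n_skipped)


def kfold_partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random split of range(n) into k folds whose sizes differ by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} associations into {k} folds")
    perm = rng.permutation(n)
    return list(np.array_split(perm, k))


def kfold_cv(data: AssociationData, SSM: SimilarityMatrix, SMR: SimilarityMatrix,
             cfg: RunConfig, k: int = 5, repeats: int = 1,
             seed: int | None = None, scorer=model_scorer) -> CVResult:
    """Repeated k-fold CV over known associations; one AUC per fold.

    Every fold's pairs are zeroed together, the model retrained once per
    fold, and the fold's held-out pairs ranked against all unknown pairs.
    Deterministic given ``seed`` (defaults to ``cfg.cv_seed``).
    """
    known = np.argwhere(data.A == 1)
    rng = np.random.default_rng(cfg.cv_seed if seed is None else seed)
    cand_mask = _candidate_mask(data)

    aucs = []
    for _ in range(repeats):
        folds = kfold_partition(len(known), k, rng)
        for fold in folds:
            train = data.copy()
            pairs = known[fold]
            train.A[pairs[:, 0], pairs[:, 1]] = 0.0
            S = scorer(train, SSM, SMR, cfg, rng)
            aucs.append(rank_auc(S[pairs[:, 0], pairs[:, 1]], S[cand_mask]))
    aucs = [float(a) for a in aucs]
    return CVResult(float(np.mean(aucs)), float(np.std(aucs)), aucs,
                    "kfold", len(known))


# ---------------------------------------------------------------------------
# case studies and controls


def case_study(data: AssociationData, SSM: SimilarityMatrix, SMR: SimilarityMatrix,
               cfg: RunConfig, sm_id: str, mode: int = 1,
               top_n: int = 50, scorer=model_scorer) -> pd.DataFrame:
    """Rank candidate miRNAs for one SM.

    Mode 1 trains on all known associations; mode 2 first removes every
    known association of ``sm_id`` (prediction for a molecule with no known
    partners).  Candidates are the miRNAs not known-associated with the SM
    in the *training* matrix, ranked by descending score with lexicographic
    tie-breaking.
    """
    if sm_id not in data.sm_ids:
        raise ValueError(f"unknown SM id {sm_id!r}")
    if mode not in (1, 2):
        raise ValueError("mode must be 1 or 2")
    i = data.sm_ids.index(sm_id)
    train = data.copy()
    if mode == 2:
        if train.A[i].sum() == 0:
            raise ValueError(f"{sm_id} has no known association to remove in mode 2")
        train.A[i, :] = 0.0
    S = scorer(train, SSM, SMR, cfg)
    candidates = train.A[i] == 0
    row = np.where(candidates, S[i], -np.inf)
    ranking = rank_mirnas(row, data.mirna_ids, top_n=None)
    ranking = ranking[np.isfinite(ranking["score"])].head(top_n).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def random_control(data: AssociationData, SSM: SimilarityMatrix, SMR: SimilarityMatrix,
                   cfg: RunConfig, n_pairs: int, seed: int,
                   scorer=model_scorer) -> pd.DataFrame:
    """Score a uniform random sample of unknown pairs (negative control).

    Returns the sampled pairs with their scores and global ranks among all
    unknown pairs (rank 1 = highest score; ties get average rank).
    """
    unknown = np.argwhere(data.A == 0)
    if n_pairs > len(unknown):
        raise ValueError(f"asked for {n_pairs} pairs but only {len(unknown)} are unknown")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(unknown), size=n_pairs, replace=False)

    S = scorer(data, SSM, SMR, cfg)
    scores_all = S[data.A == 0]
    # ranks among unknown pairs, descending score
    ranks_all = rankdata(-scores_all, method="average")
    # map each unknown pair to its position in scores_all (row-major order)
    return pd.DataFrame({
        "sm_id": [data.sm_ids[unknown[p][0]] for p in picks],
        "mirna_id": [data.mirna_ids[unknown[p][1]] for p in picks],
        "score": [S[tuple(unknown[p])] for p in picks],
        "global_rank": [float(ranks_all[p]) for p in picks],
    })
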