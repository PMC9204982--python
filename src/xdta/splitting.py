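"""Chemogenomic representative K-fold splitting.

Interaction records are split into two groups by their pKd label: Group I
(pKd strictly above the threshold, default 5 — the measurable interactions)
and Group II (pKd equal to the threshold — assay-floor weak interactions).
Group I is distributed first: the first K records in processing order seed
one fold each; every remaining record is assigned greedily to the eligible
fold with the lowest similarity score, where the score against a fold is a
weighted mean of the median protein similarity and the median compound
similarity between the record and the fold's members.  Fold eligibility
rotates in balancing rounds — within a round each fold receives at most one
record — which keeps fold sizes within one of each other per group.  Group
II is then processed identically with its own balancing rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoding import InteractionRecord
from .similarity import SimilarityMatrix

__all__ = ["SplitConfig", "FoldAssignment", "fold_similarity_score",
           "chemogenomic_kfold", "holdout_test_fold"]


@dataclass(frozen=True)
class SplitConfig:
    """Configuration of the representative splitter.

    ``weight_protein`` weighs the protein-similarity median in the fold
    score; the compound median gets ``1 - weight_protein``.  ``order_seed``
    optionally shuffles the processing order within each group; by default
    input order is used, which makes the procedure fully deterministic.
    """

    k: int = 6
    weight_protein: float = 0.5
    order_seed: int | None = None
    pkd_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("K must be >= 2")
        if not 0.0 <= self.weight_protein <= 1.0:
            raise ValueError("weight_protein must be in [0,1]")


@dataclass
class FoldAssignment:
    """Record-index -> fold and record-index -> pKd-group maps."""

    fold_of: dict[int, int]
    group_of: dict[int, str]  # "I" or "II"
    k: int

    def fold_indices(self, fold: int) -> list[int]:
        return sorted(i for i, f in self.fold_of.items() if f == fold)

    def sizes(self, group: str | None = None) -> list[int]:
        counts = [0] * self.k
        for i, f in self.fold_of.items():
            if group is None or self.group_of[i] == group:
                counts[f] += 1
        return counts


def fold_similarity_score(
    record: InteractionRecord,
    fold_members: Sequence[InteractionRecord],
    prot_sim: SimilarityMatrix,
    comp_sim: SimilarityMatrix,
    cfg: SplitConfig,
) -> float:
    """Weighted mean of median protein/compound similarity to a fold.

    score = w_p * median_j sim_prot(record, member_j)
          + (1 - w_p) * median_j sim_comp(record, member_j)
    """
    if not fold_members:
        raise ValueError("fold has no members")
    pidx = prot_sim.indexer()
    cidx = comp_sim.indexer()
    try:
        pi = pidx[record.protein_id]
        ci = cidx[record.compound_id]
        psims = [prot_sim.values[pi, pidx[m.protein_id]] for m in fold_members]
        csims = [comp_sim.values[ci, cidx[m.compound_id]] for m in fold_members]
    except KeyError as exc:
        raise KeyError(f"id {exc.args[0]!r} missing from similarity matrix") from None
    w = cfg.weight_protein
    return w * float(np.median(psims)) + (1.0 - w) * float(np.median(csims))


def _process_group(
    order: list[int],
    records: Sequence[InteractionRecord],
    folds: list[list[int]],
    prot_sim: SimilarityMatrix,
    comp_sim: SimilarityMatrix,
    cfg: SplitConfig,
    seed_folds: bool,
    fold_of: dict[int, int],
) -> None:
    k = cfg.k
    pos = 0
    if seed_folds:
        for f in range(k):
            idx = order[pos]
            folds[f].append(idx)
            fold_of[idx] = f
            pos += 1
    eligible = set(range(k))
    for idx in order[pos:]:
        if not eligible:
            eligible = set(range(k))
        rec = records[idx]
        best_f, best_score = None, None
        for f in sorted(eligible):
            score = fold_similarity_score(rec, [records[i] for i in folds[f]],
                                          prot_sim, comp_sim, cfg)
            if best_score is None or score < best_score:
                best_f, best_score = f, score
        folds[best_f].append(idx)
        fold_of[idx] = best_f
        eligible.discard(best_f)


def chemogenomic_kfold(
    records: Sequence[InteractionRecord],
    prot_sim: SimilarityMatrix,
    comp_sim: SimilarityMatrix,
    cfg: SplitConfig,
) -> FoldAssignment:
    """Assign every record to one of K folds by greedy dissimilarity.

    Requires at least K Group-I records (pKd strictly above the threshold)
    to seed the folds.  Ties in the fold score break toward the lowest fold
    index; Group II starts a fresh balancing round.
    """
    k = cfg.k
    group_i = [i for i, r in enumerate(records) if r.pkd > cfg.pkd_threshold]
    group_ii = [i for i, r in enumerate(records) if r.pkd <= cfg.pkd_threshold]
    if len(group_i) < k:
        raise ValueError(
            f"need at least K={k} records with pKd > {cfg.pkd_threshold}, "
            f"got {len(group_i)}"
        )
    if cfg.order_seed is not None:
        rng = np.random.default_rng(cfg.order_seed)
        group_i = [group_i[j] for j in rng.permutation(len(group_i))]
        group_ii = [group_ii[j] for j in rng.permutation(len(group_ii))]

    folds: list[list[int]] = [[] for _ in range(k)]
    fold_of: dict[int, int] = {}
    _process_group(group_i, records, folds, prot_sim, comp_sim, cfg,
                   seed_folds=True, fold_of=fold_of)
    if group_ii:
        _process_group(group_ii, records, folds, prot_sim, comp_sim, cfg,
                       seed_folds=False, fold_of=fold_of)
    group_of = {i: ("I" if records[i].pkd > cfg.pkd_threshold else "II")
                for i in range(len(records))}
    return FoldAssignment(fold_of=fold_of, group_of=group_of, k=k)


def holdout_test_fold(
    assignment: FoldAssignment, test_fold: int
) -> tuple[list[int], list[int]]:
    """Partition record indices into (train/validation, held-out test)."""
    if not 0 <= test_fold < assignment.k:
        raise ValueError(f"test_fold {test_fold} outside [0, {assignment.k})")
    test = assignment.fold_indices(test_fold)
    train = sorted(i for i in assignment.fold_of if assignment.fold_of[i] != test_fold)
    return train, test
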