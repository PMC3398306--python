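"""Bernoulli naive Bayes baseline over the same binary fingerprints.

The comparator for the Parzen-Rosenblatt window: per class, each fingerprint
bit is modelled as an independent Bernoulli with a Laplace-smoothed estimate

    P(bit_k = 1 | w_a) = (count_k + c) / (N_a + 2 c),       c = pseudocount,

and classes are ranked by log prior + summed bit log-likelihoods, with the
same deterministic tie rule (ascending class id) as the PRW ranker so the two
methods share the PredictionRanking contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import AssociationTable
from .prw import PredictionRanking, RankEntry, ranks_of_true_classes


@dataclass(frozen=True)
class NBModel:
    class_ids: tuple[str, ...]
    log_prior: np.ndarray  # (M,)
    log_p1: np.ndarray  # (M, d) log P(bit=1 | class)
    log_p0: np.ndarray  # (M, d) log P(bit=0 | class)
    d: int
    pseudocount: float

    def score_rows(self, queries: np.ndarray) -> np.ndarray:
        """Log posterior scores (up to the evidence constant) per query row."""
        q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        if q.shape[1] != self.d:
            raise ValueError(f"query dimension {q.shape[1]} != model dimension {self.d}")
        return self.log_prior + self.log_p0.sum(axis=1) + q @ (self.log_p1 - self.log_p0).T

    def rank_classes(self, x: np.ndarray, compound_id: str = "query") -> PredictionRanking:
        scores = self.score_rows(x)[0]
        order = np.argsort(-scores, kind="stable")
        entries = tuple(
            RankEntry(self.class_ids[j], float(scores[j]), r + 1) for r, j in enumerate(order)
        )
        return PredictionRanking(compound_id=compound_id, entries=entries)


def train_nb(table: AssociationTable, pseudocount: float = 1.0) -> NBModel:
    """Fit per-class bit frequencies with Laplace smoothing; priors are N_a/N."""
    if table.N == 0:
        raise ValueError("cannot train on an empty table")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    class_ids = table.class_ids
    d = table.d
    counts = np.zeros((len(class_ids), d), dtype=np.float64)
    sizes = np.zeros(len(class_ids), dtype=np.float64)
    col = {cid: j for j, cid in enumerate(class_ids)}
    for cid, tid in table.instances:
        j = col[tid]
        counts[j] += table.fingerprints[cid]
        sizes[j] += 1
    p1 = (counts + pseudocount) / (sizes[:, None] + 2.0 * pseudocount)
    return NBModel(
        class_ids=class_ids,
        log_prior=np.log(sizes / table.N),
        log_p1=np.log(p1),
        log_p0=np.log1p(-p1),
        d=d,
        pseudocount=float(pseudocount),
    )


def rank_classes_nb(x: np.ndarray, model: NBModel, compound_id: str = "query") -> PredictionRanking:
    return model.rank_classes(x, compound_id)


def nb_true_class_ranks(model: NBModel, queries: np.ndarray, true_ids) -> np.ndarray:
    scores = model.score_rows(queries)
    return ranks_of_true_classes(scores, model.class_ids, true_ids)
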