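"""Parzen-Rosenblatt window multi-class ranking of protein targets.

For a query fingerprint x the model scores every target class w_a by the
Bayes product p(w_a) * p(x | w_a), with

* prior      p(w_a)     = N_a / N           (instance proportion), and
* likelihood p(x | w_a) = (1/N_a) * sum over class members x_j of K(x, x_j),

where K is a Gaussian kernel on the Hamming disagreement count m between the
two binary fingerprints:

    K(x_i, x_j) = (h * sqrt(2*pi))**(-d) * exp(-m / (2 h**2)).

h is the smoothing factor (bandwidth).  Classes are ranked by descending
score; exact ties are broken by ascending class id so rankings are
reproducible.

Everything is evaluated in log space.  This is not a nicety: at the
bandwidths the grid search favours (h = 2**-3 and below) each disagreeing
bit multiplies the kernel by exp(-32) or less, so the direct product
underflows double precision after ~22 bits; the log-sum-exp form is exact
for any h in the grid.  Since the class-independent factor
1/(N * (h*sqrt(2*pi))**d) shifts every class equally, ranking depends only
on logsumexp_j(-m_j / (2 h**2)); the full log score is still reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .dataset import AssociationTable
from .fingerprints import pack_bits, pairwise_disagreement

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def log_kernel(m: int, h: float, d: int) -> float:
    """Log of the Gaussian kernel at disagreement count ``m``.

    Equals ``-d*ln(h*sqrt(2*pi)) - m/(2*h**2)``.  Consecutive disagreement
    counts differ by exactly ``-1/(2*h**2)`` in log space.
    """
    if h <= 0:
        raise ValueError(f"smoothing factor must be positive, got {h}")
    if not 0 <= m <= d:
        raise ValueError(f"disagreement count {m} outside [0, {d}]")
    return -d * (math.log(h) + LOG_SQRT_2PI) - m / (2.0 * h * h)


@dataclass(frozen=True)
class RankEntry:
    class_id: str
    log_score: float
    rank: int


@dataclass(frozen=True)
class PredictionRanking:
    """A total order over all classes for one query compound.

    Ranks run 1..M with no gaps; log scores are non-increasing with rank and
    ties are ordered by ascending class id.
    """

    compound_id: str
    entries: tuple[RankEntry, ...]

    def rank_of(self, class_id: str) -> int:
        for e in self.entries:
            if e.class_id == class_id:
                return e.rank
        raise KeyError(class_id)

    def top(self, k: int) -> list[str]:
        return [e.class_id for e in self.entries[: max(0, k)]]


class PRWModel:
    """A trained Parzen-Rosenblatt window ranker.

    Training is lazy in the kernel sense — the model simply stores the
    training table (per-class member fingerprints and instance counts) plus
    the smoothing factor h; all computation happens at query time.
    """

    def __init__(self, table: AssociationTable, h: float):
        if h <= 0:
            raise ValueError(f"smoothing factor must be positive, got {h}")
        if table.N == 0:
            raise ValueError("cannot build a model from an empty table")
        self.table = table
        self.h = float(h)
        self.d = table.d
        self.class_ids: tuple[str, ...] = table.class_ids
        # one row per training instance, grouped by class
        order = sorted(range(table.N), key=lambda i: (table.instances[i][1], table.instances[i][0]))
        rows = [table.fingerprints[table.instances[i][0]] for i in order]
        self._packed = pack_bits(rows)
        self._groups: list[np.ndarray] = []
        tids = [table.instances[i][1] for i in order]
        for tid in self.class_ids:
            idx = np.flatnonzero(np.asarray(tids, dtype=object) == tid)
            self._groups.append(idx)

    # ------------------------------------------------------------------
    def disagreements(self, queries: np.ndarray) -> np.ndarray:
        """q x N_train Hamming disagreement matrix for unpacked 0/1 queries."""
        q = np.atleast_2d(np.asarray(queries, dtype=np.uint8))
        if q.shape[1] != self.d:
            raise ValueError(f"query dimension {q.shape[1]} != model dimension {self.d}")
        return pairwise_disagreement(np.packbits(q, axis=1), self._packed)

    def score_rows(self, queries: np.ndarray, h: float | None = None) -> np.ndarray:
        """Log Bayes scores ln[p(w_a) p(x|w_a)] for each query row and class."""
        m = self.disagreements(queries)
        return scores_from_disagreement(
            m, self._groups, h if h is not None else self.h, self.d, self.table.N
        )

    def class_log_score(self, x: np.ndarray, class_id: str) -> float:
        """ln[p(w_a) * p(x | w_a)] for one class, underflow-free for any h."""
        try:
            col = self.class_ids.index(class_id)
        except ValueError:
            raise KeyError(f"unknown class {class_id!r}") from None
        return float(self.score_rows(x)[0, col])

    def rank_classes(self, x: np.ndarray, compound_id: str = "query") -> PredictionRanking:
        scores = self.score_rows(x)[0]
        order = np.argsort(-scores, kind="stable")  # stable => ties by ascending class id
        entries = tuple(
            RankEntry(self.class_ids[j], float(scores[j]), r + 1) for r, j in enumerate(order)
        )
        return PredictionRanking(compound_id=compound_id, entries=entries)

    def predict_top_k(self, x: np.ndarray, k: int = 100) -> list[str]:
        """The first min(k, M) class ids of the full ranking."""
        if k < 1:
            raise ValueError("k must be >= 1")
        return self.rank_classes(x).top(k)


def scores_from_disagreement(
    m: np.ndarray, groups: Sequence[np.ndarray], h: float, d: int, n_total: int
) -> np.ndarray:
    """Class log scores from a precomputed disagreement matrix.

    ``m`` is q x N_train with columns grouped per ``groups`` (one index array
    per class, in class-id order).  Factoring the computation this way lets a
    bandwidth grid search reuse one disagreement matrix for every h.
    """
    if h <= 0:
        raise ValueError(f"smoothing factor must be positive, got {h}")
    exponents = -m / (2.0 * h * h)
    const = -math.log(n_total) - d * (math.log(h) + LOG_SQRT_2PI)
    scores = np.empty((m.shape[0], len(groups)), dtype=np.float64)
    for j, idx in enumerate(groups):
        scores[:, j] = logsumexp(exponents[:, idx], axis=1)
    return scores + const


def ranks_of_true_classes(
    scores: np.ndarray, class_ids: Sequence[str], true_ids: Sequence[str]
) -> np.ndarray:
    """Rank (1-based) of each row's true class under the tie-break contract.

    A class outranks the true one if its score is strictly larger, or equal
    with a smaller class id.
    """
    col = {cid: j for j, cid in enumerate(class_ids)}
    true_cols = np.asarray([col[t] for t in true_ids])
    s_true = scores[np.arange(len(true_cols)), true_cols]
    better = (scores > s_true[:, None]).sum(axis=1)
    tied_before = np.asarray(
        [
            int(np.count_nonzero(scores[i, : true_cols[i]] == s_true[i]))
            for i in range(len(true_cols))
        ]
    )
    return better + tied_before + 1
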