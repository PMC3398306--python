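"""Model evaluation: stratified 99%/1% partitions, mean true-class rank,
bandwidth grid search, and the PRW-vs-NB comparison.

The protocol builds ``n_models`` (default 10) independent random partitions
of the association table.  Per class: 1% of instances go to validation
(floored, minimum one), except classes under 100 instances, which contribute
exactly one validation instance.  All remaining instances of a validation
compound are excluded from that partition's training side as well, so the
evaluation never trains on any data for a compound it is about to score.

The quality metric is the arithmetic mean, over validation instances, of the
rank that the model assigns to the instance's true class (1 = best).  The
smoothing factor h is selected by evaluating the mean rank over all
partitions on a geometric grid 2**-15, 2**-13, ..., 2**3 and taking the
argmin (ties resolved toward smaller h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import AssociationTable
from .nb import NBModel, nb_true_class_ranks, train_nb
from .prw import PRWModel, ranks_of_true_classes, scores_from_disagreement

#: The default smoothing-factor grid: exponents -15, -13, ..., 3 (ten values).
DEFAULT_H_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class Partition:
    """One train/validation split.

    ``excluded`` holds instances of validation compounds that were not
    themselves drawn for validation; they sit on neither side, so
    train + validation + excluded is the full instance set.
    """

    train: tuple[tuple[str, str], ...]
    validation: tuple[tuple[str, str], ...]
    excluded: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class PartitionSet:
    partitions: tuple[Partition, ...]
    fraction: float
    cutoff: int
    seed: int

    @property
    def n_models(self) -> int:
        return len(self.partitions)


def validation_count(class_size: int, fraction: float = 0.01, cutoff: int = 100) -> int:
    """Validation instances contributed by a class: 1 below the cutoff,
    otherwise floor(fraction * size) with a minimum of one."""
    if class_size < 2:
        raise ValueError("classes need >= 2 instances to appear on both sides")
    if class_size < cutoff:
        return 1
    return max(1, math.floor(fraction * class_size))


def make_partitions(
    table: AssociationTable,
    n_models: int = 10,
    fraction: float = 0.01,
    cutoff: int = 100,
    seed: int = 0,
) -> PartitionSet:
    """Draw ``n_models`` stratified splits, reproducibly from ``seed``."""
    by_class: dict[str, list[tuple[str, str]]] = {}
    for inst in table.instances:
        by_class.setdefault(inst[1], []).append(inst)
    for tid, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {tid!r} has a single instance; cannot split")
    streams = np.random.SeedSequence(seed).spawn(n_models)
    partitions = []
    all_instances = set(table.instances)
    for stream in streams:
        rng = np.random.default_rng(stream)
        validation: list[tuple[str, str]] = []
        for tid in sorted(by_class):
            members = by_class[tid]
            v = validation_count(len(members), fraction, cutoff)
            picks = rng.choice(len(members), size=v, replace=False)
            validation.extend(members[i] for i in picks)
        vset = set(validation)
        vcompounds = {cid for cid, _ in validation}
        train, excluded = [], []
        for inst in sorted(all_instances):
            if inst in vset:
                continue
            (excluded if inst[0] in vcompounds else train).append(inst)
        tset = {tid for _, tid in train}
        lost = set(by_class) - tset
        if lost:
            raise ValueError(
                f"classes {sorted(lost)} lost all training instances to compound-level exclusion"
            )
        partitions.append(
            Partition(train=tuple(train), validation=tuple(validation), excluded=tuple(excluded))
        )
    return PartitionSet(
        partitions=tuple(partitions), fraction=fraction, cutoff=cutoff, seed=seed
    )


def true_class_ranks(
    model: PRWModel,
    validation: Sequence[tuple[str, str]],
    fingerprints=None,
) -> np.ndarray:
    """Rank of the true class for each validation (compound, class) instance.

    ``fingerprints`` supplies the held-out compounds' bit vectors (the trained
    model's table no longer carries them); defaults to the model's own map for
    in-sample queries.
    """
    fps = dict(model.table.fingerprints)
    if fingerprints is not None:
        fps.update(fingerprints)
    known = set(model.class_ids)
    missing = sorted({t for _, t in validation if t not in known})
    if missing:
        raise ValueError(f"validation classes absent from model: {missing}")
    queries = np.asarray([fps[c] for c, _ in validation], dtype=np.uint8)
    scores = model.score_rows(queries)
    return ranks_of_true_classes(scores, model.class_ids, [t for _, t in validation])


def mean_true_rank(
    model: PRWModel, validation: Sequence[tuple[str, str]], fingerprints=None
) -> float:
    """Arithmetic mean of the true-class rank over the validation set."""
    return float(true_class_ranks(model, validation, fingerprints).mean())


@dataclass(frozen=True)
class RecoveryStats:
    """Truth-based recovery of generating classes on held-out compounds."""

    mean_rank: float
    top1_accuracy: float
    n_evaluated: int
    n_skipped: int  # held-out compounds whose generating class left the table


def recovery_statistics(
    table: AssociationTable,
    partitions: PartitionSet,
    h: float,
    truth_classes,
) -> RecoveryStats:
    """Mean rank and top-1 accuracy of each held-out compound's generating class.

    ``truth_classes`` maps compound id -> the class whose profile generated
    it (a synthetic-universe truth map).  Compounds whose generating class is
    absent from the table (e.g. pruned) are skipped and counted.
    """
    ranks: list[int] = []
    skipped = 0
    for part in partitions.partitions:
        model = PRWModel(table.subset(part.train), h=h)
        known = set(model.class_ids)
        held_out = sorted({cid for cid, _ in part.validation})
        kept = [c for c in held_out if truth_classes.get(c) in known]
        skipped += len(held_out) - len(kept)
        if not kept:
            continue
        queries = np.asarray([table.fingerprints[c] for c in kept], dtype=np.uint8)
        r = ranks_of_true_classes(
            model.score_rows(queries), model.class_ids, [truth_classes[c] for c in kept]
        )
        ranks.extend(r.tolist())
    arr = np.asarray(ranks, dtype=float)
    return RecoveryStats(
        mean_rank=float(arr.mean()),
        top1_accuracy=float((arr == 1).mean()),
        n_evaluated=int(arr.size),
        n_skipped=skipped,
    )


@dataclass(frozen=True)
class GridSearchResult:
    best_h: float
    report: pd.DataFrame  # columns: h, partition, mean_rank
    summary: pd.DataFrame  # columns: h, mean_rank (averaged over partitions)


def grid_search_h(
    table: AssociationTable,
    partitions: PartitionSet,
    grid: Sequence[float] = DEFAULT_H_GRID,
) -> GridSearchResult:
    """Mean true-class rank per h, averaged over partitions; returns the argmin.

    The per-partition disagreement matrix is computed once and reused for
    every bandwidth, so the grid adds almost no cost over a single h.
    """
    grid = sorted(grid)
    if not grid:
        raise ValueError("empty smoothing-factor grid")
    rows = []
    for p_idx, part in enumerate(partitions.partitions):
        train_table = table.subset(part.train)
        model = PRWModel(train_table, h=1.0)  # h replaced per grid point
        queries = np.asarray(
            [table.fingerprints[c] for c, _ in part.validation], dtype=np.uint8
        )
        true_ids = [t for _, t in part.validation]
        m = model.disagreements(queries)
        for h in grid:
            scores = scores_from_disagreement(m, model._groups, h, model.d, train_table.N)
            ranks = ranks_of_true_classes(scores, model.class_ids, true_ids)
            rows.append({"h": h, "partition": p_idx, "mean_rank": float(ranks.mean())})
    report = pd.DataFrame(rows)
    summary = report.groupby("h", as_index=False)["mean_rank"].mean()
    best_idx = summary["mean_rank"].idxmin()  # first minimum -> smallest h (grid sorted)
    return GridSearchResult(
        best_h=float(summary.loc[best_idx, "h"]), report=report, summary=summary
    )


@dataclass(frozen=True)
class MethodComparison:
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float


def compare_methods(
    ranks_a: Sequence[float], ranks_b: Sequence[float]
) -> MethodComparison:
    """Paired two-sided t-test on per-partition mean ranks of two methods.

    Partitions are shared between the methods, hence the paired design.  A
    degenerate all-zero difference vector is reported as statistic 0, p 1.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rank lists must be paired (equal length)")
    if a.size < 2:
        raise ValueError("need at least two partitions")
    if np.allclose(a - b, 0.0):
        return MethodComparison(0.0, 1.0, float(a.mean()), float(b.mean()))
    t = stats.ttest_rel(a, b)
    return MethodComparison(float(t.statistic), float(t.pvalue), float(a.mean()), float(b.mean()))


@dataclass(frozen=True)
class ValidationReport:
    """Cross-method evaluation at a fixed h across all partitions."""

    prw_mean_ranks: tuple[float, ...]
    nb_mean_ranks: tuple[float, ...]
    h: float
    comparison: MethodComparison


def evaluate_methods(
    table: AssociationTable,
    partitions: PartitionSet,
    h: float,
    nb_pseudocount: float = 1.0,
) -> ValidationReport:
    """Per-partition PRW and NB mean true-class ranks and their paired test."""
    prw_means, nb_means = [], []
    for part in partitions.partitions:
        train_table = table.subset(part.train)
        queries = np.asarray(
            [table.fingerprints[c] for c, _ in part.validation], dtype=np.uint8
        )
        true_ids = [t for _, t in part.validation]
        prw = PRWModel(train_table, h=h)
        prw_ranks = ranks_of_true_classes(prw.score_rows(queries), prw.class_ids, true_ids)
        prw_means.append(float(prw_ranks.mean()))
        nb: NBModel = train_nb(train_table, pseudocount=nb_pseudocount)
        nb_means.append(float(nb_true_class_ranks(nb, queries, true_ids).mean()))
    return ValidationReport(
        prw_mean_ranks=tuple(prw_means),
        nb_mean_ranks=tuple(nb_means),
        h=h,
        comparison=compare_methods(prw_means, nb_means),
    )
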