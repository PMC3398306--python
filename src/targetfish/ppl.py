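"""Phospholipidosis off-target scoring.

The target-fishing models are applied to a labelled set of compounds that
either induce phospholipidosis (PPL+, label +1) or are experimentally
confirmed not to (PPL-, label -1).  For each compound and each of the
``n_models`` partition-trained models, every class in the model's top-K
ranking counts as one predicted interaction; the per-compound, per-target
tally over models is the score matrix (entries 0..n_models).

Per target w_a the phospholipidosis score is

    PS_a = sum over compounds i of c_p(x_i) * delta_i(w_a)

summed over all models, where c_p is the +/-1 label and delta is the top-K
indicator — i.e. PS_a = (positive hits) - (negative hits).  Targets whose
inhibition plausibly causes the phenotype should accumulate positive hits
from PPL+ compounds and few negative ones.

The module also provides target-pair association statistics (Pearson r over
the two score columns and a chi-squared independence test on binarized
hits), used to ask whether two candidate mechanism targets are driven by the
same or by disjoint compound subsets, and the Ploemen physico-chemical
baseline rule (pKa > 8, ClogP > 1, ClogP^2 + pKa^2 > 90).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fingerprints import featurize_compounds
from .prw import PRWModel


@dataclass(frozen=True)
class PPLCompound:
    """A labelled phospholipidosis compound; label is +1 (PPL+) or -1 (PPL-)."""

    name: str
    smiles: str
    label: int

    def __post_init__(self):
        if self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")


@dataclass(frozen=True)
class ScoreMatrix:
    """Per compound x target count of models predicting the pair in their top-K."""

    compound_names: tuple[str, ...]
    class_ids: tuple[str, ...]
    counts: np.ndarray  # (n_compounds, M) ints in 0..n_models
    n_models: int
    k: int

    def __post_init__(self):
        if self.counts.shape != (len(self.compound_names), len(self.class_ids)):
            raise ValueError("counts shape does not match row/column labels")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_models:
            raise ValueError("entries must lie in 0..n_models")

    def column(self, class_id: str) -> np.ndarray:
        return self.counts[:, self.class_ids.index(class_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.compound_names), columns=list(self.class_ids)
        )


def score_matrix(
    models: Sequence[PRWModel],
    compounds: Sequence[PPLCompound],
    k: int = 100,
    *,
    fingerprints: Mapping[str, np.ndarray] | None = None,
) -> ScoreMatrix:
    """Tally, over models, each target's appearances in a compound's top-K.

    ``fingerprints`` maps compound name -> bit vector; when absent, vectors
    are computed from SMILES with each model's stored fingerprint settings.
    All models must share fingerprint dimension and class set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not models:
        raise ValueError("need at least one model")
    d0, cids = models[0].d, models[0].class_ids
    for m in models[1:]:
        if m.d != d0 or m.class_ids != cids:
            raise ValueError("models disagree on fingerprint dimension or class set")
    if fingerprints is None:
        meta = models[0].table.meta
        if meta.get("kind") != "morgan":
            raise ValueError("models trained on supplied fingerprints need explicit vectors")
        fingerprints = featurize_compounds(
            {c.name: c.smiles for c in compounds},
            radius=meta["radius"],
            n_bits=meta["n_bits"],
        )
    queries = np.asarray([fingerprints[c.name] for c in compounds], dtype=np.uint8)
    counts = np.zeros((len(compounds), len(cids)), dtype=np.int64)
    col = {cid: j for j, cid in enumerate(cids)}
    kk = min(k, len(cids))
    for model in models:
        scores = model.score_rows(queries)
        # top-k columns under the usual tie rule: stable argsort on -score
        order = np.argsort(-scores, axis=1, kind="stable")[:, :kk]
        for i in range(len(compounds)):
            counts[i, order[i]] += 1
    return ScoreMatrix(
        compound_names=tuple(c.name for c in compounds),
        class_ids=cids,
        counts=counts,
        n_models=len(models),
        k=k,
    )


@dataclass(frozen=True)
class PSTable:
    """Per-target phospholipidosis scores, ranked by descending PS."""

    frame: pd.DataFrame  # columns: rank, class_id, ps, pos_hits, neg_hits

    def ps(self, class_id: str) -> int:
        row = self.frame.loc[self.frame["class_id"] == class_id]
        if row.empty:
            raise KeyError(class_id)
        return int(row["ps"].iloc[0])

    def rank(self, class_id: str) -> int:
        row = self.frame.loc[self.frame["class_id"] == class_id]
        if row.empty:
            raise KeyError(class_id)
        return int(row["rank"].iloc[0])


def ps_scores(matrix: ScoreMatrix, labels: Mapping[str, int]) -> PSTable:
    """PS_a = sum_i c_p(x_i) * count(i, a), with positive/negative breakdowns.

    ``labels`` maps every compound name in the matrix to +1 or -1.  Targets
    are ranked by descending PS, ties by ascending class id (sequential
    ranks 1..M).
    """
    missing = [n for n in matrix.compound_names if n not in labels]
    if missing:
        raise ValueError(f"missing PPL labels for {missing[:5]} ...")
    lab = np.asarray([labels[n] for n in matrix.compound_names])
    if not set(np.unique(lab)) <= {-1, 1}:
        raise ValueError("labels must be +1 or -1")
    pos = matrix.counts[lab == 1].sum(axis=0)
    neg = matrix.counts[lab == -1].sum(axis=0)
    frame = pd.DataFrame(
        {
            "class_id": list(matrix.class_ids),
            "ps": (pos - neg).astype(int),
            "pos_hits": pos.astype(int),
            "neg_hits": neg.astype(int),
        }
    )
    frame = frame.sort_values(
        ["ps", "class_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return PSTable(frame=frame)


@dataclass(frozen=True)
class PairAssociation:
    pearson_r: float | None  # None when a column has zero variance
    r_note: str
    chi2_stat: float | None
    chi2_p: float | None
    contingency: np.ndarray


def target_pair_association(
    matrix: ScoreMatrix,
    class_a: str,
    class_b: str,
    *,
    r_on: str = "scores",
    chi2_on: str = "binary",
) -> PairAssociation:
    """Association between two targets' score columns.

    Pearson r is computed on the raw 0..n_models scores (``r_on="scores"``)
    or on hit indicators (``r_on="binary"``).  The chi-squared independence
    test uses a 2x2 table from binarizing each column at >= 1 hit
    (``chi2_on="binary"``, no continuity correction) or the full joint
    contingency of raw score levels (``chi2_on="raw"``).
    """
    a = matrix.column(class_a).astype(float)
    b = matrix.column(class_b).astype(float)
    if len(a) < 2:
        raise ValueError("need at least two compounds")
    if r_on == "binary":
        ra, rb = (a >= 1).astype(float), (b >= 1).astype(float)
    elif r_on == "scores":
        ra, rb = a, b
    else:
        raise ValueError(f"unknown r_on mode {r_on!r}")
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        r, note = None, "undefined: a score column has zero variance"
    else:
        r = float(stats.pearsonr(ra, rb).statistic)
        note = ""
    if chi2_on == "binary":
        table = np.asarray(
            [
                [np.sum((a >= 1) & (b >= 1)), np.sum((a >= 1) & (b < 1))],
                [np.sum((a < 1) & (b >= 1)), np.sum((a < 1) & (b < 1))],
            ],
            dtype=float,
        )
    elif chi2_on == "raw":
        table = pd.crosstab(a, b).to_numpy().astype(float)
    else:
        raise ValueError(f"unknown chi2_on mode {chi2_on!r}")
    # drop all-zero rows/columns so expected counts stay positive
    table = table[table.sum(axis=1) > 0]
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        chi2_stat, chi2_p = None, None
    else:
        res = stats.chi2_contingency(table, correction=False)
        chi2_stat, chi2_p = float(res.statistic), float(res.pvalue)
    return PairAssociation(
        pearson_r=r, r_note=note, chi2_stat=chi2_stat, chi2_p=chi2_p, contingency=table
    )


def ploemen_rule(pka: float, clogp: float) -> str:
    """Physico-chemical phospholipidosis classifier.

    Positive iff pKa > 8 and ClogP > 1 and ClogP**2 + pKa**2 > 90 (all
    strict); the boundary sum of exactly 90 is negative.
    """
    if not (np.isfinite(pka) and np.isfinite(clogp)):
        raise ValueError("pKa and ClogP must be finite")
    ok = pka > 8.0 and clogp > 1.0 and (clogp * clogp + pka * pka) > 90.0
    return "positive" if ok else "negative"


def plot_score_matrix(matrix: ScoreMatrix, class_ids: Sequence[str] | None = None, path=None):
    """Heatmap of the compound x target score matrix (0..n_models)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = list(class_ids) if class_ids is not None else list(matrix.class_ids)
    data = np.column_stack([matrix.column(c) for c in cols])
    fig, ax = plt.subplots(figsize=(max(4, len(cols) * 0.6), max(4, len(matrix.compound_names) * 0.12)))
    im = ax.imshow(data, aspect="auto", cmap="Blues", vmin=0, vmax=matrix.n_models)
    ax.set_xticks(range(len(cols)), cols, rotation=90)
    ax.set_ylabel("compound")
    fig.colorbar(im, ax=ax, label="models predicting interaction")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
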