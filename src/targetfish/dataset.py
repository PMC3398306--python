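"""Bioactivity filtering and assembly of the compound-target training table.

The raw input is a ChEMBL-style activity export: one row per measured
compound-target interaction (IC50 / Ki / Kd in concentration units, or a
percent-binding figure).  The pipeline keeps a record only when

* the compound has an associated structure,
* the target description contains one of the filter keywords
  ("enzyme", "cytosolic", "receptor", "agonist", "ion channel"), and
* the activity passes the threshold: concentration < 500 uM (after unit
  normalization) or percent binding > 50.

The deliberately permissive 500 uM cut keeps weak binders, which is the point
of off-target prediction.  Surviving (compound, target) pairs are
deduplicated into unweighted instances, targets with fewer than 20 distinct
compounds are pruned, and compounds are featurized into binary circular
fingerprints, yielding an :class:`AssociationTable` — the N instances over M
classes that the classifiers train on.  A compound may appear under several
targets; each pair is one instance.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fingerprints import DEFAULT_N_BITS, DEFAULT_RADIUS, featurize_compounds

logger = logging.getLogger(__name__)

CONCENTRATION_KINDS = frozenset({"IC50", "Ki", "Kd"})
PERCENT_KIND = "percent_binding"
MEASURE_KINDS = CONCENTRATION_KINDS | {PERCENT_KIND}

#: Unit-string -> factor converting a value to micromolar.
TO_MICROMOLAR = {
    "nm": 1e-3,
    "um": 1.0,
    "µm": 1.0,  # micro sign
    "μm": 1.0,  # greek mu
    "mm": 1e3,
}

DEFAULT_KEYWORDS = ("enzyme", "cytosolic", "receptor", "agonist", "ion channel")


@dataclass(frozen=True)
class ActivityRecord:
    """One measured compound-target interaction."""

    compound_id: str
    smiles: str
    target_id: str
    target_name: str
    target_description: str
    measure_kind: str  # one of MEASURE_KINDS
    value: float
    units: str = ""
    relation: str = "="  # activity qualifier: "=", "<", ">", "~"

    def __post_init__(self):
        if self.measure_kind not in MEASURE_KINDS:
            raise ValueError(f"unknown measure kind {self.measure_kind!r}")
        if self.value < 0:
            raise ValueError(f"negative activity value {self.value}")


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the activity-record filter.

    Thresholds are strict: a concentration equal to ``conc_threshold_um`` or a
    percent equal to ``percent_threshold`` is dropped.
    """

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    conc_threshold_um: float = 500.0
    percent_threshold: float = 50.0
    min_class_size: int = 20


def _value_in_um(record: ActivityRecord) -> float | None:
    factor = TO_MICROMOLAR.get(record.units.strip().lower())
    if factor is None:
        logger.warning(
            "rejecting %s/%s: unknown concentration units %r",
            record.compound_id,
            record.target_id,
            record.units,
        )
        return None
    return record.value * factor


def _activity_passes(record: ActivityRecord, config: FilterConfig) -> bool:
    if record.measure_kind in CONCENTRATION_KINDS:
        value = _value_in_um(record)
        if value is None:
            return False
        # Qualified values: "<x" is an upper bound, so it passes whenever the
        # bound itself does not exceed the threshold; ">x" is a lower bound
        # and can never certify sub-threshold potency.
        if record.relation == ">":
            return False
        if record.relation == "<":
            return value <= config.conc_threshold_um
        return value < config.conc_threshold_um
    # percent binding, dimensionless; the mirror-image qualifier logic
    if record.relation == "<":
        return False
    if record.relation == ">":
        return record.value >= config.percent_threshold
    return record.value > config.percent_threshold


def filter_activity_records(
    records: Iterable[ActivityRecord], config: FilterConfig = FilterConfig()
) -> list[ActivityRecord]:
    """Keep records with a structure, a keyword-matched target and a passing activity.

    Keyword matching is a case-insensitive substring test over the target
    description.  Idempotent: filtering a filtered list is a no-op.
    """
    keywords = tuple(k.lower() for k in config.keywords)
    kept = []
    for rec in records:
        if not rec.smiles:
            continue
        desc = rec.target_description.lower()
        if not any(k in desc for k in keywords):
            continue
        if _activity_passes(rec, config):
            kept.append(rec)
    return kept


def prune_small_classes(
    instances: Iterable[tuple[str, str]], min_class_size: int = 20
) -> list[tuple[str, str]]:
    """Drop every class with fewer than ``min_class_size`` distinct compounds.

    Compounds are only ever removed by losing all of their classes.
    """
    instances = sorted(set(instances))
    per_class = Counter(tid for _, tid in instances)
    return [(cid, tid) for cid, tid in instances if per_class[tid] >= min_class_size]


@dataclass(frozen=True)
class AssociationTable:
    """The filtered multi-label training set: N instances over M classes.

    ``instances`` are deduplicated (compound_id, class_id) pairs, kept sorted
    for reproducibility.  Every compound referenced by an instance has a
    fingerprint; all fingerprints share one dimension d.
    """

    instances: tuple[tuple[str, str], ...]
    fingerprints: Mapping[str, np.ndarray]
    class_names: Mapping[str, str] = field(default_factory=dict)
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "instances", tuple(sorted(self.instances)))
        dims = set()
        for cid, _ in self.instances:
            fp = self.fingerprints.get(cid)
            if fp is None:
                raise ValueError(f"instance compound {cid!r} has no fingerprint")
            dims.add(len(fp))
        if len(dims) > 1:
            raise ValueError(f"inconsistent fingerprint dimensions: {sorted(dims)}")

    # -- size accessors -------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.instances)

    @property
    def class_sizes(self) -> Counter:
        return Counter(tid for _, tid in self.instances)

    @property
    def class_ids(self) -> tuple[str, ...]:
        return tuple(sorted({tid for _, tid in self.instances}))

    @property
    def M(self) -> int:
        return len(self.class_ids)

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(sorted({cid for cid, _ in self.instances}))

    @property
    def d(self) -> int:
        if not self.instances:
            raise ValueError("empty table has no fingerprint dimension")
        return len(self.fingerprints[self.instances[0][0]])

    def subset(self, instances: Iterable[tuple[str, str]]) -> "AssociationTable":
        """A table restricted to the given instances (fingerprints trimmed)."""
        instances = tuple(sorted(set(instances)))
        missing = set(instances) - set(self.instances)
        if missing:
            raise ValueError(f"{len(missing)} instances not in table")
        cids = {cid for cid, _ in instances}
        return replace(
            self,
            instances=instances,
            fingerprints={c: self.fingerprints[c] for c in cids},
        )


def build_association_table(
    records: Iterable[ActivityRecord],
    config: FilterConfig = FilterConfig(),
    *,
    fingerprints: Mapping[str, np.ndarray] | None = None,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    on_parse_error: str = "raise",
) -> AssociationTable:
    """Filter -> dedupe -> prune -> featurize, in that order.

    ``fingerprints`` may supply precomputed bit vectors (e.g. from a
    fingerprint-matrix file or a synthetic universe), bypassing SMILES
    parsing; otherwise surviving compounds are featurized from their SMILES.
    """
    records = list(records)
    kept = filter_activity_records(records, config)
    instances = prune_small_classes(
        {(r.compound_id, r.target_id) for r in kept}, config.min_class_size
    )
    surviving_tids = {tid for _, tid in instances}
    class_names = {r.target_id: r.target_name for r in kept if r.target_id in surviving_tids}
    cids = {cid for cid, _ in instances}
    if fingerprints is None:
        smiles = {r.compound_id: r.smiles for r in kept if r.compound_id in cids}
        fps = featurize_compounds(smiles, radius=radius, n_bits=n_bits, on_error=on_parse_error)
        if on_parse_error == "skip":
            instances = prune_small_classes(
                [(c, t) for c, t in instances if c in fps], config.min_class_size
            )
        meta = {"radius": radius, "n_bits": n_bits, "kind": "morgan"}
    else:
        missing = cids - set(fingerprints)
        if missing:
            raise ValueError(f"no fingerprint supplied for {sorted(missing)[:5]} ...")
        fps = {c: np.asarray(fingerprints[c], dtype=np.uint8) for c in cids}
        meta = {"radius": None, "n_bits": None, "kind": "supplied"}
    return AssociationTable(
        instances=tuple(instances), fingerprints=fps, class_names=class_names, meta=meta
    )
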