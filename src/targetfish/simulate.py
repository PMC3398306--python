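"""Synthetic activity universes and phospholipidosis sets with known truth.

The generator emulates the statistical shape of a filtered bioactivity
corpus without any chemistry: each target class gets a random binary bit
profile; each compound is a noisy copy of its primary class's profile
(independent per-bit flips), optionally cross-listed under extra classes
(multi-label associations); activity values, units, measure kinds and target
descriptions are drawn so that the dataset-building filters are genuinely
exercised — decoy records carry failing activity values, missing structures
or keyword-free target descriptions, while every intended class member
passes, keeping requested class sizes exact after filtering.

Compound "structures" are opaque ``SYN:`` tokens; the generated fingerprints
are supplied to the pipeline directly, so model-layer behaviour can be
tested independently of SMILES parsing.  A small list of real drug SMILES
(mostly cationic amphiphilic drugs) is shipped separately for
featurization-path tests.

The phospholipidosis generator plants ground truth: designated "mechanism"
targets whose profiles PPL+ compounds carry with a configurable enrichment
probability, so PS-ranking recovery can be measured against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .dataset import DEFAULT_KEYWORDS, ActivityRecord
from .ppl import PPLCompound

#: Real structures (name -> SMILES) for featurization tests; several are
#: classic phospholipidosis-inducing cationic amphiphilic drugs.
EXAMPLE_SMILES: dict[str, str] = {
    "amiodarone": "CCCCC1=C(C2=CC=CC=C2O1)C(=O)C3=CC(=C(C(=C3)I)OCCN(CC)CC)I",
    "chloroquine": "CCN(CC)CCCC(C)NC1=C2C=CC(=CC2=NC=C1)Cl",
    "fluoxetine": "CNCCC(C1=CC=CC=C1)OC2=CC=C(C=C2)C(F)(F)F",
    "tamoxifen": "CC/C(=C(\\c1ccccc1)c1ccc(OCCN(C)C)cc1)/c1ccccc1",
    "chlorpromazine": "CN(C)CCCN1C2=CC=CC=C2SC3=C1C=C(C=C3)Cl",
    "imipramine": "CN(C)CCCN1C2=CC=CC=C2CCC3=CC=CC=C31",
    "propranolol": "CC(C)NCC(O)COC1=CC=CC2=CC=CC=C12",
    "gentamicin_core": "CNC1C(O)C(N)CC(N)C1O",
    "caffeine": "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
    "aspirin": "CC(=O)OC1=CC=CC=C1C(=O)O",
    "ibuprofen": "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",
    "paracetamol": "CC(=O)NC1=CC=C(C=C1)O",
    "ethanol": "CCO",
    "methane": "C",
}

_MEASURES = ("IC50", "Ki", "Kd", "percent_binding")
_UNIT_CYCLE = ("nM", "uM", "mM")


def _default_class_sizes(rng: np.random.Generator, m: int) -> list[int]:
    """Sizes straddling both the 20-compound and 100-instance rules:
    ~8% large (101-150), ~8% sub-threshold (15-19, pruned), rest 21-80."""
    sizes = []
    for _ in range(m):
        u = rng.random()
        if u < 0.08:
            sizes.append(int(rng.integers(101, 151)))
        elif u < 0.16:
            sizes.append(int(rng.integers(15, 20)))
        else:
            sizes.append(int(rng.integers(21, 81)))
    return sizes


@dataclass(frozen=True)
class UniverseSpec:
    """Shape of a synthetic activity universe.

    ``class_sizes`` may be an explicit sequence (length M) or None for the
    default straddling sampler.  ``decoy_fraction`` adds that proportion of
    extra records designed to be removed by the filters.
    """

    seed: int
    M: int = 50
    d: int = 256
    bits_per_profile: int = 16
    profiles_per_class: int = 3
    class_sizes: Sequence[int] | None = None
    flip_noise: float = 0.05
    multi_label_rate: float = 0.1
    decoy_fraction: float = 0.15
    seed_note: str = ""

    def __post_init__(self):
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must lie in [0, 0.5)")
        if self.bits_per_profile > self.d:
            raise ValueError("bits_per_profile cannot exceed d")
        if self.profiles_per_class < 1:
            raise ValueError("profiles_per_class must be >= 1")
        if self.M >= 2 and self.bits_per_profile == 0 and self.flip_noise == 0:
            raise ValueError("indistinguishable classes: no profile bits and no noise")
        if self.class_sizes is not None and len(self.class_sizes) != self.M:
            raise ValueError("class_sizes must have one entry per class")


@dataclass(frozen=True)
class UniverseTruth:
    """Ground truth for a generated universe."""

    fingerprints: Mapping[str, np.ndarray]
    primary_class: Mapping[str, str]  # compound -> generating class
    profiles: Mapping[str, np.ndarray]  # class -> (profiles_per_class, d) scaffold bits
    class_ids: tuple[str, ...]
    decoy_record_ids: tuple[int, ...]  # indices into the record list
    extra_labels: tuple[tuple[str, str], ...]  # multi-label (compound, class)


def _noisy_copy(profile: np.ndarray, flip_noise: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(profile.shape[0]) < flip_noise
    return (profile ^ flips).astype(np.uint8)


def _passing_record(
    cid: str, tid: str, desc: str, rng: np.random.Generator, i: int
) -> ActivityRecord:
    kind = _MEASURES[i % len(_MEASURES)]
    if kind == "percent_binding":
        value, units = float(rng.uniform(51, 100)), ""
    else:
        um = float(rng.uniform(0.001, 499.0))
        units = _UNIT_CYCLE[i % len(_UNIT_CYCLE)]
        value = um / {"nM": 1e-3, "uM": 1.0, "mM": 1e3}[units]
    return ActivityRecord(
        compound_id=cid,
        smiles=f"SYN:{cid}",
        target_id=tid,
        target_name=tid,
        target_description=desc,
        measure_kind=kind,
        value=value,
        units=units,
    )


def generate_universe(spec: UniverseSpec) -> tuple[list[ActivityRecord], UniverseTruth]:
    """Generate an activity-record list plus ground truth, reproducibly."""
    root = np.random.SeedSequence(spec.seed)
    rng_profiles, rng_compounds, rng_records, rng_decoys = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    class_ids = tuple(f"T{j:04d}" for j in range(spec.M))
    descriptions = {
        tid: f"{DEFAULT_KEYWORDS[j % len(DEFAULT_KEYWORDS)]} target {j}"
        for j, tid in enumerate(class_ids)
    }
    profiles: dict[str, np.ndarray] = {}
    for tid in class_ids:
        scaffolds = np.zeros((spec.profiles_per_class, spec.d), dtype=np.uint8)
        for s in range(spec.profiles_per_class):
            on = rng_profiles.choice(spec.d, size=spec.bits_per_profile, replace=False)
            scaffolds[s, on] = 1
        profiles[tid] = scaffolds
    sizes = (
        list(spec.class_sizes)
        if spec.class_sizes is not None
        else _default_class_sizes(rng_profiles, spec.M)
    )

    records: list[ActivityRecord] = []
    fingerprints: dict[str, np.ndarray] = {}
    primary: dict[str, str] = {}
    extra_labels: list[tuple[str, str]] = []
    counter = 0
    for tid, size in zip(class_ids, sizes):
        for _ in range(size):
            cid = f"C{counter:06d}"
            counter += 1
            scaffold = profiles[tid][int(rng_compounds.integers(0, spec.profiles_per_class))]
            fingerprints[cid] = _noisy_copy(scaffold, spec.flip_noise, rng_compounds)
            primary[cid] = tid
            records.append(
                _passing_record(cid, tid, descriptions[tid], rng_records, len(records))
            )
            # multi-label cross-listing under other classes
            n_extra = rng_compounds.poisson(spec.multi_label_rate)
            if n_extra:
                others = [t for t in class_ids if t != tid]
                picks = rng_compounds.choice(len(others), size=min(n_extra, len(others)), replace=False)
                for p in picks:
                    other = others[p]
                    extra_labels.append((cid, other))
                    records.append(
                        _passing_record(cid, other, descriptions[other], rng_records, len(records))
                    )

    # decoy records that every filter stage must remove
    decoy_ids: list[int] = []
    n_decoys = int(round(spec.decoy_fraction * len(records)))
    known_cids = sorted(fingerprints)
    for i in range(n_decoys):
        mode = i % 3
        tid = class_ids[int(rng_decoys.integers(0, spec.M))]
        cid = known_cids[int(rng_decoys.integers(0, len(known_cids)))]
        if mode == 0:  # failing activity value (both threshold kinds exercised)
            if (i // 3) % 2:
                kind, value, units = "percent_binding", float(rng_decoys.uniform(0.0, 50.0)), ""
            else:
                kind, value, units = _MEASURES[i % 3], float(rng_decoys.uniform(500.0, 5000.0)), "uM"
            rec = ActivityRecord(
                compound_id=cid,
                smiles=f"SYN:{cid}",
                target_id=f"DK{i:04d}",
                target_name=f"DK{i:04d}",
                target_description=descriptions[tid],
                measure_kind=kind,
                value=value,
                units=units,
            )
        elif mode == 1:  # missing structure
            rec = ActivityRecord(
                compound_id=f"X{i:06d}",
                smiles="",
                target_id=tid,
                target_name=tid,
                target_description=descriptions[tid],
                measure_kind="Ki",
                value=1.0,
                units="uM",
            )
        else:  # keyword-free target description
            rec = ActivityRecord(
                compound_id=cid,
                smiles=f"SYN:{cid}",
                target_id=f"DM{i:04d}",
                target_name=f"DM{i:04d}",
                target_description="miscellaneous uncharacterized protein",
                measure_kind="IC50",
                value=1.0,
                units="uM",
            )
        decoy_ids.append(len(records))
        records.append(rec)

    truth = UniverseTruth(
        fingerprints=fingerprints,
        primary_class=primary,
        profiles=profiles,
        class_ids=class_ids,
        decoy_record_ids=tuple(decoy_ids),
        extra_labels=tuple(extra_labels),
    )
    return records, truth


@dataclass(frozen=True)
class PPLSpec:
    """Shape of a synthetic phospholipidosis set.

    Defaults mirror the published dataset shape: 100 PPL+ and 82 PPL-
    compounds.  ``enrichment`` is the probability that a PPL+ compound
    carries a mechanism-target profile rather than a random one.
    """

    seed: int
    n_pos: int = 100
    n_neg: int = 82
    mechanism_targets: tuple[str, ...] = ()
    enrichment: float = 0.75
    flip_noise: float = 0.05

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("n_pos and n_neg must be positive")
        if not 0 <= self.enrichment <= 1:
            raise ValueError("enrichment must lie in [0, 1]")


@dataclass(frozen=True)
class PPLTruth:
    fingerprints: Mapping[str, np.ndarray]
    source_class: Mapping[str, str]  # compound name -> profile-donating class
    mechanism_targets: tuple[str, ...]


def generate_ppl_set(
    truth: UniverseTruth, spec: PPLSpec
) -> tuple[list[PPLCompound], PPLTruth]:
    """Labelled PPL compounds whose PPL+ members are enriched for mechanism
    target profiles; PPL- members always carry non-mechanism profiles."""
    mech = tuple(spec.mechanism_targets)
    unknown = set(mech) - set(truth.class_ids)
    if unknown:
        raise ValueError(f"mechanism targets not in universe: {sorted(unknown)}")
    if not mech:
        raise ValueError("at least one mechanism target is required")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    non_mech = [t for t in truth.class_ids if t not in set(mech)]
    if not non_mech:
        raise ValueError("universe has no non-mechanism classes")
    compounds: list[PPLCompound] = []
    fps: dict[str, np.ndarray] = {}
    source: dict[str, str] = {}
    for i in range(spec.n_pos):
        name = f"PPLpos{i:04d}"
        if rng.random() < spec.enrichment:
            tid = mech[int(rng.integers(0, len(mech)))]
        else:
            tid = non_mech[int(rng.integers(0, len(non_mech)))]
        scaffolds = truth.profiles[tid]
        fps[name] = _noisy_copy(
            scaffolds[int(rng.integers(0, len(scaffolds)))], spec.flip_noise, rng
        )
        source[name] = tid
        compounds.append(PPLCompound(name=name, smiles=f"SYN:{name}", label=+1))
    for i in range(spec.n_neg):
        name = f"PPLneg{i:04d}"
        tid = non_mech[int(rng.integers(0, len(non_mech)))]
        scaffolds = truth.profiles[tid]
        fps[name] = _noisy_copy(
            scaffolds[int(rng.integers(0, len(scaffolds)))], spec.flip_noise, rng
        )
        source[name] = tid
        compounds.append(PPLCompound(name=name, smiles=f"SYN:{name}", label=-1))
    return compounds, PPLTruth(fingerprints=fps, source_class=source, mechanism_targets=mech)
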