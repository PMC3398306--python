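"""File formats: activity tables, fingerprint matrices, PPL sets, model dirs.

Everything is plain text: activity records and instance lists are TSV,
fingerprints are hex-encoded bit rows with a JSON sidecar recording the
dimension and hashing parameters, and a model directory is a serialized
association table plus a JSON manifest (model kind, h or pseudocount,
fingerprint settings).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ActivityRecord, AssociationTable
from .ppl import PPLCompound

ACTIVITY_COLUMNS = (
    "compound_id",
    "smiles",
    "target_id",
    "target_name",
    "target_description",
    "measure_kind",
    "value",
    "units",
    "relation",
)


# -- activity tables -----------------------------------------------------
def write_activity_table(records: Sequence[ActivityRecord], path) -> None:
    frame = pd.DataFrame([vars(r) for r in records], columns=list(ACTIVITY_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def read_activity_table(path, column_map: Mapping[str, str] | None = None) -> list[ActivityRecord]:
    """Read a delimited activity export; ``column_map`` renames source columns
    onto the canonical field names (e.g. {"canonical_smiles": "smiles"})."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = set(ACTIVITY_COLUMNS[:-2]) - set(frame.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            ActivityRecord(
                compound_id=row.compound_id,
                smiles=row.smiles,
                target_id=row.target_id,
                target_name=row.target_name,
                target_description=row.target_description,
                measure_kind=row.measure_kind,
                value=float(row.value),
                units=getattr(row, "units", ""),
                relation=getattr(row, "relation", "=") or "=",
            )
        )
    return records


# -- fingerprint matrices ------------------------------------------------
def write_fingerprints(fingerprints: Mapping[str, np.ndarray], path, meta: dict | None = None):
    """Hex-encoded bit rows (one compound per line) + a JSON sidecar."""
    path = Path(path)
    d = None
    with open(path, "w") as fh:
        fh.write("compound_id\tbits_hex\n")
        for cid in sorted(fingerprints):
            bits = np.asarray(fingerprints[cid], dtype=np.uint8)
            if d is None:
                d = len(bits)
            elif len(bits) != d:
                raise ValueError("inconsistent fingerprint dimensions")
            fh.write(f"{cid}\t{np.packbits(bits).tobytes().hex()}\n")
    sidecar = {"d": d, **(meta or {})}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_fingerprints(path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    d = meta["d"]
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            cid, hexbits = line.rstrip("\n").split("\t")
            packed = np.frombuffer(bytes.fromhex(hexbits), dtype=np.uint8)
            out[cid] = np.unpackbits(packed)[:d].astype(np.uint8)
    return out, meta


# -- PPL datasets --------------------------------------------------------
_STATUS = {"PPL+": +1, "PPL-": -1, "PPL−": -1}


def write_ppl_set(compounds: Sequence[PPLCompound], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tSMILES\tstatus\n")
        for c in compounds:
            fh.write(f"{c.name}\t{c.smiles}\t{'PPL+' if c.label > 0 else 'PPL-'}\n")


def read_ppl_set(path) -> list[PPLCompound]:
    """Read a labelled phospholipidosis set (TSV/CSV or .xlsx workbook).

    Expects columns name, SMILES, status with status in {PPL+, PPL-}.
    """
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        frame = pd.read_excel(path, dtype=str)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    need = {"name", "smiles", "status"}
    if not need <= set(frame.columns):
        raise ValueError(f"PPL file must have columns {sorted(need)}, got {list(frame.columns)}")
    out = []
    for row in frame.itertuples(index=False):
        status = str(row.status).strip()
        if status not in _STATUS:
            raise ValueError(f"unknown PPL status {status!r} for {row.name!r}")
        out.append(PPLCompound(name=str(row.name), smiles=str(row.smiles), label=_STATUS[status]))
    return out


# -- association tables & models ----------------------------------------
def save_table(table: AssociationTable, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(table.instances, columns=["compound_id", "class_id"]).to_csv(
        directory / "instances.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(table.class_sizes.items()), columns=["class_id", "n_instances"]
    ).assign(name=lambda f: [table.class_names.get(c, c) for c in f["class_id"]]).to_csv(
        directory / "classes.tsv", sep="\t", index=False
    )
    write_fingerprints(table.fingerprints, directory / "fingerprints.tsv", dict(table.meta))


def load_table(directory) -> AssociationTable:
    directory = Path(directory)
    inst = pd.read_csv(directory / "instances.tsv", sep="\t", dtype=str)
    classes = pd.read_csv(directory / "classes.tsv", sep="\t", dtype=str)
    fps, meta = read_fingerprints(directory / "fingerprints.tsv")
    meta.pop("d", None)
    return AssociationTable(
        instances=tuple(map(tuple, inst.to_numpy())),
        fingerprints=fps,
        class_names=dict(zip(classes["class_id"], classes["name"])),
        meta=meta,
    )


def save_model(model, directory, *, table: AssociationTable | None = None) -> None:
    """Persist a model as its training table + JSON manifest (kind-flagged).

    PRW models carry their table; for an NB model pass the training
    ``table`` explicitly (the fitted frequencies are recomputed on load).
    """
    from .nb import NBModel
    from .prw import PRWModel

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, PRWModel):
        save_table(model.table, directory / "table")
        manifest = {"kind": "prw", "h": model.h, "d": model.d}
    elif isinstance(model, NBModel):
        if table is None:
            raise ValueError("NB persistence needs the training table")
        save_table(table, directory / "table")
        manifest = {"kind": "nb", "pseudocount": model.pseudocount, "d": model.d}
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(directory):
    from .nb import train_nb
    from .prw import PRWModel

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    table = load_table(directory / "table")
    if manifest["kind"] == "prw":
        return PRWModel(table, h=manifest["h"])
    if manifest["kind"] == "nb":
        return train_nb(table, pseudocount=manifest["pseudocount"])
    raise ValueError(f"unsupported model kind {manifest['kind']!r}")
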