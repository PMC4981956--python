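"""Readers and writers for the project's interchange tables and trees.

All tables are comma-separated UTF-8 with a mandatory header row and "."
as the decimal separator. Missing optional measurements are empty cells
and surface as ``None`` ("absent"), never 0. Declared round-trip
precision: lengths 3 decimals (mm), ages 1 decimal (Ma).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import RecordError, SchemaError
from .tree import Phylogeny, from_newick
from .types import (
    CalibrationConstraint,
    SpecimenRecord,
    TendonObservation,
    VertebraMeasurement,
    SPECIMEN_COLUMNS,
    TENDON_COLUMNS,
    VERTEBRA_COLUMNS,
)

PathLike = Union[str, Path]

_OPTIONAL_SPECIMEN = {
    "head_length", "L_head_in_vertebrae", "N_PCV", "N_CV",
    "AR_head", "AR_PCV", "AR_CV",
}
_OPTIONAL_TENDON = {"tl_start", "tl_end", "element_length"}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _cell(row: pd.Series, name: str, optional: bool, row_ix: int, path: PathLike):
    raw = row[name]
    if pd.isna(raw) or (isinstance(raw, str) and raw.strip() == ""):
        if optional:
            return None
        raise RecordError(f"{path} row {row_ix}: required field {name!r} is empty")
    return raw


def _number(raw, name: str, row_ix: int, path: PathLike, integer: bool = False):
    if raw is None:
        return None
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise RecordError(
            f"{path} row {row_ix}: non-numeric value {raw!r} in column {name!r}"
        ) from None
    if not math.isfinite(v):
        raise RecordError(f"{path} row {row_ix}: non-finite value in column {name!r}")
    if integer:
        if v != int(v):
            raise RecordError(
                f"{path} row {row_ix}: column {name!r} must be integral, got {raw!r}"
            )
        return int(v)
    return v


def _read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=True)


# -- specimens -------------------------------------------------------


def read_specimen_table(path: PathLike) -> List[SpecimenRecord]:
    """Read a specimen measurement CSV; one :class:`SpecimenRecord` per row,
    in file order. Raises :class:`SchemaError` for missing columns and
    :class:`RecordError` (naming the row) for bad values."""
    df = _read_table(path)
    _require_columns(df, SPECIMEN_COLUMNS, path)
    records = []
    for ix, row in df.iterrows():
        kwargs = {
            "taxon_id": str(_cell(row, "taxon_id", False, ix, path)),
            "status": str(_cell(row, "status", False, ix, path)),
            "clade": str(_cell(row, "clade", False, ix, path)),
        }
        for name in SPECIMEN_COLUMNS[3:]:
            raw = _cell(row, name, name in _OPTIONAL_SPECIMEN, ix, path)
            kwargs[name] = _number(raw, name, ix, path, integer=name.startswith("N_"))
        records.append(SpecimenRecord(**kwargs))
    return records


def write_specimen_table(records: Sequence[SpecimenRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for k, v in d.items():
            if isinstance(v, float):
                d[k] = round(v, 3)
        rows.append(d)
    pd.DataFrame(rows, columns=SPECIMEN_COLUMNS).to_csv(path, index=False)


# -- vertebrae -------------------------------------------------------


def read_vertebra_table(path: PathLike) -> List[VertebraMeasurement]:
    df = _read_table(path)
    _require_columns(df, VERTEBRA_COLUMNS, path)
    out = []
    seen = set()
    for ix, row in df.iterrows():
        m = VertebraMeasurement(
            taxon_id=str(_cell(row, "taxon_id", False, ix, path)),
            index=_number(_cell(row, "index", False, ix, path), "index", ix, path, True),
            region=str(_cell(row, "region", False, ix, path)),
            centrum_length=_number(
                _cell(row, "centrum_length", False, ix, path), "centrum_length", ix, path
            ),
            centrum_height=_number(
                _cell(row, "centrum_height", False, ix, path), "centrum_height", ix, path
            ),
        )
        key = (m.taxon_id, m.index)
        if key in seen:
            raise RecordError(f"{path} row {ix}: duplicate vertebra index {key}")
        seen.add(key)
        out.append(m)
    return out


def write_vertebra_table(measurements: Sequence[VertebraMeasurement], path: PathLike) -> None:
    rows = []
    for m in measurements:
        d = dataclasses.asdict(m)
        d["centrum_length"] = round(d["centrum_length"], 3)
        d["centrum_height"] = round(d["centrum_height"], 3)
        rows.append(d)
    pd.DataFrame(rows, columns=VERTEBRA_COLUMNS).to_csv(path, index=False)


# -- tendon observations ---------------------------------------------


def read_tendon_table(path: PathLike) -> List[TendonObservation]:
    df = _read_table(path)
    _require_columns(df, TENDON_COLUMNS, path)
    out = []
    for ix, row in df.iterrows():
        kwargs = {
            "taxon_id": str(_cell(row, "taxon_id", False, ix, path)),
            "element": str(_cell(row, "element", False, ix, path)),
            "side": str(_cell(row, "side", False, ix, path)),
        }
        for name in ("k_min", "k_max", "tl_start", "tl_end", "element_length"):
            raw = _cell(row, name, name in _OPTIONAL_TENDON, ix, path)
            kwargs[name] = _number(raw, name, ix, path)
        out.append(TendonObservation(**kwargs))
    return out


def write_tendon_table(observations: Sequence[TendonObservation], path: PathLike) -> None:
    rows = []
    for o in observations:
        d = dataclasses.asdict(o)
        for k, v in d.items():
            if isinstance(v, float):
                d[k] = round(v, 3)
        rows.append(d)
    pd.DataFrame(rows, columns=TENDON_COLUMNS).to_csv(path, index=False)


# -- tip ages and constraints ----------------------------------------


def read_tip_ages(path: PathLike) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Read a taxon -> (first_occurrence, last_occurrence) side table (Ma)."""
    df = _read_table(path)
    _require_columns(df, ["taxon_id", "first_occurrence", "last_occurrence"], path)
    first, last = {}, {}
    for ix, row in df.iterrows():
        tax = str(_cell(row, "taxon_id", False, ix, path))
        first[tax] = _number(
            _cell(row, "first_occurrence", False, ix, path), "first_occurrence", ix, path
        )
        last[tax] = _number(
            _cell(row, "last_occurrence", False, ix, path), "last_occurrence", ix, path
        )
    return first, last


def write_tip_ages(
    first: Dict[str, float], last: Dict[str, float], path: PathLike
) -> None:
    rows = [
        {
            "taxon_id": t,
            "first_occurrence": round(first[t], 1),
            "last_occurrence": round(last.get(t, 0.0), 1),
        }
        for t in first
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_constraints(path: PathLike) -> List[CalibrationConstraint]:
    """Constraint CSV: columns mrca_of (';'-separated tip labels), age, kind."""
    df = _read_table(path)
    _require_columns(df, ["mrca_of", "age", "kind"], path)
    out = []
    for ix, row in df.iterrows():
        labels = [
            s.strip() for s in str(_cell(row, "mrca_of", False, ix, path)).split(";")
            if s.strip()
        ]
        out.append(
            CalibrationConstraint(
                mrca_of=frozenset(labels),
                age=_number(_cell(row, "age", False, ix, path), "age", ix, path),
                kind=str(_cell(row, "kind", False, ix, path)),
            )
        )
    return out


def write_constraints(constraints: Sequence[CalibrationConstraint], path: PathLike) -> None:
    rows = [
        {"mrca_of": ";".join(sorted(c.mrca_of)), "age": round(c.age, 1), "kind": c.kind}
        for c in constraints
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- trees -----------------------------------------------------------


def read_tree(
    path: PathLike,
    tip_ages_path: Optional[PathLike] = None,
    schema: str = "newick",
) -> Phylogeny:
    """Read a Newick (or NEXUS) tree, optionally joining a tip-age side
    table. Polytomies are preserved."""
    text = Path(path).read_text()
    first, last = ({}, {})
    if tip_ages_path is not None:
        first, last = read_tip_ages(tip_ages_path)
    if schema == "newick":
        return from_newick(text, first_occurrence=first, last_occurrence=last)
    import dendropy

    tree = dendropy.Tree.get(data=text, schema=schema, preserve_underscores=True)
    return Phylogeny(tree, first_occurrence=first, last_occurrence=last)


def write_tree(phylogeny: Phylogeny, path: PathLike, include_ages: bool = False) -> None:
    Path(path).write_text(phylogeny.as_newick(include_ages=include_ages) + "\n")
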