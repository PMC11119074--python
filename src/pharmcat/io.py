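"""CSV and JSON input/output.

Two CSV formats are shared by the library and the CLI:

* **assessment CSV** — one row per (trial, rater):
  ``trial_id, centre_id, trial_type, phase, rater_id, item_1 ... item_15``
  (item columns follow the instrument's item ids).
* **score CSV** — one row per (trial, rater):
  ``trial_id, centre_id, trial_type, phase, rater_id, total[, category]``.

Cut-off sets travel as JSON objects ``{"low_max": int, "med_max": int}``.
Parse failures raise :class:`~pharmcat.errors.ParseError` naming the row
(1-based, counting the header as row 1) and column at fault.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .categorization import ComplexityCategory, CutoffSet
from .errors import ParseError
from .instrument import (
    Assessment,
    Instrument,
    ItemResponse,
    Phase,
    TrialType,
    default_instrument,
)

__all__ = [
    "ScoreRecord",
    "read_assessments",
    "write_assessments",
    "read_scores",
    "write_scores",
    "read_cutoffs",
    "write_cutoffs",
]

_META_COLUMNS = ["trial_id", "centre_id", "trial_type", "phase", "rater_id"]


@dataclass(frozen=True)
class ScoreRecord:
    """A scored (trial, rater) row with the trial metadata kept alongside."""

    trial_id: str
    centre_id: str
    trial_type: TrialType
    phase: Phase
    rater_id: str
    total: int
    category: Union[ComplexityCategory, None] = None


def _item_columns(inst: Instrument) -> list[str]:
    return [f"item_{i}" for i in inst.item_ids]


def _parse_enum(enum_cls, raw: str, column: str, row: int):
    try:
        return enum_cls(raw)
    except ValueError:
        valid = "/".join(m.value for m in enum_cls)
        raise ParseError(f"row {row}: invalid {column} {raw!r} (expected {valid})") from None


def _parse_int(raw, column: str, row: int) -> int:
    try:
        f = float(raw)
        i = int(f)
        if i != f:
            raise ValueError
        return i
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: column {column}: non-integer value {raw!r}") from None


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"could not read CSV {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


def read_assessments(path, instrument: Union[Instrument, None] = None) -> list[Assessment]:
    """Read an assessment CSV into :class:`Assessment` records.

    Values are checked field by field; the first offending cell aborts with
    a :class:`ParseError` naming its row and column.  No instrument-level
    validation is done here — use
    :func:`~pharmcat.instrument.validate_assessment` for that.
    """
    inst = instrument or default_instrument()
    df = _read_csv(path)
    item_cols = _item_columns(inst)
    _require_columns(df, _META_COLUMNS + item_cols, path)

    assessments = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is row 1
        trial_type = _parse_enum(TrialType, row["trial_type"], "trial_type", rownum)
        phase = _parse_enum(Phase, row["phase"], "phase", rownum)
        responses = tuple(
            ItemResponse(item_id=item_id, score=_parse_int(row[col], col, rownum))
            for item_id, col in zip(inst.item_ids, item_cols)
        )
        assessments.append(
            Assessment(
                trial_id=row["trial_id"],
                centre_id=row["centre_id"],
                trial_type=trial_type,
                phase=phase,
                rater_id=row["rater_id"],
                responses=responses,
            )
        )
    return assessments


def write_assessments(path, assessments, instrument: Union[Instrument, None] = None) -> None:
    """Write assessments to the standard assessment CSV format."""
    inst = instrument or default_instrument()
    rows = []
    for a in assessments:
        rmap = a.response_map()
        row = {
            "trial_id": a.trial_id,
            "centre_id": a.centre_id,
            "trial_type": a.trial_type.value,
            "phase": a.phase.value,
            "rater_id": a.rater_id,
        }
        row.update({f"item_{i}": rmap[i] for i in inst.item_ids})
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS + _item_columns(inst)).to_csv(path, index=False)


def read_scores(path) -> list[ScoreRecord]:
    """Read a score CSV; the ``category`` column is optional."""
    df = _read_csv(path)
    _require_columns(df, _META_COLUMNS + ["total"], path)
    has_cat = "category" in df.columns
    records = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2
        category = None
        if has_cat and row["category"]:
            try:
                category = ComplexityCategory[row["category"]]
            except KeyError:
                raise ParseError(
                    f"row {rownum}: invalid category {row['category']!r} (expected low/medium/high)"
                ) from None
        records.append(
            ScoreRecord(
                trial_id=row["trial_id"],
                centre_id=row["centre_id"],
                trial_type=_parse_enum(TrialType, row["trial_type"], "trial_type", rownum),
                phase=_parse_enum(Phase, row["phase"], "phase", rownum),
                rater_id=row["rater_id"],
                total=_parse_int(row["total"], "total", rownum),
                category=category,
            )
        )
    return records


def write_scores(path, records) -> None:
    """Write :class:`ScoreRecord` rows to the standard score CSV format."""
    rows = []
    for r in records:
        rows.append(
            {
                "trial_id": r.trial_id,
                "centre_id": r.centre_id,
                "trial_type": r.trial_type.value,
                "phase": r.phase.value,
                "rater_id": r.rater_id,
                "total": r.total,
                "category": "" if r.category is None else r.category.name,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS + ["total", "category"]).to_csv(path, index=False)


def read_cutoffs(path) -> CutoffSet:
    try:
        doc = json.loads(Path(path).read_text("utf-8"))
        return CutoffSet(low_max=int(doc["low_max"]), med_max=int(doc["med_max"]))
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"invalid cutoffs JSON {path}: {exc}") from exc


def write_cutoffs(path, cutoffs: CutoffSet) -> None:
    Path(path).write_text(
        json.dumps({"low_max": cutoffs.low_max, "med_max": cutoffs.med_max}, indent=2) + "\n",
        "utf-8",
    )
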