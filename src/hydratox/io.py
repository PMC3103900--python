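"""Tabular I/O for the four bioassay CSV schemas.

Schemas (one header row, comma separated):

* ``quantal``:    label, axis, value, n_exposed, n_dead, time_hr
* ``scores``:     animal_id, label, dose_nM, time_hr, score
* ``tentacles``:  polyp_id, label, day, c1, c2, c3, c4, c5
* ``population``: replicate_id, label, day, n

``load_table`` validates every row against the record invariants, sorts by
the schema's natural key, and (for quantal tables) pools duplicate doses
within a series by summing counts.  ``write_results`` serialises stage
outputs to CSV or JSON with full float precision so that a written file
reloads to identical values.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .records import (
    AXIS_DOSE,
    AXIS_TIME,
    DoseGroup,
    MorphologyRecord,
    PopulationCount,
    QuantalSeries,
    SchemaError,
    TentacleProfile,
    ValidationError,
    pool_duplicates,
)

SCHEMAS = {
    "quantal": ["label", "axis", "value", "n_exposed", "n_dead", "time_hr"],
    "scores": ["animal_id", "label", "dose_nM", "time_hr", "score"],
    "tentacles": ["polyp_id", "label", "day", "c1", "c2", "c3", "c4", "c5"],
    "population": ["replicate_id", "label", "day", "n"],
}


def _read_csv(path, schema: str) -> pd.DataFrame:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    unknown = [c for c in df.columns if c not in SCHEMAS[schema]]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown} for schema {schema!r}")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty data section")
    return df


def load_table(path, schema: str):
    """Load and validate a bioassay CSV.

    Returns records of the schema's type: a list of :class:`QuantalSeries`
    (one per label/axis/time combination, pooled and dose-sorted) for
    ``quantal``; lists of :class:`MorphologyRecord`, :class:`TentacleProfile`
    or :class:`PopulationCount` for the other schemas.  Row numbers in error
    messages refer to data rows (header = row 0).
    """
    df = _read_csv(path, schema)
    loader = {
        "quantal": _load_quantal,
        "scores": _load_scores,
        "tentacles": _load_tentacles,
        "population": _load_population,
    }[schema]
    return loader(df)


def _row_error(schema: str, idx: int, exc: Exception) -> ValidationError:
    return ValidationError(f"{schema} row {idx + 1}: {exc}")


def _load_quantal(df: pd.DataFrame) -> list[QuantalSeries]:
    groups: dict[tuple, list[DoseGroup]] = {}
    for idx, row in df.iterrows():
        axis = str(row["axis"])
        if axis not in (AXIS_DOSE, AXIS_TIME):
            raise _row_error("quantal", idx, ValueError(f"axis must be dose/time, got {axis!r}"))
        time_hr = row["time_hr"]
        time_val = None if pd.isna(time_hr) else float(time_hr)
        try:
            if axis == AXIS_DOSE:
                g = DoseGroup(
                    dose=float(row["value"]),
                    n_exposed=int(row["n_exposed"]),
                    n_dead=int(row["n_dead"]),
                    time=time_val,
                )
            else:
                # time-axis rows: `value` is the fixed dose, time_hr the ordinate
                if time_val is None:
                    raise ValidationError("time-axis rows need time_hr")
                g = DoseGroup(
                    dose=float(row["value"]),
                    n_exposed=int(row["n_exposed"]),
                    n_dead=int(row["n_dead"]),
                    time=time_val,
                )
        except ValidationError as exc:
            raise _row_error("quantal", idx, exc) from exc
        key = (str(row["label"]), axis, time_val if axis == AXIS_DOSE else float(row["value"]))
        groups.setdefault(key, []).append(g)
    out = []
    for (label, axis, _), glist in sorted(groups.items(), key=lambda kv: str(kv[0])):
        pooled = pool_duplicates(glist, axis=axis)
        out.append(QuantalSeries(groups=tuple(pooled), axis=axis, label=label))
    return out


def _load_scores(df: pd.DataFrame) -> list[MorphologyRecord]:
    records = []
    for idx, row in df.iterrows():
        score = row["score"]
        try:
            if float(score) != int(score):
                raise ValidationError(f"score must be an integer in 1..10, got {score}")
            records.append(
                MorphologyRecord(
                    animal_id=str(row["animal_id"]),
                    dose=float(row["dose_nM"]),
                    time=float(row["time_hr"]),
                    score=int(score),
                    label=str(row["label"]),
                )
            )
        except ValidationError as exc:
            raise _row_error("scores", idx, exc) from exc
    records.sort(key=lambda r: (r.label, r.dose, r.time, r.animal_id))
    return records


def _load_tentacles(df: pd.DataFrame) -> list[TentacleProfile]:
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                TentacleProfile(
                    polyp_id=str(row["polyp_id"]),
                    day=float(row["day"]),
                    counts=tuple(int(row[f"c{k}"]) for k in range(1, 6)),
                    label=str(row["label"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise _row_error("tentacles", idx, exc) from exc
    records.sort(key=lambda r: (r.label, r.polyp_id, r.day))
    return records


def _load_population(df: pd.DataFrame) -> list[PopulationCount]:
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PopulationCount(
                    replicate_id=str(row["replicate_id"]),
                    day=int(row["day"]),
                    n=int(row["n"]),
                    label=str(row["label"]),
                )
            )
        except ValidationError as exc:
            raise _row_error("population", idx, exc) from exc
    records.sort(key=lambda r: (r.label, r.replicate_id, r.day))
    return records


def quantal_to_frame(series_list) -> pd.DataFrame:
    """Render QuantalSeries back into the quantal CSV schema."""
    rows = []
    for s in series_list:
        for g in s.groups:
            value = g.dose if s.axis == AXIS_DOSE else g.dose
            rows.append(
                {
                    "label": s.label,
                    "axis": s.axis,
                    "value": value,
                    "n_exposed": g.n_exposed,
                    "n_dead": g.n_dead,
                    "time_hr": g.time,
                }
            )
    return pd.DataFrame(rows, columns=SCHEMAS["quantal"])


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_results(results: Any, path, format: str = "json",
                  metadata: Optional[dict] = None) -> None:
    """Write a stage output to ``path`` as CSV or JSON.

    JSON output wraps the payload in ``{"metadata": ..., "results": ...}``
    so that the analysis parameters (trim, confidence, seed) travel with the
    numbers.  Floats are written at full (shortest round-trip) precision.
    """
    path = Path(path)
    if format == "json":
        payload = {"metadata": _jsonable(metadata or {}), "results": _jsonable(results)}
        path.write_text(json.dumps(payload, indent=2, allow_nan=False) + "\n")
    elif format == "csv":
        if isinstance(results, pd.DataFrame):
            df = results
        else:
            rows = [
                dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in results
            ]
            df = pd.DataFrame(rows)
        df.to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown output format {format!r}; expected csv or json")


def read_results(path) -> dict:
    """Read back a JSON result envelope written by :func:`write_results`."""
    with open(path) as fh:
        return json.load(fh)
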