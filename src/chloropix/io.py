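"""CSV and JSON interchange for calibration data and fitted curves.

Calibration points travel as CSV with columns ``sample_id, pigment, chl,
gpi_final`` and optional per-photo replicates ``gpi_rep1..gpi_rep3``.
Fitted curves are stored as a JSON artifact holding one record per pigment
plus provenance (input hash, seed, tool version, timestamp); that file is
what the predict and compare commands consume.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import CalibrationCurve, CalibrationPoint
from .errors import ValidationError

__all__ = [
    "read_points_csv",
    "write_points_csv",
    "save_curves",
    "load_curves",
    "sha256_of",
]

_REP_COLS = ("gpi_rep1", "gpi_rep2", "gpi_rep3")


def read_points_csv(path: str | Path) -> dict[str, list[CalibrationPoint]]:
    """Read calibration points grouped by pigment."""
    df = pd.read_csv(path)
    required = {"sample_id", "chl", "gpi_final"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"points CSV {path} missing columns: {sorted(missing)}")
    if "pigment" not in df.columns:
        df["pigment"] = "total"
    has_reps = all(c in df.columns for c in _REP_COLS)
    out: dict[str, list[CalibrationPoint]] = {}
    for row in df.itertuples():
        reps = None
        if has_reps:
            vals = [getattr(row, c) for c in _REP_COLS]
            if all(pd.notna(v) for v in vals):
                reps = tuple(float(v) for v in vals)
        out.setdefault(str(row.pigment), []).append(
            CalibrationPoint(
                sample_id=str(row.sample_id),
                chl=float(row.chl),
                gpi_final=float(row.gpi_final),
                pigment=str(row.pigment),
                replicate_gpis=reps,
            )
        )
    return out


def write_points_csv(
    path: str | Path, points: Sequence[CalibrationPoint]
) -> None:
    rows = []
    for p in points:
        row = {
            "sample_id": p.sample_id,
            "pigment": p.pigment,
            "chl": p.chl,
            "gpi_final": p.gpi_final,
        }
        if p.replicate_gpis is not None:
            row.update(dict(zip(_REP_COLS, p.replicate_gpis)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def save_curves(
    path: str | Path,
    curves: dict[str, CalibrationCurve],
    provenance: dict | None = None,
) -> None:
    doc = {
        "format": "chloropix-calibration/1",
        "provenance": {
            "created_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            **(provenance or {}),
        },
        "curves": {pig: c.to_dict() for pig, c in curves.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_curves(path: str | Path) -> dict[str, CalibrationCurve]:
    try:
        doc = json.loads(Path(path).read_text())
        return {
            pig: CalibrationCurve.from_dict(d) for pig, d in doc["curves"].items()
        }
    except (KeyError, json.JSONDecodeError) as exc:
        raise ValidationError(f"malformed calibration artifact {path}: {exc}") from exc
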