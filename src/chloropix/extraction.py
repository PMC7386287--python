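"""Reference chlorophyll quantification by solvent extraction.

Chlorophyll a and b concentrations of the original culture are computed
from extract absorbances at 663.6 and 646.6 nm (each corrected by the
750 nm turbidity reading) using the extinction-coefficient equations for
80% (v/v) acetone / 20% methanol:

    Chl a     (ug/ml) = (12.25 E663.6 -  2.55 E646.6) * V_extract / V_culture
    Chl b     (ug/ml) = (20.31 E646.6 -  4.91 E663.6) * V_extract / V_culture
    Chl a + b (ug/ml) = (17.76 E646.6 +  7.34 E663.6) * V_extract / V_culture

The total coefficients are exactly the sums of the a and b coefficients
(12.25 - 4.91 = 7.34 and 20.31 - 2.55 = 17.76), so chl_total == chl_a +
chl_b identically.  The extract volume defaults to 1 ml, which reduces the
expressions to the usual "divide by sample volume" form.

The exact inverse (two-by-two linear solve) is also provided so synthetic
fixtures can generate absorbances from target concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "AbsorbanceTriple",
    "ChlorophyllResult",
    "chlorophyll_from_absorbance",
    "absorbance_from_chlorophyll",
    "chlorophyll_table",
    "read_absorbance_csv",
]

# Rows: (chl a, chl b); columns: (E663.6, E646.6).
_COEF = np.array([[12.25, -2.55], [-4.91, 20.31]])
_COEF_TOTAL = (7.34, 17.76)  # (E663.6, E646.6); equals the column sums of _COEF
_DET = float(np.linalg.det(_COEF))  # 236.277, never singular


@dataclass(frozen=True)
class AbsorbanceTriple:
    """One spectrophotometer record for a chlorophyll extract."""

    a663_6: float
    a646_6: float
    a750: float = 0.0
    culture_volume_ml: float = 1.0
    extract_volume_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.culture_volume_ml <= 0 or self.extract_volume_ml <= 0:
            raise ValidationError(
                f"volumes must be positive, got culture={self.culture_volume_ml} ml, "
                f"extract={self.extract_volume_ml} ml"
            )

    @property
    def e663_6(self) -> float:
        """Turbidity-corrected absorbance at 663.6 nm."""
        return self.a663_6 - self.a750

    @property
    def e646_6(self) -> float:
        """Turbidity-corrected absorbance at 646.6 nm."""
        return self.a646_6 - self.a750


@dataclass(frozen=True)
class ChlorophyllResult:
    """Pigment concentrations of the original culture, in ug/ml."""

    chl_a: float
    chl_b: float
    chl_total: float


def chlorophyll_from_absorbance(t: AbsorbanceTriple) -> ChlorophyllResult:
    """Apply the extinction-coefficient equations to one absorbance record.

    Warns (without aborting) when a raw absorbance exceeds 1.00 — the
    protocol dilutes extracts to stay below that — or when a corrected
    absorbance is negative, which happens for noisy near-blank extracts.
    """
    if max(t.a663_6, t.a646_6) >= 1.00:
        warnings.warn(
            "absorbance >= 1.00: dilute the extract (working range is < 1.00)",
            stacklevel=2,
        )
    e = np.array([t.e663_6, t.e646_6])
    if (e < 0).any():
        warnings.warn(
            "corrected absorbance negative after 750 nm subtraction; "
            "proceeding (near-blank extract)",
            stacklevel=2,
        )
    scale = t.extract_volume_ml / t.culture_volume_ml
    chl_a, chl_b = (_COEF @ e) * scale
    chl_total = (_COEF_TOTAL[0] * e[0] + _COEF_TOTAL[1] * e[1]) * scale
    return ChlorophyllResult(float(chl_a), float(chl_b), float(chl_total))


def absorbance_from_chlorophyll(
    chl_a: float,
    chl_b: float,
    culture_volume_ml: float = 1.0,
    extract_volume_ml: float = 1.0,
) -> AbsorbanceTriple:
    """Exact inverse of :func:`chlorophyll_from_absorbance` (a750 = 0).

    Solves the two-by-two extinction system for the corrected absorbances
    that reproduce the requested concentrations.
    """
    scale = extract_volume_ml / culture_volume_ml
    e = np.linalg.solve(_COEF, np.array([chl_a, chl_b]) / scale)
    return AbsorbanceTriple(
        a663_6=float(e[0]),
        a646_6=float(e[1]),
        a750=0.0,
        culture_volume_ml=culture_volume_ml,
        extract_volume_ml=extract_volume_ml,
    )


def read_absorbance_csv(path: str | Path) -> pd.DataFrame:
    """Read absorbance records; see :func:`chlorophyll_table` for columns."""
    df = pd.read_csv(path)
    required = {"sample_id", "a663_6", "a646_6"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"absorbance CSV missing columns: {sorted(missing)}")
    if "a750" not in df.columns:
        df["a750"] = 0.0
    if "culture_volume_ml" not in df.columns:
        df["culture_volume_ml"] = 1.0
    if "extract_volume_ml" not in df.columns:
        df["extract_volume_ml"] = 1.0
    return df


def chlorophyll_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised conversion of an absorbance table to concentrations.

    Input columns: sample_id, a663_6, a646_6 [, a750, culture_volume_ml,
    extract_volume_ml].  Returns the input plus chl_a, chl_b, chl_total.
    """
    out = df.copy()
    results = [
        chlorophyll_from_absorbance(
            AbsorbanceTriple(
                a663_6=row.a663_6,
                a646_6=row.a646_6,
                a750=getattr(row, "a750", 0.0),
                culture_volume_ml=getattr(row, "culture_volume_ml", 1.0),
                extract_volume_ml=getattr(row, "extract_volume_ml", 1.0),
            )
        )
        for row in df.itertuples()
    ]
    out["chl_a"] = [r.chl_a for r in results]
    out["chl_b"] = [r.chl_b for r in results]
    out["chl_total"] = [r.chl_total for r in results]
    return out
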