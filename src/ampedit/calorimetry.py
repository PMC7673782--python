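"""Indirect-calorimetry derivations from VO2/VCO2 time series.

Closed-form formulas, applied elementwise to measurements already
normalized to metabolic body mass (kg^0.75):

    RER               = VCO2 / VO2
    energy expenditure (kcal/day/kg^0.75)
                      = 1.44 * VO2 * (3.815 + 1.232 * RER)
    glucose oxidation (g/min/kg^0.75)
                      = (4.545 * VCO2 - 3.205 * VO2) / 1000
    lipid oxidation   (g/min/kg^0.75)
                      = 1.672 * (VO2 - VCO2) / 1000

Negative oxidation values are physiologically suspect but are preserved
as-is and flagged, never clipped.  Units are carried as labels only; no
conversion is attempted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

ArrayLike = "float | np.ndarray | pd.Series"


def rer(vco2, vo2):
    """Respiratory exchange ratio VCO2/VO2; requires VO2 > 0."""
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 <= 0):
        raise ValueError("VO2 must be positive to compute RER")
    out = np.asarray(vco2, dtype=float) / vo2
    return out.item() if out.ndim == 0 else out


def energy_expenditure(vo2, rer_value):
    """Energy expenditure, kcal/day/kg^0.75."""
    out = 1.44 * np.asarray(vo2, float) * (3.815 + 1.232 * np.asarray(rer_value, float))
    return out.item() if out.ndim == 0 else out


def glucose_oxidation(vo2, vco2):
    """Glucose oxidation, g/min/kg^0.75; may be negative (flagged downstream)."""
    out = (4.545 * np.asarray(vco2, float) - 3.205 * np.asarray(vo2, float)) / 1000.0
    return out.item() if out.ndim == 0 else out


def lipid_oxidation(vo2, vco2):
    """Lipid oxidation, g/min/kg^0.75; zero exactly at RER = 1."""
    out = 1.672 * (np.asarray(vo2, float) - np.asarray(vco2, float)) / 1000.0
    return out.item() if out.ndim == 0 else out


RER_WARN_RANGE = (0.6, 1.3)


def derive(table: pd.DataFrame) -> pd.DataFrame:
    """Add all derived quantities to a table with ``vo2``/``vco2`` columns.

    Adds ``rer``, ``energy_expenditure``, ``glucose_oxidation``,
    ``lipid_oxidation``, plus ``negative_oxidation`` flagging rows where
    either oxidation rate is negative, and ``rer_out_of_range`` for RER
    outside [0.6, 1.3].
    """
    out = table.copy()
    out["rer"] = rer(out["vco2"], out["vo2"])
    out["energy_expenditure"] = energy_expenditure(out["vo2"], out["rer"])
    out["glucose_oxidation"] = glucose_oxidation(out["vo2"], out["vco2"])
    out["lipid_oxidation"] = lipid_oxidation(out["vo2"], out["vco2"])
    out["negative_oxidation"] = (
        (out["glucose_oxidation"] < 0) | (out["lipid_oxidation"] < 0)
    )
    out["rer_out_of_range"] = (out["rer"] < RER_WARN_RANGE[0]) | (
        out["rer"] > RER_WARN_RANGE[1]
    )
    return out


def derive_tsv(in_path: str | Path, out_path: str | Path) -> pd.DataFrame:
    """Read a VO2/VCO2 TSV, derive all quantities, write and return them."""
    table = pd.read_csv(in_path, sep="\t")
    out = derive(table)
    out.to_csv(out_path, sep="\t", index=False)
    return out
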