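"""NMR conformational-shift analysis for short peptides.

Conformational (secondary) chemical shifts Δδ = δ_obs − δ_random-coil of
Hα protons report on backbone structure: upfield (negative) Hα shifts
indicate helix. Residues with |Δδ| ≤ 0.1 ppm are within the commonly
accepted random-coil range. The helical population of a residue window is
estimated from the mean of the negative Δδ values relative to the mean
shift of fully formed helices (−0.39 ppm).

Shift tables use pandas DataFrames with columns:

    residue_index  int   (full-length p53 numbering, e.g. 17..29)
    residue_code   str   (one-letter; lower case or 'pS'/'pT' style allowed)
    atom           str   ('HA', 'HN', ...)
    delta_obs_ppm  float
    delta_rc_ppm   float (random-coil reference, caller supplied)
    phospho        bool  (optional)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .constants import FULL_HELIX_SHIFT_PPM, RANDOM_COIL_THRESHOLD_PPM

__all__ = [
    "SHIFT_COLUMNS",
    "validate_shift_table",
    "conformational_shifts",
    "classify_random_coil",
    "helix_percent_from_shifts",
    "phospho_downfield_report",
]

SHIFT_COLUMNS = ("residue_index", "residue_code", "atom",
                 "delta_obs_ppm", "delta_rc_ppm")


def validate_shift_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and (residue, atom) uniqueness."""
    missing = [c for c in SHIFT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"shift table missing columns: {missing}")
    dup = table.duplicated(subset=["residue_index", "atom"])
    if dup.any():
        raise ValueError("duplicate (residue_index, atom) rows in shift table")
    if "phospho" not in table.columns:
        table = table.assign(phospho=False)
    return table


def conformational_shifts(table: pd.DataFrame, atom: str = "HA") -> pd.DataFrame:
    """Per-residue Δδ = δ_obs − δ_RC for one atom type.

    Rows with a missing random-coil reference are kept and flagged
    (``missing_reference=True``, Δδ=NaN), never silently dropped.
    """
    table = validate_shift_table(table)
    sub = table[table["atom"] == atom].copy()
    sub["delta_delta_ppm"] = sub["delta_obs_ppm"] - sub["delta_rc_ppm"]
    sub["missing_reference"] = sub["delta_rc_ppm"].isna()
    sub.loc[sub["missing_reference"], "delta_delta_ppm"] = np.nan
    return sub.set_index("residue_index")[
        ["residue_code", "atom", "delta_delta_ppm", "phospho",
         "missing_reference"]
    ]


def classify_random_coil(shifts: pd.DataFrame | pd.Series,
                         threshold_ppm: float = RANDOM_COIL_THRESHOLD_PPM
                         ) -> pd.Series:
    """Boolean per residue: |Δδ| ≤ threshold (boundary inclusive)."""
    dd = shifts["delta_delta_ppm"] if isinstance(shifts, pd.DataFrame) else shifts
    return dd.abs() <= threshold_ppm


def helix_percent_from_shifts(shifts: pd.DataFrame | pd.Series,
                              window: tuple[int, int] | None = None,
                              full_helix_ppm: float = FULL_HELIX_SHIFT_PPM
                              ) -> float:
    """Helix percentage for a residue window from negative Hα shifts.

    Only the negative Δδ values inside the window enter the mean (positive
    shifts are excluded outright, not zeroed); the mean is divided by the
    full-helix reference shift. Returns 0 when no negative shift exists.
    Percentages are clamped to [0, 100] with a warning.
    """
    dd = shifts["delta_delta_ppm"] if isinstance(shifts, pd.DataFrame) else shifts
    if window is not None:
        lo, hi = window
        dd = dd.loc[(dd.index >= lo) & (dd.index <= hi)]
    if dd.empty:
        raise ValueError("empty residue window")
    neg = dd[dd < 0]
    if neg.empty:
        return 0.0
    pct = 100.0 * neg.mean() / full_helix_ppm
    if pct > 100.0:
        warnings.warn("helix percentage clamped to 100", stacklevel=2)
        return 100.0
    if pct < 0.0:
        warnings.warn("helix percentage clamped to 0", stacklevel=2)
        return 0.0
    return float(pct)


def phospho_downfield_report(table: pd.DataFrame) -> pd.DataFrame:
    """Check the downfield NH tendency of phosphorylated residues.

    For every phospho-flagged residue with an HN row, reports whether
    δ_obs(HN) − δ_RC(HN) > 0 (downfield shift), the qualitative signature
    used to confirm phosphorylation. No quantitative threshold is applied.
    """
    table = validate_shift_table(table)
    sub = table[(table["atom"] == "HN") & table["phospho"]].copy()
    sub["downfield"] = (sub["delta_obs_ppm"] - sub["delta_rc_ppm"]) > 0
    return sub.set_index("residue_index")[["residue_code", "downfield"]]
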