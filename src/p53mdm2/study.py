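"""Measured biophysical parameters of the p53(17-29)/MDM2 peptide study.

These are the printed experimental inputs the package's derived
quantities are recomputed from: per-peptide TFE-titration parameters and
[Θ]222 values (CD, 5 °C), pseudo-first-order rate constants
(stopped-flow, 15 °C), fluorescence-titration dissociation constants,
and calorimetric ΔH / log K_A (ITC, 15 °C). NaN marks quantities that
could not be determined for that peptide (flat TFE curves, no
exponential behaviour, no measurable ITC heat).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["helicity_table", "kinetics_table", "itc_table"]

_HELICITY_CSV = """\
peptide,tfe_half_percent,tfe_half_err,m_value,m_err,helix_pct_tfe,helix_pct_tfe_err,mre222,helix_pct_mre,helix_pct_remd,sigmoidal
P53-WT,7,7,130,50,16,3,-2741,8.7,7,True
P53-pTpS,,,,,,,-2547,8.1,2.1,False
P53-pT,,,,,,,-3213,10.2,2,False
P53-pS,,,,,,,-4614,14.6,15,False
P53-E18,14,5,103,42,7,1,-2380,7.5,2.8,True
P53-D20,25,3,74,32,4,2,-2811,9,7.6,True
P53-E18-D20,15,1,135,18,3,1,-2100,6.6,6.7,True
P53-E18-D20-E24-E25,,,,,,,142.7,0,,False
P53-E18-E20,24.5,0.9,420,390,1,10,-2757,8.7,5,True
P53-D18,12.0,0.7,383,142,1,10,-3313,10.5,2.5,True
P53-E20,25,2,231,141,1,10,-2911,9.2,10,True
P53-D18-E20,33,5,112,70,1,10,-3597,11.4,6,True
P53-D18-D20,9.8,0.8,263,47,1,10,-2811,9,4.7,True
"""

_KINETICS_CSV = """\
peptide,kon_1e6,kon_1e6_err,koff,koff_err,kd_kinetic_uM,kd_kinetic_err,kd_fluor_uM,kd_fluor_err
P53-WT,1.6,0.1,9.0,0.3,5.5,0.5,3.0,1.2
P53-E18,3.8,0.7,16,2,4.2,0.9,2.3,0.6
P53-D20,9.5,0.9,7,2,0.7,0.2,1.5,0.4
P53-E18-D20,4,2,18,6,4.0,3.0,8.3,4.9
P53-E18-D20-E24-E25,,,,,,,,
P53-E18-E20,2.7,0.9,17,2,6,2,,
P53-D18,5,3,23,9,5.0,3.0,,
P53-E20,9,2,8,5,0.9,0.6,0.7,0.1
P53-D18-E20,8,2,13,4,1.6,0.6,3.2,0.9
P53-D18-D20,11,4,20,11,1.8,1.2,,
P53-pS,3.3,0.8,5,1,1.6,0.6,0.3,0.1
P53-pT,2.8,1.6,20,3,7.0,4.0,3.0,1.6
P53-pTpS,1.9,1.1,11,2,5.7,3.5,2.5,0.9
"""

_ITC_CSV = """\
peptide,dH_kcal,log10_KA,kd_uM,TdS_kcal
P53-WT,-10.07,5.73,1.8,-3.23
P53-E18,-7.02,5.15,7.1,-0.26
P53-D20,-10.24,5.24,5.7,-3.36
P53-E18-D20,-8.80,4.69,20.4,-2.64
P53-E18-D20-E24-E25,,,,
P53-E18-E20,-9.12,5.30,5.0,-2.16
P53-D18,-18.39,4.72,19.0,-12.19
P53-E20,,,,
P53-D18-E20,-9.90,5.23,5.9,-3.03
P53-D18-D20,-9.95,4.56,27.5,-3.96
P53-pS,-9.73,5.71,1.9,-2.26
P53-pT,-6.83,4.60,25.1,-0.79
P53-pTpS,-4.81,4.60,25.1,1.23
"""


def _load(csv: str) -> pd.DataFrame:
    df = pd.read_csv(StringIO(csv))
    return df.set_index("peptide")


def helicity_table() -> pd.DataFrame:
    """CD helicity measurements: TFE-titration parameters, [Θ]222-derived
    helix percentages, and simulated (REMD) helicities. Rows with
    ``sigmoidal=False`` had flat TFE curves from which no free energy
    could be extracted."""
    df = _load(_HELICITY_CSV)
    df["sigmoidal"] = df["sigmoidal"].astype(bool)
    return df


def kinetics_table() -> pd.DataFrame:
    """Stopped-flow rate constants (kon in 1e6 M⁻¹s⁻¹, koff in s⁻¹),
    kinetic K_d = koff/kon and fluorescence-titration K_d (μM). The
    quadruple mutant showed no exponential behaviour."""
    return _load(_KINETICS_CSV)


def itc_table() -> pd.DataFrame:
    """Calorimetric ΔH (kcal/mol), log10 K_A (with K_d in μM) and TΔS
    (kcal/mol) at 15 °C."""
    return _load(_ITC_CSV)
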