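"""Study pipeline: orchestrate all analysis stages over a peptide panel.

The pipeline regenerates, for every peptide with measured parameters,
synthetic experiments at the study conditions (TFE titrations at 5 °C,
stopped-flow series at 1-3 μM MDM2 with 0.125 μM peptide, fluorescence
titrations of 0-10 μM peptide into 4 μM MDM2, ITC at 15 °C), refits them
with the corresponding analysis modules, and assembles per-peptide report
tables: a helicity table, a kinetics table and a calorimetry table. It
also cross-checks the kinetic-ratio K_d against the calorimetric K_d and
flags peptides whose two estimates disagree beyond propagated error —
the signature of a binding mechanism with more than one step.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding, cd, itc, kinetics, study, synthetic
from .constants import (FULL_HELIX_SHIFT_PPM, MRE_FULL_HELIX,
                        RANDOM_COIL_THRESHOLD_PPM, T_BINDING_K, T_CD_K)
from .datatypes import RateSeries
from .peptides import PEPTIDES
from .synthetic import GroundTruth, ITCSchedule, Kind

__all__ = ["StudyConfig", "run_pipeline"]


@dataclass
class StudyConfig:
    """Pipeline configuration: peptide panel, temperatures and seeds."""

    peptides: dict[str, str] = field(default_factory=lambda: dict(PEPTIDES))
    temperature_cd_K: float = T_CD_K
    temperature_binding_K: float = T_BINDING_K
    mre_full_helix: float = MRE_FULL_HELIX
    full_helix_shift_ppm: float = FULL_HELIX_SHIFT_PPM
    random_coil_threshold_ppm: float = RANDOM_COIL_THRESHOLD_PPM
    seed: int = 0
    noise_tfe: float = 150.0       # deg cm2 dmol-1, on [Θ]222
    noise_trace: float = 0.005     # fluorescence units (amplitude ~1)
    noise_fluor: float = 0.01
    noise_itc: float = 0.05        # μcal
    mdm2_total_M: float = 4e-6
    peptide_conc_M: float = 0.125e-6
    mdm2_grid_M: tuple = (1e-6, 1.5e-6, 2e-6, 2.5e-6, 3e-6)
    data_files: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature_cd_K <= 0 or self.temperature_binding_K <= 0:
            raise ValueError("temperatures must be positive")
        missing = [p for p in self.data_files.values()
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"configured data files not found: "
                                    f"{missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError("config must be a mapping")
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mdm2_grid_M" in payload:
            payload["mdm2_grid_M"] = tuple(payload["mdm2_grid_M"])
        return cls(**payload)


def _peptide_seed(base: int, name: str, stage: int) -> int:
    # stable small seed per (peptide, stage), independent of dict order
    h = sum((i + 1) * ord(c) for i, c in enumerate(name))
    return (base * 10_007 + h * 101 + stage) % (2**31 - 1)


def _helicity_stage(cfg: StudyConfig, name: str,
                    row: pd.Series) -> dict[str, float | bool | None]:
    out: dict[str, float | bool | None] = {
        "helix_pct_mre": cd.helix_percent_from_mre(
            row["mre222"], full_helix=cfg.mre_full_helix)
        if np.isfinite(row["mre222"]) else None,
    }
    if not row["sigmoidal"] or not np.isfinite(row["tfe_half_percent"]):
        out.update(sigmoidal=False, tfe_half_percent=None, m_value=None,
                   dG_water=None, helix_pct_tfe=None)
        return out
    dG = row["tfe_half_percent"] * row["m_value"]
    truth = GroundTruth(
        kind=Kind.TFE_TITRATION,
        params={"dG_water": dG, "m_value": row["m_value"],
                "theta_coil": -2000.0, "theta_helix": -30000.0,
                "temperature_K": cfg.temperature_cd_K},
        noise_sd=cfg.noise_tfe, seed=_peptide_seed(cfg.seed, name, 1))
    curve = synthetic.generate_tfe_titration(truth, np.linspace(0, 60, 25))
    fit = cd.fit_tfe_titration(curve, temperature_K=cfg.temperature_cd_K)
    out.update(
        sigmoidal=fit.sigmoidal,
        tfe_half_percent=fit.tfe_half_percent,
        m_value=fit.m_value,
        dG_water=fit.dG_water,
        helix_pct_tfe=(100.0 * fit.helix_fraction_water
                       if fit.helix_fraction_water is not None else None))
    return out


def _kinetics_stage(cfg: StudyConfig, name: str,
                    row: pd.Series) -> dict[str, float | None]:
    if not np.isfinite(row["kon_1e6"]):
        return {"kon_1e6": None, "koff": None, "kd_kinetic_uM": None,
                "kd_kinetic_err_uM": None}
    kon = row["kon_1e6"] * 1e6
    koff = row["koff"]
    kobs_list, err_list = [], []
    for j, conc in enumerate(cfg.mdm2_grid_M):
        truth = GroundTruth(
            kind=Kind.KINETIC_TRACE,
            params={"kobs": kon * conc + koff, "amplitude": 1.0,
                    "offset": 0.2, "mdm2_conc_M": conc,
                    "peptide_conc_M": cfg.peptide_conc_M},
            noise_sd=cfg.noise_trace,
            seed=_peptide_seed(cfg.seed, name, 10 + j))
        kobs_expected = truth.params["kobs"]
        t = np.linspace(0.0, 5.0 / kobs_expected, 200)[1:]
        trace = synthetic.generate_kinetic_trace(truth, t)
        fit = kinetics.fit_single_exponential(trace)
        kobs_list.append(fit.kobs_s)
        err_list.append(fit.errors["kobs"])
    series = RateSeries(mdm2_conc_M=np.asarray(cfg.mdm2_grid_M),
                        kobs_s=np.asarray(kobs_list),
                        kobs_err=np.asarray(err_list))
    rate_fit = kinetics.fit_pseudo_first_order(series)
    kd, kd_err = kinetics.kd_from_rates(rate_fit)
    return {"kon_1e6": rate_fit.kon / 1e6, "koff": rate_fit.koff,
            "kd_kinetic_uM": kd * 1e6, "kd_kinetic_err_uM": kd_err * 1e6}


def _binding_stage(cfg: StudyConfig, name: str,
                   row: pd.Series) -> dict[str, float | None]:
    if not np.isfinite(row["kd_fluor_uM"]):
        return {"kd_fluor_uM": None}
    truth = GroundTruth(
        kind=Kind.FLUOR_TITRATION,
        params={"Kd": row["kd_fluor_uM"] * 1e-6, "F0": 1.0, "dFmax": 0.5,
                "MDM2_total": cfg.mdm2_total_M},
        noise_sd=cfg.noise_fluor, seed=_peptide_seed(cfg.seed, name, 2))
    curve = synthetic.generate_fluor_titration(
        truth, np.linspace(0.0, 10e-6, 16))
    fit = binding.fit_quadratic_binding(curve, mdm2_total=cfg.mdm2_total_M)
    return {"kd_fluor_uM": fit.Kd * 1e6}


def _itc_stage(cfg: StudyConfig, name: str,
               row: pd.Series) -> dict[str, float | None]:
    if not np.isfinite(row["log10_KA"]):
        return {"dH_kcal": None, "log10_KA": None, "kd_itc_uM": None,
                "dG_kcal": None, "TdS_kcal": None, "n": None}
    ka = 10.0 ** row["log10_KA"]
    truth = GroundTruth(
        kind=Kind.ITC_HEATS,
        params={"KA": ka, "dH": row["dH_kcal"],
                "n": 1.0, "dilution_heat": -0.15},
        noise_sd=cfg.noise_itc, seed=_peptide_seed(cfg.seed, name, 3))
    # weak binders need more material: keep the Wiseman c-value ~15 so
    # the titration saturates and the dilution plateau exists
    cell = max(20e-6, 15.0 / ka)
    exp = synthetic.generate_itc_heats(
        truth, ITCSchedule(temperature_K=cfg.temperature_binding_K,
                           cell_conc_M=cell, syringe_conc_M=20.0 * cell))
    corrected, _ = itc.dilution_correct(exp.heats_ucal)
    # float a residual offset: the plateau still contains binding heat
    result = itc.fit_isotherm(exp, heats_ucal=corrected,
                              float_dilution=True)
    decomp = itc.thermo_decompose(result.log10_KA, result.dH,
                                  cfg.temperature_binding_K)
    return {"dH_kcal": result.dH, "log10_KA": result.log10_KA,
            "kd_itc_uM": decomp["Kd_M"] * 1e6, "dG_kcal": decomp["dG_kcal"],
            "TdS_kcal": decomp["TdS_kcal"], "n": result.n}


def run_pipeline(config: StudyConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage over the peptide panel and assemble the report.

    Returns a dict with DataFrames ``helicity``, ``kinetics``,
    ``calorimetry``, ``consistency`` and a provenance map; optionally
    writes them as CSV plus a JSON bundle to ``out_dir``.
    """
    cfg = config or StudyConfig()
    if not cfg.peptides:
        raise ValueError("config lists no peptides")
    hel_in = study.helicity_table()
    kin_in = study.kinetics_table()
    itc_in = study.itc_table()

    hel_rows, kin_rows, cal_rows, cons_rows = [], [], [], []
    provenance: dict[str, str] = {}
    for name in cfg.peptides:
        if name in hel_in.index:
            res = _helicity_stage(cfg, name, hel_in.loc[name])
            hel_rows.append({"peptide": name, **res})
            provenance[f"helicity.{name}"] = "cd_helicity"
        kd_kin = kd_kin_err = kd_itc = None
        if name in kin_in.index:
            res = _kinetics_stage(cfg, name, kin_in.loc[name])
            res.update(_binding_stage(cfg, name, kin_in.loc[name]))
            kin_rows.append({"peptide": name, **res})
            kd_kin, kd_kin_err = res["kd_kinetic_uM"], res["kd_kinetic_err_uM"]
            provenance[f"kinetics.{name}"] = "kinetics+equilibrium_binding"
        if name in itc_in.index:
            res = _itc_stage(cfg, name, itc_in.loc[name])
            cal_rows.append({"peptide": name, **res})
            kd_itc = res["kd_itc_uM"]
            provenance[f"calorimetry.{name}"] = "itc"
        if kd_kin is not None and kd_itc is not None:
            # two-state binding requires koff/kon == equilibrium Kd;
            # a gap beyond the propagated error implies extra steps
            gap = abs(kd_kin - kd_itc)
            tol = 2.0 * (kd_kin_err or 0.0)
            cons_rows.append({
                "peptide": name, "kd_kinetic_uM": kd_kin,
                "kd_itc_uM": kd_itc, "ratio": kd_kin / kd_itc,
                "non_two_state": bool(gap > tol)})
            provenance[f"consistency.{name}"] = "kinetics vs itc"

    report = {
        "helicity": pd.DataFrame(hel_rows),
        "kinetics": pd.DataFrame(kin_rows),
        "calorimetry": pd.DataFrame(cal_rows),
        "consistency": pd.DataFrame(cons_rows),
        "provenance": provenance,
        "seed": cfg.seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("helicity", "kinetics", "calorimetry", "consistency"):
            report[key].to_csv(out / f"{key}.csv", index=False)
        bundle = {k: report[k].to_dict(orient="records")
                  for k in ("helicity", "kinetics", "calorimetry",
                            "consistency")}
        bundle["provenance"] = provenance
        bundle["seed"] = cfg.seed
        (out / "report.json").write_text(json.dumps(bundle, indent=2,
                                                    default=float))
    return report
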