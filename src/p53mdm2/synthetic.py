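"""Synthetic-data generators for every input type the analysis consumes.

Each generator takes a :class:`GroundTruth` (known parameters + noise
level + seed) and produces the corresponding data container, so every
downstream fit can be validated by parameter recovery without external
data. Noise is i.i.d. Gaussian on the signal. Identical (params, seed)
yield bit-identical output.

Default concentrations, schedules and grids mirror the study conditions:
stopped-flow peptide 0.125 μM with MDM2 at 1-3 μM, fluorescence
titrations of 0-10 μM peptide into 4 μM MDM2, TFE titrations at 5 °C,
and ITC with one 0.5 μl injection followed by 19 of 2 μl into a 200 μl
cell at 15 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cd import two_state_mre
from .binding import quadratic_binding_signal
from .constants import FULL_HELIX_SHIFT_PPM, T_BINDING_K, T_CD_K
from .datatypes import KineticTrace, TitrationCurve
from .ensemble import Ensemble
from .geometry import ALPHA_PHI_DEG, ALPHA_PSI_DEG, build_backbone, ideal_helix
from .itc import ITCExperiment, predicted_heats
from .peptides import Residue

__all__ = [
    "Kind",
    "GroundTruth",
    "ITCSchedule",
    "generate_kinetic_trace",
    "generate_fluor_titration",
    "generate_tfe_titration",
    "generate_itc_heats",
    "generate_itc_power_trace",
    "generate_shift_table",
    "generate_ensemble",
    "write_curve_csv",
    "write_trace_csv",
    "write_itc_csv",
    "write_shift_table_tsv",
    "write_ensemble_pdb",
    "write_ground_truth_yaml",
]


class Kind(str, Enum):
    KINETIC_TRACE = "kinetic_trace"
    PFO_SERIES = "pfo_series"
    FLUOR_TITRATION = "fluor_titration"
    TFE_TITRATION = "tfe_titration"
    ITC_HEATS = "itc_heats"
    SHIFT_TABLE = "shift_table"
    ENSEMBLE = "ensemble"


_POSITIVE = {"kobs", "kon", "koff", "Kd", "KA", "m_value", "MDM2_total",
             "temperature_K"}


@dataclass
class GroundTruth:
    """Known parameters of a synthetic experiment.

    ``params`` keys depend on ``kind`` (documented on each generator);
    ``noise_sd`` is in signal units; ``seed`` fixes the noise stream.
    """

    kind: Kind
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = Kind(self.kind)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for key in _POSITIVE & set(self.params):
            if np.any(np.asarray(self.params[key]) <= 0):
                raise ValueError(f"parameter {key!r} must be positive")
        hp = self.params.get("helix_prob")
        if hp is not None:
            hp = np.asarray(hp, dtype=float)
            if np.any((hp < 0) | (hp > 1)):
                raise ValueError("helix probabilities must lie in [0, 1]")
        af = self.params.get("active_fraction")
        if af is not None and not (0.0 < af <= 1.0):
            raise ValueError("active_fraction must be in (0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def require(self, kind: Kind, *keys: str) -> None:
        if self.kind is not kind:
            raise ValueError(f"ground truth is {self.kind.value}, "
                             f"expected {kind.value}")
        missing = [k for k in keys if k not in self.params]
        if missing:
            raise ValueError(f"missing parameters: {missing}")


def generate_kinetic_trace(truth: GroundTruth,
                           times: Sequence[float]) -> KineticTrace:
    """Single-exponential stopped-flow relaxation.

    params: kobs (s⁻¹), amplitude, offset; optional mdm2_conc_M,
    peptide_conc_M metadata.
    """
    truth.require(Kind.KINETIC_TRACE, "kobs", "amplitude", "offset")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be positive and strictly increasing")
    p = truth.params
    signal = p["offset"] + p["amplitude"] * np.exp(-p["kobs"] * t)
    signal = signal + truth.rng().normal(0.0, truth.noise_sd, t.shape)
    return KineticTrace(time_s=t, signal=signal,
                        mdm2_conc_M=p.get("mdm2_conc_M", np.nan),
                        peptide_conc_M=p.get("peptide_conc_M", np.nan),
                        meta={"truth": p, "noise_sd": truth.noise_sd,
                              "seed": truth.seed})


def generate_fluor_titration(truth: GroundTruth,
                             peptide_concs: Sequence[float]
                             ) -> TitrationCurve:
    """Saturable 1:1 binding titration from the tight-binding equation.

    params: Kd (M), F0, dFmax, MDM2_total (M).
    """
    truth.require(Kind.FLUOR_TITRATION, "Kd", "F0", "dFmax", "MDM2_total")
    x = np.asarray(peptide_concs, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    p = truth.params
    y = quadratic_binding_signal(x, F0=p["F0"], dFmax=p["dFmax"],
                                 Kd=p["Kd"], mdm2_total=p["MDM2_total"])
    y = y + truth.rng().normal(0.0, truth.noise_sd, x.shape)
    return TitrationCurve(x=x, y=y, x_label="peptide_total_M", y_label="F",
                          meta={"truth": p, "noise_sd": truth.noise_sd,
                                "seed": truth.seed,
                                "mdm2_total": p["MDM2_total"]})


def generate_tfe_titration(truth: GroundTruth,
                           tfe_percents: Sequence[float]) -> TitrationCurve:
    """Two-state helix-coil TFE titration with constant baselines.

    params: dG_water (cal/mol), m_value (cal/mol/%), theta_coil,
    theta_helix (deg cm² dmol⁻¹); optional temperature_K (default 278.15).
    """
    truth.require(Kind.TFE_TITRATION, "dG_water", "m_value", "theta_coil",
                  "theta_helix")
    x = np.asarray(tfe_percents, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("%TFE must lie in [0, 100]")
    p = truth.params
    if p["m_value"] <= 0:
        raise ValueError("m_value must be positive")
    y = two_state_mre(x, dG_water=p["dG_water"], m_value=p["m_value"],
                      theta_coil=p["theta_coil"],
                      theta_helix=p["theta_helix"],
                      temperature_K=p.get("temperature_K", T_CD_K))
    y = y + truth.rng().normal(0.0, truth.noise_sd, x.shape)
    return TitrationCurve(x=x, y=y, x_label="tfe_percent", y_label="mre222",
                          meta={"truth": p, "noise_sd": truth.noise_sd,
                                "seed": truth.seed})


@dataclass
class ITCSchedule:
    """Injection schedule: one small pre-injection then equal injections."""

    cell_volume_L: float = 200e-6
    first_volume_L: float = 0.5e-6
    injection_volume_L: float = 2e-6
    n_injections: int = 19
    syringe_conc_M: float = 400e-6
    cell_conc_M: float = 20e-6
    temperature_K: float = T_BINDING_K

    def volumes(self) -> np.ndarray:
        return np.concatenate(([self.first_volume_L],
                               np.full(self.n_injections,
                                       self.injection_volume_L)))


def generate_itc_heats(truth: GroundTruth,
                       schedule: ITCSchedule | None = None) -> ITCExperiment:
    """Per-injection differential heats of a 1:1 isotherm.

    params: KA (M⁻¹), dH (kcal/mol), n; optional dilution_heat (μcal,
    default 0) and active_fraction in (0, 1] (default 1). The first
    injection is included; downstream code decides its exclusion.
    """
    truth.require(Kind.ITC_HEATS, "KA", "dH", "n")
    schedule = schedule or ITCSchedule()
    if schedule.cell_volume_L <= 0:
        raise ValueError("cell volume must be positive")
    if schedule.syringe_conc_M <= 0:
        raise ValueError("syringe concentration must be positive")
    p = truth.params
    exp = ITCExperiment(
        cell_volume_L=schedule.cell_volume_L,
        syringe_conc_M=schedule.syringe_conc_M,
        cell_conc_M=schedule.cell_conc_M,
        injection_volumes_L=schedule.volumes(),
        heats_ucal=np.zeros(schedule.n_injections + 1),
        temperature_K=schedule.temperature_K,
        active_fraction=p.get("active_fraction", 1.0),
        meta={"truth": p, "noise_sd": truth.noise_sd, "seed": truth.seed})
    heats = predicted_heats(exp, n=p["n"], KA=p["KA"], dH=p["dH"],
                            dilution_heat_ucal=p.get("dilution_heat", 0.0))
    heats = heats + truth.rng().normal(0.0, truth.noise_sd, heats.shape)
    exp.heats_ucal = heats
    return exp


def generate_itc_power_trace(heats_ucal: Sequence[float],
                             spacing_s: float = 150.0,
                             peak_width_s: float = 8.0,
                             baseline_ucal_s: float = 0.0,
                             dt_s: float = 0.5
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Differential-power trace with one Gaussian peak per injection.

    Returns ``(time_s, power_ucal_per_s, injection_times_s)``; each peak
    integrates to the corresponding heat.
    """
    q = np.asarray(heats_ucal, dtype=float)
    t_end = spacing_s * (q.size + 1)
    t = np.arange(0.0, t_end, dt_s)
    inj = spacing_s * (np.arange(q.size) + 0.5)
    power = np.full_like(t, baseline_ucal_s)
    for qi, ti in zip(q, inj):
        center = ti + 5.0 * peak_width_s
        power += (qi / (peak_width_s * np.sqrt(2 * np.pi))
                  * np.exp(-0.5 * ((t - center) / peak_width_s) ** 2))
    return t, power, inj


def generate_shift_table(truth: GroundTruth,
                         sequence: Sequence[Residue]) -> pd.DataFrame:
    """Hα shift table from random-coil references plus helix offsets.

    δ_obs = δ_RC + helix_prob · full_helix offset (+ noise). params:
    helix_prob (per residue), rc_shifts (per-residue Hα references, same
    length as the sequence — caller supplied); optional full_helix_ppm
    (default −0.39), rc_shifts_hn and nh_downfield_ppm (default +0.2) for
    the HN rows of phospho residues.
    """
    truth.require(Kind.SHIFT_TABLE, "helix_prob", "rc_shifts")
    p = truth.params
    hp = np.asarray(p["helix_prob"], dtype=float)
    rc = np.asarray(p["rc_shifts"], dtype=float)
    if not (len(sequence) == hp.size == rc.size):
        raise ValueError("sequence, helix_prob and rc_shifts lengths differ")
    if np.any(np.isnan(rc)):
        raise ValueError("every residue needs a random-coil reference shift")
    full = p.get("full_helix_ppm", FULL_HELIX_SHIFT_PPM)
    rng = truth.rng()
    obs = rc + hp * full + rng.normal(0.0, truth.noise_sd, rc.shape)
    rows = [{"residue_index": r.index, "residue_code": r.code, "atom": "HA",
             "delta_obs_ppm": obs[i], "delta_rc_ppm": rc[i],
             "phospho": r.phospho}
            for i, r in enumerate(sequence)]
    rc_hn = p.get("rc_shifts_hn")
    nh_off = p.get("nh_downfield_ppm", 0.2)
    for i, r in enumerate(sequence):
        if r.phospho:
            ref = (rc_hn[i] if rc_hn is not None else 8.3)
            rows.append({"residue_index": r.index, "residue_code": r.code,
                         "atom": "HN",
                         "delta_obs_ppm": ref + nh_off
                         + rng.normal(0.0, truth.noise_sd),
                         "delta_rc_ppm": ref, "phospho": True})
    return pd.DataFrame(rows)


_COIL_PHI_RANGE = (-180.0, -50.0)
# psi coil basin: beta/PPII region, excluding the helical window
_COIL_PSI_RANGES = ((60.0, 180.0), (-180.0, -150.0))


def _sample_coil(rng: np.random.Generator) -> tuple[float, float]:
    phi = rng.uniform(*_COIL_PHI_RANGE)
    widths = [hi - lo for lo, hi in _COIL_PSI_RANGES]
    which = rng.random() * sum(widths)
    if which < widths[0]:
        lo, hi = _COIL_PSI_RANGES[0]
        psi = lo + which
    else:
        lo, hi = _COIL_PSI_RANGES[1]
        psi = lo + (which - widths[0])
    return phi, psi


def generate_ensemble(truth: GroundTruth, n_frames: int,
                      n_residues: int) -> Ensemble:
    """Backbone ensemble with prescribed per-residue helix probabilities.

    Residue i is α-helical (φ=−60°, ψ=−45°) with probability
    helix_prob[i], otherwise its dihedrals are drawn uniformly from the
    coil basin. Coordinates are built with ideal geometry; the reference
    frame is the ideal helix of the same length.
    """
    truth.require(Kind.ENSEMBLE, "helix_prob")
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if n_frames < 1:
        raise ValueError("need at least 1 frame")
    hp = np.broadcast_to(np.asarray(truth.params["helix_prob"], dtype=float),
                         (n_residues,))
    rng = truth.rng()
    frames = np.empty((n_frames, 3 * n_residues, 3))
    helical_mask = np.empty((n_frames, n_residues), dtype=bool)
    for k in range(n_frames):
        phi = np.empty(n_residues)
        psi = np.empty(n_residues)
        for i in range(n_residues):
            if rng.random() < hp[i]:
                phi[i], psi[i] = ALPHA_PHI_DEG, ALPHA_PSI_DEG
                helical_mask[k, i] = True
            else:
                phi[i], psi[i] = _sample_coil(rng)
                helical_mask[k, i] = False
        frames[k] = build_backbone(phi, psi)
    atom_names = ["N", "CA", "C"] * n_residues
    return Ensemble(coords=frames, atom_names=atom_names,
                    reference=ideal_helix(n_residues),
                    meta={"truth": dict(truth.params),
                          "helical_mask": helical_mask,
                          "seed": truth.seed})


# ---------------------------------------------------------------- writers

def write_curve_csv(curve: TitrationCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def write_trace_csv(trace: KineticTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_itc_csv(exp: ITCExperiment, path: str | Path) -> None:
    pd.DataFrame({
        "injection_volume_uL": exp.injection_volumes_L * 1e6,
        "heat_ucal": exp.heats_ucal,
    }).to_csv(path, index=False)


def write_shift_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_ensemble_pdb(ens: Ensemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (coordinates in Å)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = len(ens.atom_names)
    n_res = n_atoms // 3
    template = struc.AtomArray(n_atoms)
    template.coord = np.zeros((n_atoms, 3), dtype=np.float32)
    template.atom_name = np.array(ens.atom_names)
    template.element = np.array([a[0] for a in ens.atom_names])
    template.res_id = np.repeat(np.arange(1, n_res + 1), 3)
    template.res_name = np.array(["ALA"] * n_atoms)
    template.chain_id = np.array(["A"] * n_atoms)
    stack = struc.stack([template] * ens.n_frames)
    stack.coord = (ens.coords * 10.0).astype(np.float32)  # nm -> Angstrom
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def write_ground_truth_yaml(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "kind": truth.kind.value,
        "params": {k: (np.asarray(v).tolist()
                       if isinstance(v, (list, tuple, np.ndarray)) else v)
                   for k, v in truth.params.items()},
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
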