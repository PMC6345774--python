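"""Isothermal titration calorimetry: peak integration, dilution correction,
1:1 isotherm fitting and thermodynamic decomposition.

A titration injects ligand (p53 peptide) from a syringe into a cell of
fixed volume containing the macromolecule (MDM2). Each injection displaces
cell volume, so both species are diluted by (1 − v/V0) per injection while
the injected ligand accumulates. The differential heat of injection i is
the enthalpy times the change in complex content of the cell,

    q_i = ΔH · V0 · ( [PL]_i − [PL]_{i−1}·(1 − v_i/V0) ),

with [PL] the exact 1:1 equilibrium complex concentration at the
post-injection totals. The stoichiometry parameter n multiplies the
nominal cell concentration; a binding-competent ("active") fraction of
the macromolecule below 1 therefore shows up as an apparent n below 1
when the nominal concentration is taken at face value.

Decomposition at temperature T uses ΔG = −RT ln K_A and TΔS = ΔH − ΔG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .binding import bound_complex_concentration
from .constants import R_KCAL, T_BINDING_K

__all__ = [
    "ITCExperiment",
    "ThermoResult",
    "PlateauNotFoundError",
    "predicted_heats",
    "integrate_peaks",
    "dilution_correct",
    "fit_isotherm",
    "thermo_decompose",
]

KCAL_TO_UCAL = 1e9


@dataclass
class ITCExperiment:
    """An injection schedule with per-injection heats (μcal).

    The first injection (conventionally a small 0.5 μl pre-injection) is
    kept in the data; downstream fitting excludes it by default.
    """

    cell_volume_L: float
    syringe_conc_M: float
    cell_conc_M: float
    injection_volumes_L: np.ndarray
    heats_ucal: np.ndarray
    temperature_K: float = T_BINDING_K
    active_fraction: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.injection_volumes_L = np.asarray(self.injection_volumes_L,
                                              dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.cell_volume_L <= 0:
            raise ValueError("cell volume must be positive")
        if self.syringe_conc_M <= 0:
            raise ValueError("syringe concentration must be positive")
        if self.cell_conc_M <= 0:
            raise ValueError("cell concentration must be positive")
        if np.any(self.injection_volumes_L <= 0):
            raise ValueError("injection volumes must be positive")
        if self.injection_volumes_L.shape != self.heats_ucal.shape:
            raise ValueError("injection volumes and heats differ in length")
        if not (0.0 < self.active_fraction <= 1.0):
            raise ValueError("active_fraction must be in (0, 1]")


@dataclass
class ThermoResult:
    """Fitted and derived 1:1 binding thermodynamics.

    The identities K_d·K_A = 1, ΔG = −RT ln K_A and TΔS = ΔH − ΔG hold to
    machine precision by construction.
    """

    n: float
    KA: float
    dH: float
    temperature_K: float
    errors: dict[str, float] = field(default_factory=dict)
    c_value: float = float("nan")
    poorly_determined: bool = False
    active_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.KA <= 0:
            raise ValueError("KA must be positive")

    @property
    def Kd(self) -> float:
        return 1.0 / self.KA

    @property
    def log10_KA(self) -> float:
        return float(np.log10(self.KA))

    @property
    def dG(self) -> float:
        return -R_KCAL * self.temperature_K * np.log(self.KA)

    @property
    def TdS(self) -> float:
        return self.dH - self.dG


def _cell_totals(exp_volumes_L: np.ndarray, cell_volume_L: float,
                 cell_conc_M: float, syringe_conc_M: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-injection total cell concentrations (macromolecule, ligand).

    Exact displacement bookkeeping: each injection of volume v dilutes the
    cell contents by (1 − v/V0) and delivers syringe ligand at v/V0.
    Returns (M_tot, X_tot, dilution_factor) after each injection.
    """
    m = np.empty(exp_volumes_L.size)
    x = np.empty(exp_volumes_L.size)
    f = np.empty(exp_volumes_L.size)
    m_cur, x_cur = cell_conc_M, 0.0
    for i, v in enumerate(exp_volumes_L):
        d = v / cell_volume_L
        m_cur = m_cur * (1.0 - d)
        x_cur = x_cur * (1.0 - d) + syringe_conc_M * d
        m[i], x[i], f[i] = m_cur, x_cur, 1.0 - d
    return m, x, f


def predicted_heats(exp: ITCExperiment, n: float, KA: float, dH: float,
                    dilution_heat_ucal: float = 0.0,
                    active_fraction: float | None = None) -> np.ndarray:
    """Model per-injection heats (μcal) for a 1:1 isotherm.

    ``n`` scales the binding-competent cell concentration; an explicit
    ``active_fraction`` multiplies it further (defaults to the
    experiment's recorded value).
    """
    af = exp.active_fraction if active_fraction is None else active_fraction
    m_tot, x_tot, f = _cell_totals(exp.injection_volumes_L, exp.cell_volume_L,
                                   exp.cell_conc_M * af * n,
                                   exp.syringe_conc_M)
    pl = bound_complex_concentration(x_tot, m_tot, 1.0 / KA)
    pl_prev = np.concatenate(([0.0], pl[:-1]))
    dq = dH * exp.cell_volume_L * (pl - pl_prev * f)
    return dq * KCAL_TO_UCAL + dilution_heat_ucal


def integrate_peaks(time_s: np.ndarray, power_ucal_s: np.ndarray,
                    injection_times_s: np.ndarray,
                    quiet_fraction: float = 0.1
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a differential-power trace into per-injection heats.

    The baseline over each inter-injection interval is the straight line
    between the mean power of the quiet windows (last ``quiet_fraction``
    of the interval) preceding the injection and preceding the next one.
    The heat is the trapezoidal integral of (power − baseline). Intervals
    whose end window has not returned to within 3 baseline-noise SDs are
    flagged as overlapping.

    Returns ``(heats_ucal, overlap_flags)``.
    """
    t = np.asarray(time_s, dtype=float)
    p = np.asarray(power_ucal_s, dtype=float)
    tau = np.asarray(injection_times_s, dtype=float)
    if tau.min() < t[0] or tau.max() > t[-1]:
        raise ValueError("injection times outside the trace")
    bounds = np.concatenate((tau, [t[-1]]))
    heats = np.empty(tau.size)
    flags = np.zeros(tau.size, dtype=bool)

    def quiet_stats(t_end: float, width: float) -> tuple[float, float]:
        sel = (t >= t_end - width) & (t < t_end)
        if not sel.any():
            sel = np.array([np.searchsorted(t, t_end) - 1])
        return float(np.mean(p[sel])), float(np.std(p[sel]))

    for i in range(tau.size):
        t0, t1 = bounds[i], bounds[i + 1]
        width = quiet_fraction * (t1 - t0)
        b0, s0 = quiet_stats(t0, width)
        b1, s1 = quiet_stats(t1, width)
        sel = (t >= t0) & (t <= t1)
        baseline = np.interp(t[sel], [t0, t1], [b0, b1])
        heats[i] = np.trapezoid(p[sel] - baseline, t[sel])
        # unresolved return to baseline before the next peak -> overlap
        noise = max(s0, s1, 1e-12)
        peak_amp = float(np.max(np.abs(p[sel] - baseline)))
        if i + 1 < tau.size:
            tail = p[(t >= t1 - width) & (t < t1)]
            end_dev = abs(float(np.mean(tail)) - b0) if tail.size else 0.0
            if peak_amp > 10 * noise and end_dev > 3 * max(noise, 1e-12):
                flags[i] = True
    return heats, flags


class PlateauNotFoundError(RuntimeError):
    """No saturation plateau detected; pass explicit plateau indices."""


def dilution_correct(heats_ucal: np.ndarray, n_plateau: int = 4,
                     rel_tol: float = 0.05,
                     plateau_indices: np.ndarray | None = None
                     ) -> tuple[np.ndarray, float]:
    """Subtract the dilution heat estimated from post-saturation injections.

    The dilution heat is the mean of the plateau injections — by default
    the last ``n_plateau``, accepted as a plateau only when their spread
    is below ``rel_tol`` of the full heat range. Explicit
    ``plateau_indices`` override detection.

    Returns ``(corrected_heats, dilution_heat)``.
    """
    q = np.asarray(heats_ucal, dtype=float)
    if plateau_indices is not None:
        plateau = q[np.asarray(plateau_indices, dtype=int)]
    else:
        if q.size < n_plateau + 1:
            raise ValueError("too few injections for plateau detection")
        plateau = q[-n_plateau:]
        full_range = np.ptp(q)
        if full_range > 0 and np.ptp(plateau) > rel_tol * full_range:
            raise PlateauNotFoundError(
                "last injections do not form a plateau; pass "
                "plateau_indices explicitly")
    dilution = float(np.mean(plateau))
    return q - dilution, dilution


def fit_isotherm(exp: ITCExperiment, float_active_fraction: bool = False,
                 exclude_first: bool = True,
                 heats_ucal: np.ndarray | None = None,
                 float_dilution: bool = False) -> ThermoResult:
    """Least-squares fit of the 1:1 isotherm to dilution-corrected heats.

    Free parameters are (n, K_A, ΔH). With ``float_active_fraction`` the
    stoichiometry is fixed at 1 and the binding-competent fraction of the
    nominal cell concentration floats instead (the two are exactly
    degenerate, so only one may vary). ``float_dilution`` adds a constant
    per-injection heat offset as a fourth parameter, absorbing any
    residual dilution heat the plateau subtraction missed. The first
    (small) injection is excluded from the residuals by default. A
    Wiseman c-value (K_A·n·[cell]) outside ~1–1000 flags the result as
    poorly determined.
    """
    q = exp.heats_ucal if heats_ucal is None else np.asarray(heats_ucal,
                                                             dtype=float)
    mask = np.ones(q.size, dtype=bool)
    if exclude_first:
        mask[0] = False

    def residual(params):
        model = predicted_heats(
            exp, n=params["n"].value, KA=10.0 ** params["log10_KA"].value,
            dH=params["dH"].value,
            dilution_heat_ucal=params["dilution_heat"].value,
            active_fraction=params["active_fraction"].value)
        return (model - q)[mask]

    # ΔH start: first fitted heat per mole of injectant (fully bound limit)
    v_first = exp.injection_volumes_L[mask][0]
    moles_first = exp.syringe_conc_M * v_first
    dh0 = q[mask][0] / KCAL_TO_UCAL / moles_first if moles_first > 0 else -10.0
    params = lmfit.Parameters()
    params.add("log10_KA", value=5.5, min=1.0, max=12.0)
    params.add("dH", value=dh0 if dh0 != 0 else -10.0)
    params.add("n", value=1.0, min=1e-3, vary=not float_active_fraction)
    params.add("active_fraction", value=exp.active_fraction if not
               float_active_fraction else 0.8, min=1e-3, max=1.0,
               vary=float_active_fraction)
    params.add("dilution_heat", value=0.0, vary=float_dilution)
    out = lmfit.minimize(residual, params)
    if not out.success:
        raise RuntimeError("isotherm fit did not converge")
    p = out.params
    ka = 10.0 ** p["log10_KA"].value
    n = p["n"].value if not float_active_fraction else p["active_fraction"].value
    errors = {}
    for name in ("log10_KA", "dH", "n", "active_fraction"):
        errors[name] = (p[name].stderr
                        if p[name].stderr is not None else np.nan)
    c_value = ka * n * exp.cell_conc_M
    poorly = not (1.0 <= c_value <= 1000.0)
    if poorly:
        warnings.warn(f"Wiseman c-value {c_value:.3g} outside ~1-1000; "
                      "isotherm curvature poorly determined", stacklevel=2)
    return ThermoResult(
        n=float(p["n"].value), KA=float(ka), dH=float(p["dH"].value),
        temperature_K=exp.temperature_K, errors=errors,
        c_value=float(c_value), poorly_determined=poorly,
        active_fraction=(float(p["active_fraction"].value)
                         if float_active_fraction else None))


def thermo_decompose(log10_KA: float, dH_kcal: float,
                     temperature_K: float = T_BINDING_K) -> dict[str, float]:
    """Derive K_d, ΔG and TΔS from log10 K_A and ΔH at temperature T.

    Returns a dict with Kd_M, dG_kcal, TdS_kcal (and the inputs echoed).
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    ka = 10.0 ** log10_KA
    dG = -R_KCAL * temperature_K * np.log(ka)
    return {
        "log10_KA": float(log10_KA),
        "KA_per_M": float(ka),
        "Kd_M": float(10.0 ** (-log10_KA)),
        "dH_kcal": float(dH_kcal),
        "dG_kcal": float(dG),
        "TdS_kcal": float(dH_kcal - dG),
        "temperature_K": float(temperature_K),
    }
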