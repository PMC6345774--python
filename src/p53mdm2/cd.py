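"""CD helicity analysis: mean residue ellipticity, helix fractions and
two-state TFE helix-coil titration fits.

The helix content of a short peptide is read out two ways. Directly, the
mean residue ellipticity at 222 nm ([Θ]222) is compared with the value of a
100% helical peptide (−31500 deg cm² dmol⁻¹). Indirectly, a titration with
the helix-inducing cosolvent 2,2,2-trifluoroethanol (TFE) is fitted to a
two-state helix ↔ coil equilibrium whose free energy is linear in %TFE,

    ΔG([TFE]) = ΔG_water − m·[TFE],   K = exp(−ΔG/RT),

so the signal is (θ_coil + θ_helix·K)/(1 + K). The midpoint of the
transition is [TFE]1/2 = ΔG_water/m and the helix population in water is
K(0)/(1+K(0)). A positive ΔG_water means helix is unfavourable in water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import MRE_FULL_HELIX, R_CAL, T_CD_K
from .datatypes import TitrationCurve

__all__ = [
    "CDRecord",
    "TFEFit",
    "mean_residue_ellipticity",
    "helix_percent_from_mre",
    "two_state_mre",
    "helix_fraction",
    "fit_tfe_titration",
]


@dataclass
class CDRecord:
    """A raw CD measurement in machine units (millidegrees)."""

    wavelength_nm: float
    theta_mdeg: float
    concentration_M: float
    pathlength_cm: float
    n_residues: int

    def __post_init__(self) -> None:
        if self.concentration_M <= 0:
            raise ValueError("concentration must be positive")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be positive")
        if self.n_residues <= 0:
            raise ValueError("n_residues must be positive")


@dataclass
class TFEFit:
    """Result of a two-state TFE titration fit.

    ``dG_water == tfe_half_percent * m_value`` holds exactly by
    construction. ``sigmoidal`` is False when the data do not bracket the
    transition or the baseline separation is not resolved above noise; in
    that case no population estimate is reported.
    """

    tfe_half_percent: float
    m_value: float
    dG_water: float
    theta_coil: float
    theta_helix: float
    helix_fraction_water: float | None
    temperature_K: float
    sigmoidal: bool
    fit_errors: dict[str, float] = field(default_factory=dict)
    result: lmfit.model.ModelResult | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.dG_water, self.tfe_half_percent * self.m_value,
                          rtol=1e-12, atol=1e-9):
            raise ValueError("dG_water must equal tfe_half_percent * m_value")


def mean_residue_ellipticity(rec: CDRecord) -> float:
    """Convert raw ellipticity to mean residue ellipticity.

    [Θ] = θ_mdeg / (10 · c · l · N) in deg cm² dmol⁻¹ residue⁻¹, with c in
    mol/L, l in cm and N the number of peptide bonds/residues.
    """
    return rec.theta_mdeg / (10.0 * rec.concentration_M * rec.pathlength_cm
                             * rec.n_residues)


def helix_percent_from_mre(mre222: float,
                           full_helix: float = MRE_FULL_HELIX) -> float:
    """Helix percentage from [Θ]222 against the 100%-helix reference.

    Positive ellipticities (no helix signal) clamp to 0 with a warning, as
    do values beyond the full-helix reference (clamped to 100).
    """
    pct = 100.0 * mre222 / full_helix
    if pct < 0.0:
        warnings.warn("positive [Θ]222: helix percentage clamped to 0",
                      stacklevel=2)
        return 0.0
    if pct > 100.0:
        warnings.warn("[Θ]222 beyond full-helix reference: clamped to 100",
                      stacklevel=2)
        return 100.0
    return pct


def _equilibrium_constant(tfe_percent, dG_water, m_value, temperature_K):
    dG = dG_water - m_value * np.asarray(tfe_percent, dtype=float)
    return np.exp(-dG / (R_CAL * temperature_K))


def helix_fraction(tfe_percent, dG_water, m_value,
                   temperature_K: float = T_CD_K):
    """Two-state helix population at a given %TFE."""
    K = _equilibrium_constant(tfe_percent, dG_water, m_value, temperature_K)
    return K / (1.0 + K)


def two_state_mre(tfe_percent, dG_water, m_value, theta_coil, theta_helix,
                  temperature_K: float = T_CD_K):
    """Model ellipticity of the two-state helix-coil titration."""
    f = helix_fraction(tfe_percent, dG_water, m_value, temperature_K)
    return theta_coil + (theta_helix - theta_coil) * f


class TFEFitError(RuntimeError):
    """Non-convergent TFE fit; carries the residuals for diagnosis."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


def fit_tfe_titration(curve: TitrationCurve,
                      temperature_K: float = T_CD_K,
                      baseline_resolution_sigma: float = 3.0) -> TFEFit:
    """Fit a two-state TFE titration of (%TFE, [Θ]222) data.

    Free parameters are ΔG_water, m, and the coil and helix baselines
    (fitted as constants). Reports [TFE]1/2 = ΔG_water/m and the helix
    population in water. The fit is flagged non-sigmoidal when the fitted
    midpoint is not bracketed by the data or when the baseline separation
    is below ``baseline_resolution_sigma`` times its standard error; in
    that case the water population is withheld.
    """
    if len(curve) < 6:
        raise ValueError("need at least 6 titration points")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    x, y = curve.x, curve.y

    model = lmfit.Model(two_state_mre, independent_vars=["tfe_percent"])
    # data-driven starts: midpoint from the half-signal crossing, m from the
    # steepest observed slope (two-state: dy/dx|mid = (θh−θc)·m/(4RT))
    span = float(y[-1] - y[0])
    if span == 0.0:
        span = float(np.ptp(y)) or 1.0
    ymid = 0.5 * (y[0] + y[-1])
    tfe_half0 = float(x[np.argmin(np.abs(y - ymid))]) or float(np.median(x))
    slope_max = float(np.max(np.abs(np.gradient(y, x))))
    rt = R_CAL * temperature_K
    m0 = float(np.clip(4.0 * rt * slope_max / abs(span), 10.0, 2000.0))
    params = model.make_params(
        dG_water=dict(value=tfe_half0 * m0),
        m_value=dict(value=m0, min=1e-6),
        theta_coil=dict(value=float(y[0])),
        theta_helix=dict(value=float(y[-1] + 0.25 * span)),
        temperature_K=dict(value=temperature_K, vary=False),
    )
    result = model.fit(y, params, tfe_percent=x)
    if not result.success:
        raise TFEFitError("two-state TFE fit failed to converge",
                          residuals=result.residual)

    p = result.params
    dG = p["dG_water"].value
    m = p["m_value"].value
    tfe_half = dG / m
    errors = {name: (p[name].stderr if p[name].stderr is not None else np.nan)
              for name in ("dG_water", "m_value", "theta_coil", "theta_helix")}
    # propagated midpoint error from the (dG, m) covariance
    if result.covar is not None and p["dG_water"].stderr:
        names = [n for n in result.var_names]
        i, j = names.index("dG_water"), names.index("m_value")
        var = (result.covar[i, i] / m**2
               + dG**2 * result.covar[j, j] / m**4
               - 2 * dG * result.covar[i, j] / m**3)
        errors["tfe_half_percent"] = float(np.sqrt(max(var, 0.0)))

    sep = p["theta_helix"].value - p["theta_coil"].value
    sep_err = np.sqrt(
        (errors["theta_helix"] if np.isfinite(errors["theta_helix"]) else 0.0) ** 2
        + (errors["theta_coil"] if np.isfinite(errors["theta_coil"]) else 0.0) ** 2
    )
    bracketed = bool(x.min() <= tfe_half <= x.max())
    resolved = bool(sep_err == 0.0 or abs(sep) > baseline_resolution_sigma * sep_err)
    sigmoidal = bracketed and resolved

    frac_water = (float(helix_fraction(0.0, dG, m, temperature_K))
                  if sigmoidal else None)
    return TFEFit(
        tfe_half_percent=float(tfe_half),
        m_value=float(m),
        dG_water=float(tfe_half * m),
        theta_coil=float(p["theta_coil"].value),
        theta_helix=float(p["theta_helix"].value),
        helix_fraction_water=frac_water,
        temperature_K=temperature_K,
        sigmoidal=sigmoidal,
        fit_errors=errors,
        result=result,
    )
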