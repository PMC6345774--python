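"""Equilibrium fluorescence titrations: quadratic tight-binding fits.

When the fixed component's concentration is comparable to K_d, free and
total ligand cannot be equated and the bound fraction follows the exact
solution of the 1:1 mass-action equilibrium. The observed fluorescence at
total peptide concentration P_T with MDM2 fixed at M_T is

    F = F0 + (ΔFmax / (2·M_T)) · [ (M_T + P_T + Kd)
            − sqrt((M_T + P_T + Kd)² − 4·M_T·P_T) ],

where the bracketed term is twice the complex concentration. The
discriminant is clamped at zero before the square root: it is
algebraically non-negative but floating-point cancellation is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .datatypes import TitrationCurve

__all__ = [
    "BindingFit",
    "quadratic_binding_signal",
    "bound_complex_concentration",
    "subtract_blank",
    "check_inner_filter",
    "fit_quadratic_binding",
]


@dataclass
class BindingFit:
    """Fitted parameters of the quadratic tight-binding titration."""

    Kd: float
    Kd_err: float
    F0: float
    dFmax: float
    mdm2_total: float
    poorly_determined: bool = False
    errors: dict[str, float] = field(default_factory=dict)
    result: lmfit.model.ModelResult | None = None

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")


def bound_complex_concentration(peptide_total, mdm2_total, Kd):
    """Exact 1:1 complex concentration from total concentrations."""
    P = np.asarray(peptide_total, dtype=float)
    s = mdm2_total + P + Kd
    disc = np.clip(s * s - 4.0 * mdm2_total * P, 0.0, None)
    # conjugate form of the smaller root: no catastrophic cancellation
    # in the weak-binding limit (4*M*P << s^2)
    return 2.0 * mdm2_total * P / (s + np.sqrt(disc))


def quadratic_binding_signal(peptide_total, F0, dFmax, Kd, mdm2_total):
    """Evaluate the tight-binding titration model."""
    if mdm2_total <= 0:
        raise ValueError("mdm2_total must be positive")
    if np.any(np.asarray(peptide_total) < 0):
        raise ValueError("concentrations must be non-negative")
    complex_conc = bound_complex_concentration(peptide_total, mdm2_total, Kd)
    return F0 + dFmax * complex_conc / mdm2_total


def subtract_blank(curve: TitrationCurve, blank: TitrationCurve
                   ) -> TitrationCurve:
    """Subtract a peptide-only blank titration point-by-point."""
    if not np.allclose(curve.x, blank.x):
        raise ValueError("blank titration must share the concentration grid")
    return TitrationCurve(x=curve.x.copy(), y=curve.y - blank.y,
                          x_label=curve.x_label, y_label=curve.y_label,
                          meta=dict(curve.meta, blank_subtracted=True))


def check_inner_filter(absorbance, limit: float = 0.2) -> bool:
    """Warn when absorbance exceeds the inner-filter safe limit."""
    a = np.max(np.asarray(absorbance, dtype=float))
    if a > limit:
        warnings.warn(f"absorbance {a:.3g} exceeds {limit}; inner-filter "
                      "effects likely", stacklevel=2)
        return False
    return True


def fit_quadratic_binding(curves: TitrationCurve | list[TitrationCurve],
                          mdm2_total: float) -> BindingFit:
    """Fit (Kd, F0, ΔFmax) to one titration or jointly to replicates.

    Replicate curves share all three parameters (joint least squares on the
    concatenated data). The fit is flagged ``poorly_determined`` when the
    Kd standard error exceeds Kd itself or the amplitude is not resolved
    above its error — small-amplitude titrations determine Kd badly.
    """
    if isinstance(curves, TitrationCurve):
        curves = [curves]
    x = np.concatenate([c.x for c in curves])
    y = np.concatenate([c.y for c in curves])
    if x.size < 6:
        raise ValueError("need at least 6 titration points")
    if x.max() < 2.0 * mdm2_total:
        warnings.warn("titrant range below ~2x the fixed concentration; "
                      "saturation poorly constrained", stacklevel=2)

    model = lmfit.Model(quadratic_binding_signal,
                        independent_vars=["peptide_total"])
    span = float(y[-1] - y[0]) or float(np.ptp(y)) or 1.0
    params = model.make_params(
        F0=dict(value=float(y[0])),
        dFmax=dict(value=span),
        Kd=dict(value=max(mdm2_total, x.max() / 4.0), min=1e-15),
        mdm2_total=dict(value=mdm2_total, vary=False),
    )
    result = model.fit(y, params, peptide_total=x)
    if not result.success:
        raise RuntimeError("quadratic binding fit did not converge")
    p = result.params
    errors = {k: (p[k].stderr if p[k].stderr is not None else np.nan)
              for k in ("Kd", "F0", "dFmax")}
    kd, kd_err = p["Kd"].value, errors["Kd"]
    amp, amp_err = p["dFmax"].value, errors["dFmax"]
    poorly = bool(
        (np.isfinite(kd_err) and kd_err > kd)
        or not np.isfinite(kd_err)
        or (np.isfinite(amp_err) and abs(amp) < 2.0 * amp_err)
    )
    if poorly:
        warnings.warn("Kd poorly determined (error comparable to value or "
                      "amplitude unresolved)", stacklevel=2)
    return BindingFit(Kd=float(kd),
                      Kd_err=float(kd_err) if np.isfinite(kd_err) else np.nan,
                      F0=float(p["F0"].value), dFmax=float(amp),
                      mdm2_total=mdm2_total, poorly_determined=poorly,
                      errors=errors, result=result)
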