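"""Stopped-flow binding kinetics under pseudo-first-order conditions.

With one partner (MDM2) in large excess, the approach to equilibrium of a
bimolecular association is single-exponential with observed rate

    k_obs = k_on · [MDM2] + k_off,

so fitting averaged traces to ``offset + amplitude·exp(−k_obs·t)`` at a
series of MDM2 concentrations and regressing k_obs on [MDM2] yields k_on
(slope) and k_off (intercept), and hence the kinetic dissociation constant
K_d = k_off/k_on. The intercept relies on extrapolation to zero
concentration, so k_off carries the larger relative error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import statsmodels.api as sm

from .datatypes import KineticTrace, RateSeries

__all__ = [
    "ExponentialFit",
    "RateFit",
    "NoExponentialBehaviour",
    "average_traces",
    "fit_single_exponential",
    "fit_pseudo_first_order",
    "kd_from_rates",
]


class NoExponentialBehaviour(RuntimeError):
    """Raised when a trace shows no resolvable exponential relaxation."""


@dataclass
class ExponentialFit:
    """Single-exponential fit of one kinetic trace."""

    kobs_s: float
    amplitude: float
    offset: float
    errors: dict[str, float]
    residuals: np.ndarray
    redchi: float
    result: lmfit.model.ModelResult | None = None


@dataclass
class RateFit:
    """Pseudo-first-order line fit: kon (slope), koff (intercept)."""

    kon: float
    kon_err: float
    koff: float
    koff_err: float
    weighted: bool = False
    negative_koff: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def kd_kinetic(self) -> float:
        return self.koff / self.kon


def average_traces(traces: list[KineticTrace]) -> KineticTrace:
    """Pointwise mean of replicate traces on a common time base.

    All traces must share the time grid and concentrations; fewer than four
    replicates triggers a warning (averaging at least four is the working
    standard for these measurements).
    """
    if not traces:
        raise ValueError("no traces supplied")
    ref = traces[0]
    for tr in traces[1:]:
        if not np.array_equal(tr.time_s, ref.time_s):
            raise ValueError("traces have mismatched time grids")
        if not (np.isclose(tr.mdm2_conc_M, ref.mdm2_conc_M, equal_nan=True)
                and np.isclose(tr.peptide_conc_M, ref.peptide_conc_M,
                               equal_nan=True)):
            raise ValueError("traces have mismatched concentrations")
    n = len(traces)
    if n < 4:
        warnings.warn(f"averaging only {n} traces (fewer than 4)",
                      stacklevel=2)
    mean_signal = np.mean([tr.signal for tr in traces], axis=0)
    return KineticTrace(time_s=ref.time_s.copy(), signal=mean_signal,
                        mdm2_conc_M=ref.mdm2_conc_M,
                        peptide_conc_M=ref.peptide_conc_M, n_averaged=n)


def _exp_model(t, kobs, amplitude, offset):
    return offset + amplitude * np.exp(-kobs * t)


def _initial_kobs(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting values from log-linearised early decay."""
    offset0 = float(np.mean(y[-max(3, y.size // 10):]))
    amp0 = float(y[0] - offset0)
    if amp0 == 0.0:
        amp0 = float(np.ptp(y)) or 1.0
    z = (y - offset0) / amp0
    mask = z > 0.05
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(z[mask]), 1)[0]
        kobs0 = max(-slope, 1e-6)
    else:
        kobs0 = 1.0 / max(t[-1] - t[0], 1e-12)
    return kobs0, amp0, offset0


def fit_single_exponential(trace: KineticTrace) -> ExponentialFit:
    """Least-squares fit of ``offset + amplitude·exp(−kobs·t)``.

    Raises :class:`NoExponentialBehaviour` when the fitted amplitude is
    indistinguishable from zero at the 95% level (flat trace) or the fit
    does not converge. Warns when the time span covers less than 3/kobs.
    """
    t, y = trace.time_s, trace.signal
    if t.size < 10:
        raise ValueError("need at least 10 points for an exponential fit")
    kobs0, amp0, offset0 = _initial_kobs(t, y)
    model = lmfit.Model(_exp_model)
    params = model.make_params(kobs=dict(value=kobs0, min=1e-12),
                               amplitude=dict(value=amp0),
                               offset=dict(value=offset0))
    result = model.fit(y, params, t=t)
    if not result.success:
        raise NoExponentialBehaviour("exponential fit did not converge")
    p = result.params
    amp, amp_err = p["amplitude"].value, p["amplitude"].stderr
    if amp_err is not None and abs(amp) < 1.96 * amp_err:
        raise NoExponentialBehaviour(
            "no exponential behaviour: amplitude indistinguishable from 0")
    if amp_err is None and np.allclose(y, y[0]):
        raise NoExponentialBehaviour("no exponential behaviour: flat trace")
    kobs = p["kobs"].value
    if (t[-1] - t[0]) * kobs < 3.0:
        warnings.warn("time span covers less than 3/kobs; "
                      "offset poorly constrained", stacklevel=2)
    errors = {k: (p[k].stderr if p[k].stderr is not None else np.nan)
              for k in ("kobs", "amplitude", "offset")}
    return ExponentialFit(kobs_s=float(kobs), amplitude=float(amp),
                          offset=float(p["offset"].value), errors=errors,
                          residuals=np.asarray(result.residual),
                          redchi=float(result.redchi), result=result)


def fit_pseudo_first_order(series: RateSeries,
                           weighted: bool | None = None) -> RateFit:
    """Linear regression of k_obs on [MDM2]: slope k_on, intercept k_off.

    Weighted (1/err²) when per-point errors are supplied and ``weighted``
    is not explicitly False; unweighted otherwise. Standard errors come
    from the regression. A negative fitted intercept is flagged, never
    clamped.
    """
    c, k = series.mdm2_conc_M, series.kobs_s
    if np.unique(c).size < 3:
        warnings.warn("fewer than 3 distinct concentrations", stacklevel=2)
    if c.max() < 2.0 * c.min():
        warnings.warn("concentration range spans less than 2-fold",
                      stacklevel=2)
    use_weights = (series.kobs_err is not None) if weighted is None else weighted
    if use_weights and series.kobs_err is None:
        raise ValueError("weighted fit requested but no kobs errors supplied")
    X = sm.add_constant(c)
    if use_weights:
        model = sm.WLS(k, X, weights=1.0 / series.kobs_err**2)
    else:
        model = sm.OLS(k, X)
    res = model.fit()
    koff, kon = res.params
    koff_err, kon_err = res.bse
    return RateFit(kon=float(kon), kon_err=float(kon_err), koff=float(koff),
                   koff_err=float(koff_err), weighted=bool(use_weights),
                   negative_koff=bool(koff < 0),
                   meta={"rsquared": float(res.rsquared)
                         if np.isfinite(res.rsquared) else np.nan})


def kd_from_rates(fit: RateFit, monte_carlo: bool = False,
                  n_draws: int = 100_000,
                  rng: np.random.Generator | None = None
                  ) -> tuple[float, float]:
    """K_d = k_off/k_on with propagated error.

    Default propagation is first-order in quadrature,
    σ_Kd = Kd·√((σ_kon/kon)² + (σ_koff/koff)²). With ``monte_carlo=True``
    the error is the standard deviation of koff/kon over Gaussian draws of
    (kon, koff) instead.
    """
    if fit.kon <= 0:
        raise ValueError("kon must be positive")
    kd = fit.koff / fit.kon
    if monte_carlo:
        rng = rng or np.random.default_rng(0)
        kon = rng.normal(fit.kon, fit.kon_err, n_draws)
        koff = rng.normal(fit.koff, fit.koff_err, n_draws)
        good = kon > 0
        return float(kd), float(np.std(koff[good] / kon[good]))
    if fit.koff == 0:
        return 0.0, float(fit.koff_err / fit.kon)
    err = abs(kd) * np.hypot(fit.kon_err / fit.kon, fit.koff_err / fit.koff)
    return float(kd), float(err)
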