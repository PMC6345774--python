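# Methods

This note records the models implemented, the defaults chosen where the
underlying measurements leave a choice open, and what the synthetic
validation does and does not demonstrate.

## Two-state TFE analysis

The helix ⇌ coil equilibrium of a short peptide titrated with
trifluoroethanol is modelled with a free energy linear in cosolvent
percentage, ΔG([TFE]) = ΔG_water − m·[TFE], with K = exp(−ΔG/RT) the
coil→helix equilibrium constant. ΔG_water > 0 therefore means helix is
unfavourable in water, consistent with all fitted peptides having helix
populations below 50%. R = 1.987 cal·mol⁻¹·K⁻¹ and T = 278.15 K (the
5 °C CD temperature) are the defaults, both configurable.

Baselines θ_coil and θ_helix are fitted as constants. Over the short
titration ranges of 13-mers the data cannot resolve TFE-sloped
baselines, and the constant-baseline fit reproduces the derived helix
populations of the measured panel; sloped baselines would be the first
extension to try if residual structure appeared at the extremes.

A fit is reported "sigmoidal" only when the fitted midpoint lies inside
the sampled TFE range and the baseline separation is resolved at 3σ.
Otherwise the water population is withheld entirely rather than
reported with a meaningless error, matching how flat titrations of the
phosphorylated peptides must be treated.

Helix percentages from [Θ]₂₂₂ are clamped to [0, 100] with a warning —
a positive ellipticity (possible for polyproline-II-rich peptides)
reports 0% helix. Note that the printed panel percentages mix rounding
and truncation in the last digit, and the rows whose two-state
population computes far below 1% are tabulated as a 1% floor; the
recomputation tests compare only at printed precision and only where
the arithmetic is resolved.

## Quadratic tight-binding titrations

With the fixed component at a concentration comparable to K_d, the
fluorescence titration follows the exact 1:1 mass-action solution
(quadratic formula). The smaller root is evaluated in its conjugate
form 2·M_T·P_T/(s + √(s²−4·M_T·P_T)), which is immune to the
floating-point cancellation that the textbook form suffers in the
weak-binding limit; the discriminant is additionally clamped at zero.
Equivalence to an explicit free-species solver is enforced at 1e-10
relative tolerance across four orders of magnitude in (K_d, M_T, P_T).

Blank subtraction is a separate preprocessing step applied before
fitting, and absorbance metadata above 0.2 triggers an inner-filter
warning. Replicate curves are fitted jointly with shared parameters. A
fit whose K_d error exceeds K_d, or whose amplitude is unresolved at
2σ, is flagged poorly determined — small-amplitude titrations genuinely
cannot pin K_d.

## Stopped-flow kinetics

Traces are fitted to offset + amplitude·exp(−k_obs·t) with
deterministic starts (rate from the log-linearised early decay, offset
from the tail mean). A trace whose amplitude is indistinguishable from
zero at 95% raises a "no exponential behaviour" error instead of
returning a number — the correct verdict for a non-binding peptide.

The pseudo-first-order line k_obs = k_on[MDM2] + k_off is fitted by
weighted least squares when per-point errors are available (weights
1/σ²), unweighted otherwise; unweighted is the default since the
original analysis does not state a weighting. K_d = k_off/k_on errors
propagate first-order in quadrature, with a Monte-Carlo option.
First-order propagation is accurate when k_on's relative error is small
(K_d is linear in k_off but not k_on); at the ~50% relative errors some
peptides carry, the Monte-Carlo spread is systematically larger and the
quadrature number should be read as a lower bound.

Validity of the pseudo-first-order analysis: the true relaxation rate
of a reversible bimolecular step is k_on([M]eq+[P]eq) + k_off, so at
the minimum 8-fold excess the extrapolated intercept (k_off) carries a
~2% systematic inflation from the k_on·[P]eq term. The cross-module
consistency checks therefore run the probe peptide at 1/16 to 1/48 of
the MDM2 concentration, where the bias is ~1%.

## ITC

The 1:1 isotherm uses exact displacement bookkeeping: each injection of
volume v dilutes both cell species by (1 − v/V₀) and delivers syringe
ligand at v/V₀; the differential heat is ΔH·V₀·([PL]_i − [PL]_{i−1}(1 −
v_i/V₀)). The stoichiometry n multiplies the nominal cell
concentration, so a binding-competent fraction below 1 appears as an
apparent n < 1 when the nominal concentration is taken at face value —
fitting a generator truth with 25% active protein returns n ≈ 0.25, and
conversely fixing n = 1 and floating the active fraction returns 0.25
(the two parameters are exactly degenerate, so only one may float).

Dilution heat is estimated as the mean of the last four injections,
accepted as a plateau only if their spread is under 5% of the full heat
range (explicit plateau indices override). Because a real isotherm
still releases some binding heat at the end of the titration, the
plateau estimate retains a small bias; an optional constant
per-injection offset can be floated in the fit to absorb it. The
default synthetic schedule (200 μl cell at 20 μM, 400 μM syringe, one
0.5 μl + 19 × 2 μl injections, 15 °C) reaches a final molar ratio of
~3.9 precisely so that the saturation plateau the correction relies on
actually exists. The first, small injection is excluded from fitting by
default. A Wiseman c-value (K_A·n·[cell]) outside ~1–1000 flags the
curvature as uninformative.

Decomposition uses R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 288.15 K
(15 °C). The identities K_d·K_A = 1, ΔG = −RT ln K_A and TΔS = ΔH − ΔG
hold to machine precision by construction. Recomputing TΔS from the
printed (ΔH, log K_A) reproduces the panel within 0.03 kcal/mol except
for the phospho-Ser20 row (0.06, printed-input rounding) and the
wild-type row, whose printed −3.23 is internally inconsistent with its
own ΔH and log K_A (recomputes to −2.52); the wild-type TΔS is
therefore excluded from recomputation checks.

## Mechanism simulators

Three schemes are integrated deterministically (LSODA, adaptive,
stiff-capable), with mass conservation of both moieties verified at
1e-9 relative tolerance as a postcondition. The probe signal is total
bound peptide with equal weights for both complex forms of the
induced-fit scheme; a per-species weight vector is configurable since a
tryptophan probe need not weigh an intermediate and a final complex
equally. Apparent dissociation constants referred to total free peptide
and total complex are analytic: k_off/k_on (two-state), ×(1 + k_u/k_f)
(conformational selection), ÷(1 + k_on*/k_off*) (induced fit); the ODE
equilibrium endpoint matches these to 0.1%. Relaxation-rate extraction
delegates to the exponential fitter and flags multi-phasic decays by
residual structure; the eigenvalues of the linearised rate matrix are
available as an independent oracle. Stochastic simulation is out of
scope — the measurements are ensemble-scale.

## Ensembles and free-energy surfaces

Backbones are built from (φ, ψ) with ideal bond geometry (ω = 180°);
only N/Cα/C atoms are placed since downstream consumers need Cα-level
RMSD, R_g and dihedrals. The synthetic generator draws each residue
α-helical (φ=−60°, ψ=−45°) with its prescribed probability, otherwise
uniformly from a coil basin φ ∈ (−180°, −50°), ψ ∈ (60°, 180°) ∪
(−180°, −150°) — the β/PPII region, deliberately disjoint from the
helix window so that dihedral-based assignment is exact.

RMSD uses optimal proper-rotation superposition (Kabsch); R_g uses
uniform masses over the Cα selection — absolute surfaces are not
compared against any external reference, so only internal consistency
matters. The FES is −ln(count/total) on a 50×50 grid by default
(configurable; the original binning is unstated), shifted so the
occupied minimum is zero; unsampled bins are masked rather than given a
sentinel value, forcing downstream consumers to treat missingness
explicitly. A residue-frame is called helical for φ ∈ [−100°, −30°],
ψ ∈ [−67°, −7°]; terminal residues are undefined (NaN), not zero. A
DSSP-style hydrogen-bond criterion would differ in absolute terms;
the window is configurable and absolute agreement with
simulation-derived helicities is not claimed.

## Synthetic data and what the tests show

Noise is i.i.d. Gaussian on the signal for every generator — adequate
for shot-noise-dominated photomultiplier/CD/ITC data at these scales,
and the simplest model consistent with the measurements, which report
no noise statistics. Defaults mirror the study conditions: stopped-flow
peptide 0.125 μM against 1–3 μM MDM2, fluorescence titrations of
0–10 μM peptide into 4 μM MDM2, TFE titrations at 5 °C, ITC at 15 °C.
Per-point noise magnitudes are chosen to be plausible for the
instruments (e.g. 1% of the kinetic amplitude, 0.05 μcal per
injection), not calibrated to reproduce the printed fitting errors.
Random-coil reference shifts are caller-supplied rather than shipped:
the tabulated reference values belong to external compilations.

Passing parameter-recovery tests therefore shows that the estimators
are unbiased and correctly propagate uncertainty under the stated noise
model — not that real traces are free of drift, photobleaching,
inner-filter effects or baseline artefacts, which the generators do not
emulate. The FES and helix-propensity checks validate the machinery on
ensembles with known per-residue helicity; they cannot certify
agreement with molecular-dynamics ensembles, which this package
analyses but does not produce.

Problem sizes used throughout the suites: 200-point kinetic traces,
25-point TFE titrations, 16-point binding titrations, 20-injection
isotherms, 100-seed replicate studies, and 2000-frame ensembles for
binomial checks — sizes typical of the corresponding experiments.
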