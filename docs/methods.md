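# Methods

This note records the models as implemented, the numerical choices, and
what the synthetic-data validation does and does not establish.

## Speciation model

The equilibrium state vector holds four species: flavylium AH⁺, neutral
quinonoid base A, anionic base A⁻ and (E)-chalcone C_E.  The hemiketal
B and (Z)-chalcone C_Z are fast, non-accumulating intermediates for
3-deoxyanthocyanidins (the (E)-isomer is far more stable), so hydration
is represented by a single apparent equilibrium AH⁺ ⇌ C_E + H⁺ with
constant K'h.  Mole fractions are computed from ratios to AH⁺ in
exponent form, shifted by the maximum exponent before exponentiation so
the normalization is finite at any pH in [0, 14].  pH is treated as
exact (buffered measurements) and activity corrections are omitted —
the constants are mixed concentration constants.

`EquilibriumConstants` accepts an optional K_i alongside (pKa₁, pK'h)
and enforces their 5% mutual consistency, since
K_i = 10^(pKa₁ − pK'h) parameterizes the same equilibrium.

The absorbance-vs-pH titration across the A ⇌ A⁻ transition is the
standard two-state sigmoid A(pH) = A_n·(1 + r_A·10^(pH−pKa₂)) /
(1 + 10^(pH−pKa₂)); r_A is the anionic/neutral molar-absorption ratio
at the observation wavelength.  Only this instantaneous two-state model
is implemented: titrations equilibrated long enough for substantial
chalcone formation would need a third state, which the data this
package targets do not resolve.  A flat titration (r_A ≈ 1) leaves pKa₂
undetermined; the fit reports this through the covariance condition
number rather than returning an arbitrary estimate (threshold 1e8).

## Iron-binding models

All colored forms in fast acid-base equilibrium are pooled into a
single ligand species L — no internal protonation states.  Three models
share the CSV trace format (`time_s, A_<nm>`) and a 1 cm path:

* Two-step binding: d[L]/dt = −k_b[Fe][L]; d[FeL₁]/dt = k_b[Fe][L] −
  k_r[FeL₁]; d[FeL₂]/dt = k_r[FeL₁].  Binding is irreversible here;
  reversibility is expressed separately by the equilibrium isotherm,
  mirroring how fast-binding (kinetic) and fast-equilibrating
  (thermodynamic) pigments are analyzed.
* Isotherm: ΔA = Δε·(M_t − [Fe]) with [Fe] the positive root of
  K_b[Fe]² + (1 + K_b(L_t − M_t))[Fe] − M_t = 0.
* Autoxidation: d[Fe²⁺]/dt = −k_autox[Fe²⁺]; the Fe(III) formed binds
  (k_b) in competition with hydration of L (k_h^obs).  For
  metal/pigment ≤ 1 a steady-state variant assumes every Fe(III)
  binds immediately, eliminating k_b (it is unidentifiable there; the
  full-mode fit raises a flag instead of failing).

ODE states are reduced so the conservation laws hold exactly: the
two-step system integrates (FeL₁, FeL₂) and recovers L and Fe by
difference; the autoxidation system integrates (Fe²⁺, LFe, C_E);
the peroxidation system integrates MbFe(IV) and recovers MbFe(III)
from total heme.  Integration uses LSODA at rtol 1e-10 / atol 1e-16
(1e-9/1e-15 for peroxidation, whose absorbances are ~100× larger).

The free-pigment molar absorption ε_L at each wavelength is fixed from
the t = 0 absorbance (A₀/L₀) rather than fitted — the complex and
chalcone coefficients are the unknowns.  For synthetic generation the
defaults are ε_L(470) = 15,000, ε_L(620/630/650) = 0 and
ε_L(375) = 3,000 M⁻¹·cm⁻¹: a strong flavylium band near 470 nm, no
free-pigment absorption in the charge-transfer region beyond 600 nm,
and weak absorption at the chalcone wavelength.  These choices set only
the baseline of the simulated traces, not any fitted rate constant.

Nominal mixing concentrations (e.g. 50 µM pigment) are used as exact.

## HSA-binding model

I_F = f_P·[P]·exp(−ε_L·l·L_t), with the free-protein concentration [P]
from the 1:1 mass-action system L_t = [L](1 + K_b[P]),
P_t = [P](1 + K_b[L]).  The inner-filter exponential is driven by the
*total* ligand concentration (bound ligand absorbs as well), ε_L is the
sum of the ligand absorptions at excitation and emission wavelengths —
a fixed input determined by UV-vis, never fitted — and l = 0.65 cm is
the instrument's mean excitation path at the detection point.  f_P is
fitted per titration.  Both free concentrations come from their own
sign-stable quadratic root (Citardauq form for a positive linear
coefficient, standard form otherwise), so the solution stays accurate
to ~1e-12 even at K_b·C ≫ 1; the same helper backs the iron isotherm.

Chalcone titrations are made on equilibrated solutions that retain
residual colored forms (3:1 chalcone:colored for P1 at pH 7.4, from the
speciation model).  The apparent constant is deconvolved linearly:
K_b,app = f·K_b,chalcone + (1−f)·K_b,colored.  Mole-fraction weighting
is exact for a 1:1 model in the dilute-protein limit and reproduces the
worked numbers (344→368 ×10³ M⁻¹ at f = 0.75) exactly.

## Peroxidation model

States: MbFe(IV), LOOH, LH and the antioxidant sub-unit pool AH_u;
MbFe(III) = Mb₀ − MbFe(IV).  Reactions:

* initiation 1: MbFe(III) + LOOH → MbFe(IV) + LO• (k_i1); LO• abstracts
  H instantly and is absorbed into the radical budget (alcohols make a
  minor contribution and are ignored);
* initiation 2: MbFe(IV) + LH → MbFe(III) + L• (k_i2 = k_i1, tied to
  limit the number of adjustable parameters);
* propagation/termination under radical QSSA: the chain flux is
  r₂·[LH]·√R_i with R_i = k_i1[MbIII][LOOH] + k_i2[MbIV][LH] counting
  one radical per initiation event from both heme steps, and
  r₂ = k_p/√(2k_t);
* inhibition: AH_u + MbFe(IV) → MbFe(III) (k_a = AE·k_i2), with
  [AH_u]₀ = n·AH₀ — an antioxidant of stoichiometry n is modelled as n
  independent one-electron sub-units; n is fitted continuously.

LOOH is consumed by the k_i1 step; A234 = ε_CD·[LOOH] with
ε_CD = 24×10³ M⁻¹·cm⁻¹.  MbFe(IV) is *not* put in steady state — its
build-up over ~1/(k_i1·[LOOH]₀) generates the lag phase.  O₂ is
saturating (open-air assay) and carries no state; heme bleaching and
micelle partitioning are out of model; the antioxidant does not
scavenge peroxyl radicals (hydrophilic phenols act on hypervalent
heme).  LOOH₀ defaults to 1 µM — hydroperoxide contamination of any
PUFA stock — and can be co-fitted in the uninhibited analysis.

A useful early-time reduction (LH, MbFe(III) ~ constant, MbFe(IV)
at its fast quasi-steady level so both heme steps feed radicals):
y = [LOOH] obeys dy/dt = c√y − ky with c = r₂·LH₀·√(2·k_i1·Mb₀) and
k = k_i1·Mb₀, giving √y(t) = c/k + (√y₀ − c/k)·e^(−kt/2).  The full
integration matches this to <2% over the first ~20 s; beyond that,
substrate drift takes over.  Note the √2: once MbFe(IV) reaches its
quasi-steady level, the second initiation channel doubles R_i.

Under the assay conditions the antioxidant intercepts only a modest
fraction of MbFe(IV) (k_a·[AH_u] vs k_i2·[LH] ≈ 0.16 for the worked
example), so (AE, n) perturb the curve weakly and mostly through their
product.  They are nonetheless separable — the depletion trajectory of
AH_u depends on AE alone — but the fit needs care: see "Fitting" below.

## Fitting

One engine serves every model: unweighted pooled least squares over one
or more curves (each point weight 1; weights can be supplied),
`scipy.optimize.least_squares` (trust-region reflective) on parameters
transformed to log space when they must stay positive — no hard bounds,
no boundary pathologies.  Standard errors are linearized Gauss-Newton
values, s²·diag[(JᵀJ)⁻¹] square-rooted and mapped back through the log
transform (SE(p) = p·SE(log p)); they should be read as asymptotic
standard deviations, not bootstrap intervals.  The Pearson correlation
between pooled observed and predicted values is reported as r.  If the
first solve fails or parks a parameter at a bound, three jittered
restarts (fixed seed) are tried and the best objective kept.

Two choices matter for the ODE-embedded fits:

* Finite-difference step: residuals computed through an ODE solver
  carry integration error ~rtol·A, far above machine precision.  With
  the default √ε step, the induced Jacobian noise in weakly-sensitive
  directions (k_r early on; AE and n always) swamps the true gradient
  and the optimizer stalls at spurious points.  All ODE fitters
  therefore use a relative step of 1e-4, large enough for the residual
  change to dominate integration error, small enough for curvature
  error to be negligible.
* Staging and starting values: the two-step fit initializes k_b from
  the half-completion time of the fast phase and the ε's from the early
  plateau and final absorbances; the autoxidation fit initializes
  k_autox from the half-rise of the complex band.  The inhibited
  peroxidation fit runs in two stages — r₂ alone first, then
  (r₂, AE, n) — because r₂ dominates the objective and releasing the
  correlated antioxidant pair from a wrong r₂ invites ridge-walking.

With these in place, every fitter recovers its generating parameters
exactly (to optimizer tolerance) from noiseless data and without
detectable bias at instrument noise (validated over 25–100 replicates
per family).

## Synthetic data

The generator reproduces the study designs: 0.5 s sampling over 2 min
(binding kinetics) or 15 s over 15 min (slow processes) at 50 µM
pigment and iron/pigment 0.5–5; six-point equilibrium titrations;
11-point pH titrations over 6–8; 11-point fluorescence titrations at
2 µM HSA, ligand 0–20 µM; 10 s sampling over 30 min for conjugated
dienes at 0.7 mM linoleic acid, 0.5 µM metmyoglobin, 0.5–7.5 µM
antioxidant.  Noise is additive Gaussian, σ = 0.002 AU on kinetic
traces and 0.005 AU on equilibrium series, and 1% multiplicative on
fluorescence — plausible diode-array and fluorimeter noise levels,
fixed once in the scenario files.  All randomness flows through a
single seed; replicate studies derive independent sub-seeds
deterministically.

What this validates: that the fitters are correct and unbiased for data
generated by the models at realistic noise.  What it does not: model
adequacy for real traces (baseline drift, heme bleaching, stray-light
nonlinearity, pigment oxidation products are all absent), so agreement
here is a necessary, not sufficient, condition for trusting estimates
from an actual instrument.

## Degenerate inputs and diagnostics

Unidentifiable configurations are detected, flagged and reported rather
than silently clipped: flat titrations, isotherms far from saturation
(only K_b·Δε determined), k_r·t_max ≪ 1, truncated peroxidation traces,
sub-stoichiometric autoxidation runs fitted in full mode.  The
covariance condition number (threshold 1e8) and per-parameter standard
errors carry the signal.  Non-convergence sets `converged = False` with
the optimizer message attached; replicate studies count and exclude
such fits explicitly.
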