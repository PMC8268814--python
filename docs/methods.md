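# Methods

## Scope and model

`bilemic` analyses the self-aggregation of ionic (bile-salt type)
surfactants under the closed mass-action model: a single aggregate species
`M_n` in equilibrium with monomers, `n S ⇌ M_n`, `K = [M_n]/[S]^n`. The
model deliberately ignores polydispersity of aggregate size, shell–core
geometry, and activity-coefficient corrections; `n` is treated as a real
number because fits of soft transitions do not resolve integers. All
concentrations are millimolar, so `K` carries the unit mM^(1−n); the gas
constant is fixed at R = 8.314 J mol⁻¹ K⁻¹.

The mass balance `S_tot = [S] + nK[S]^n` is solved for `[S]` by bracketed
Brent iteration. Both `S_tot` and `(S_tot/nK)^(1/n)` bound the root from
above; using the smaller as the bracket end keeps `s^n` finite for any
`n ≤ ~60` and `K` up to ~10³⁰, and the accepted root must satisfy the
balance to a relative residual of 1e-10 (a violation raises an error rather
than clamping). The derivative `d[S]/dS_tot = 1/(1 + n²K s^(n−1))` is
evaluated as a logistic function of `ln(n²K) + (n−1) ln s`, which cannot
overflow.

## The cmc convention

The mass-action model has no sharp cmc, so a criterion must be chosen. The
package defines the cmc as the total concentration at which `d²[S]/dS_tot²`
is extremal — the steepest point of the monomer-vs-total curve, which is
also the midpoint of the sigmoidal ITC heat transition, i.e. the
operational calorimetric cmc. For this model the criterion is closed-form:

```
n²K s*^(n−1) = (n−2)/(2n−1),    cmc = s*·(1 + (n−2)/(n(2n−1)))
```

making `params_from_cmc(n, cmc)` and `cmc_from_params` exact inverses. The
criterion flattens as `n → 2` and is reported as an error there. A
mole-fraction convention (`K = x_cmc^(−n)`, `x_cmc = cmc/55.5 M`) is
available behind the `convention` switch for comparison with literature
that defines `K` that way. Because published tables rarely state which
convention produced their ΔG values, absolute Gibbs energies from refit
data should not be expected to match external tables digit for digit; the
package therefore treats tabulated ΔG as input when regenerating ΔS.

## ITC analysis

A demicellization experiment injects aliquots of micellar solution
(syringe concentration `c_syr`) into buffer. The cell concentration after
injection `i` follows the constant-volume displacement model
`c_i = c_syr(1 − Π_j(1 − v_j/V₀))`. The discrete forward model of the
per-injection heat (kJ per mole of injectant) is

```
h_i = ΔH_dil + ΔH_demic · Δn_i/(v_i c_syr)
Δn_i = V₀·s(c_i) − (V₀−v_i)·s(c_{i−1}) − v_i·s_syr
```

where `s(·)` is the equilibrium monomer concentration and `s_syr` the
monomer content of the syringe load — monomers injected as monomers release
no demicellization heat. This bookkeeping matters: for a soft transition
(n ≈ 10) at `c_syr ≈ 9×cmc`, `s_syr/c_syr` is ~15–20%, so the heat plateau
below the cmc sits at `ΔH_dil + ΔH_demic(1 − s_syr/c_syr)`, not at
`ΔH_dil + ΔH_demic`.

Fitting proceeds in stages:

1. **Linearization.** `x_i = (h_i − ΔH_dil)/ΔH_demic` estimates
   `d[S]/dS_tot`; the ordinate `y_i = d ln(x⁻¹−1)/d ln S_tot` is built by
   nonuniform 3-point central differences on `ln S_tot` (exact for
   quadratics), one-sided at the ends with the endpoint stencils
   down-weighted 0.5 in the line fit. Heats are attributed to the
   arithmetic midpoint of the injection's concentration interval. Points
   with `x` outside (1e-4, 1−1e-4) are dropped and counted. The exact
   identity `y = (n−1)/n + ((n−1)²/n)x` then makes the scatter a line.
2. **Linearity optimization.** `(ΔH_demic, ΔH_dil)` are optimized by
   Nelder–Mead to maximize the weighted r² of that line. The search is
   restricted to the physically meaningful region (enthalpy of the
   plateau-difference sign and magnitude, dilution heat inside the observed
   range, intercept in (0,1), positive slope, x-span ≥ 0.3): outside it,
   high r² can be achieved trivially on a handful of surviving tail points.
3. **Model refinement (default).** The linearization estimates an
   *effective* ΔH_demic scaled by `1 − s_syr/c_syr` and inherits the other
   distortions of the derivative proxy. The final estimate therefore comes
   from nonlinear least squares of the full discrete forward model over
   `(n, ln cmc, ΔH_demic, ΔH_dil)`, initialized from a coarse profile grid
   over `(n, cmc)` — the model is linear in the two enthalpies at fixed
   `(n, cmc)`, so each grid cell costs one linear solve. On noise-free
   synthetic data this recovers the generator's parameters to machine
   precision; `refine=False` gives the pure linearization path with a
   one-shot syringe-monomer correction.
4. **Diagnostics.** The reported line intercept/slope/r² are computed by
   inverting the bookkeeping at the fitted parameters (reconstructing the
   cell monomer profile from the measured heats) so that on clean data they
   agree with `(n−1)/n` and `(n−1)²/n` to a few percent. Both the
   slope-only and intercept-only inversions of `n` are reported; the joint
   estimate minimizes the summed squared *relative* deviations of intercept
   and slope, which weights the two channels comparably. A pair whose
   single-channel estimates disagree by >50% sets a flag and warns but does
   not fail — the intercept channel is very sensitive near 1.

Degenerate inputs: fewer than 10 injections, or fewer than 4 usable
linearization points, raise explicit errors; a heat range below the noise
floor (estimated from successive differences of the final plateau) raises
"no transition", as the cmc is then outside the scanned range. The fit is
deterministic for identical input and options, invariant under a common
rescaling of all heats (the enthalpies scale, `n`, cmc and `K` do not), and
insensitive (<1% in `n`) to dropping the first injection.

## Counterion binding and buffer speciation

`β` is the negative slope of the ordinary least-squares line of
`log₁₀(cmc)` on `log₁₀[Na⁺]` (base-10 logs; natural logs appear only inside
`K_mic` and ΔG). Values outside [0, 1] are flagged as unphysical, never
clamped. Sodium delivered by a carbonate/bicarbonate buffer of total
concentration `c_b` at pH near pKa₂ is `c_b(1 + f)`, with carbonate
fraction `f = 1/(1 + 10^(pKa₂−pH))`; pKa₂ defaults to the thermodynamic
25 °C value 10.33 and is configurable. Ionic-strength corrections are
omitted. The `[Na⁺]^(βn)` contribution to ΔG_demic is reported as a
magnitude, `RTβ|ln[Na⁺]|` (the literal logarithm is negative for sub-molar
sodium).

## Tensiometry

The cmc is the breakpoint of a continuous two-segment line in
`(ln c, γ)`, fitted by least squares: breakpoint candidates are every
interior sample abscissa plus an 8-point in-fill of each admissible
interval (≥3 points per side), each evaluated by a closed-form hinge-basis
linear solve, followed by bounded local refinement of the best interval;
ties break toward the lower concentration. A two-segment fit that does not
beat a single line in a partial F-test (2 extra parameters, α = 0.05) is
rejected as "no breakpoint", as is an exactly collinear curve. A post-break
slope steeper than the pre-break slope is flagged as atypical (micellar
plateaus flatten the curve) but still returned. The estimate is invariant
under affine transforms of γ and equivariant under concentration-unit
changes. No Gibbs-isotherm surface-excess analysis is performed.

## Lipophilicity

Predictors are benchmarked by the mean of squared residuals against
experimental monoanion log P values — `Σ(logP_pred − logP_exp)²/n` with `n`
in the denominator (no n−1); this is the convention that reproduces the
packaged benchmark row. Reliability bands: ≤0.5 reliable, (0.5, 1]
acceptable, >1 not acceptable (boundaries inclusive below). The
log P–cmc calibration `log P = 2.79 − 1.00·log₁₀(cmc/mM)` ships as a
constant because several of its underlying points come from literature cmc
values that are not redistributable; refitting utilities
(`LogPCmcRegression`, `fit_logp_cmc`) are provided for new datasets, and
prediction/inversion are exact inverses of each other.

## Synthetic data

The generators replace the instruments and define the reference study
conditions: 2 µL injections of a 4 mM solution into a 200 µL cell
(38 injections put the cmc crossing mid-titration for the reference truth
n = 10, cmc = 0.45 mM, ΔH_demic = −5 kJ/mol, ΔH_dil = −0.2 kJ/mol),
Gaussian heat noise defaulting to 1% of |ΔH_demic|, carbonate buffer
sodium series 0.0765/0.227/1.06 M, two-segment tensiometry curves
(pre-slope −8 mN m⁻¹ per ln-unit, plateau 53.4 mN m⁻¹, break at 0.4 mM),
and calibration datasets with cmc log-uniform over 0.1–15 mM. Noise on
positive cmc-like quantities is lognormal; on heats and γ, Gaussian. Every
generator is a deterministic function of (seed, settings).

What the generators do *not* emulate: baseline drift and integration error
of raw power traces, slow aggregate-morphology kinetics (tubule formation),
temperature-dependent parameters within one titration, adsorption
depletion in tensiometry, or correlated predictor errors. Passing round
trips therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every instrumental artifact.

## Problem sizes and runtime choices

The test suite uses 38-injection titrations, 50-seed Monte-Carlo recovery
for the ITC fitter (2% heat noise), 100-seed recovery for β (2% lognormal
cmc noise) and the tensiometry breakpoint (0.3 mN m⁻¹ γ noise), and
200-point noise-free grids for the linearization-identity checks. These
sizes make the full suite run in seconds on one CPU while leaving the
Monte-Carlo medians far from their tolerance edges.

## Known limitations

- Absolute ΔG_demic values depend on the `K(n, cmc)` convention; only the
  inflection convention is exactly self-consistent within the package.
- The aggregation number is weakly identified by soft transitions: at 2%
  heat noise its median recovery error (~5–6%) is an order of magnitude
  larger than that of cmc or ΔH_demic.
- The reference thermodynamic table is transcribed from printed, rounded
  values; two of its fifteen rows (cmc 0.220 mM with mole fraction
  3.95×10⁻⁶) are mutually inconsistent with the 55.5 M water molarity that
  the other thirteen rows imply, at about 1.4×10⁻⁸ in mole fraction.
- One aggregate species only; systems forming tubes or vesicles (very
  large apparent `n`, distinct ΔC_P) satisfy the equations but not the
  physical picture behind them.
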