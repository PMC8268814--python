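# bilemic

Demicellization thermodynamics and lipophilicity of bile-salt surfactants.

Bile salts (sodium cholate and its derivatives) are facially amphiphilic
steroids that self-assemble into small micelles. Attaching bulky hydrophobic
or hydrophilic groups at the C3 position of the steroid nucleus shifts both
the critical micelle concentration (cmc) and the octan-1-ol/water partition
coefficient (log P), and the two turn out to be linked by a simple
double-logarithmic law. `bilemic` is a tested analysis pipeline for this kind
of characterization campaign, aimed at physical chemists working with
isothermal titration calorimetry (ITC), drop-volume tensiometry and log P
predictors. Because raw instrument data of this kind are rarely deposited,
the package also ships seeded synthetic generators that emulate every input
with known ground truth, so each fitting stage is validated by round trip.

## The model

Micellization is described by the mass-action equilibrium

```
n S  ⇌  M_n,     K = [M_n]/[S]^n,     S_tot = [S] + n K [S]^n
```

with real-valued aggregation number `n` and equilibrium constant `K`
(mM^(1−n); all concentrations in mM). Differentiating the mass balance gives
the exact identity

```
d ln{(d[S]/dS_tot)⁻¹ − 1} / d ln S_tot  =  (n−1)/n + ((n−1)²/n) · d[S]/dS_tot
```

so an ITC demicellization experiment — whose per-injection heats, after
subtracting the dilution enthalpy and normalizing by ΔH_demic, estimate
d[S]/dS_tot — linearizes to a straight line whose intercept `(n−1)/n` and
slope `(n−1)²/n` both encode `n`. `bilemic` fits `(n, ΔH_demic, ΔH_dil)` by
maximizing the linearity of this transform, then refines
`(n, cmc, ΔH_demic, ΔH_dil)` against the full discrete injection model
(including the monomer content of the syringe load), and derives:

- `K_mic = K·[Na⁺]^(βn)` — counterion-corrected constant (β from a
  Corrin–Harkins plot, `log cmc = A − β log [Na⁺]`);
- `ΔG_demic = (RT/n) ln K_mic`, `ΔS_demic = (ΔH − ΔG)/T`;
- `ΔC_P,demic` — the ordinary-least-squares slope of ΔH_demic vs T;
- cmc from tensiometry via continuous two-segment regression of γ on ln c;
- the lipophilicity calibration
  `Virtual log P = −1.00·log(cmc/mM) + 2.79  (r² = 0.948)`,
  plus predictor benchmarking by mean squared residual
  `Σ(logP_pred − logP_exp)²/n`.

The regression-shaped stages are scikit-learn style estimators
(`DemicellizationEstimator`, `CorrinHarkinsRegression`,
`SegmentedBreakpointRegression`, `LogPCmcRegression`) with plain-function
wrappers.

## Worked example

Simulate one titration at the reference conditions (n = 10, cmc = 0.45 mM,
ΔH_demic = −5 kJ/mol, ΔH_dil = −0.2 kJ/mol, 2 µL injections of a 4 mM
solution into a 200 µL cell, 2% heat noise) and fit it back:

```python
from bilemic import synthetic, fit_demicellization, predict_logp_from_cmc

truth = synthetic.default_truth(noise_sd=0.1, seed=7)
series = synthetic.gen_itc_experiment(truth)
fit = fit_demicellization(series)
print(f"n          = {fit.n:.2f}   (truth 10.00)")
print(f"cmc        = {fit.cmc:.3f} mM (truth 0.450)")
print(f"dH_demic   = {fit.dH_demic:.2f} kJ/mol (truth -5.00)")
print(f"dH_dil     = {fit.dH_dil:.2f} kJ/mol (truth -0.20)")
print(f"K          = {fit.K:.3e} mM^(1-n)")
print(f"log P(cmc) = {predict_logp_from_cmc(fit.cmc):.2f}")
```

prints

```
n          = 9.23   (truth 10.00)
cmc        = 0.447 mM (truth 0.450)
dH_demic   = -5.04 kJ/mol (truth -5.00)
dH_dil     = -0.22 kJ/mol (truth -0.20)
K          = 5.277e+00 mM^(1-n)
log P(cmc) = 3.14
```

The aggregation number is the softest parameter (the heat curve constrains
it only through the transition width), while cmc and the enthalpies are
recovered to about 1%. The last line converts the fitted cmc into a
lipophilicity estimate through the packaged calibration line.

The same stages are available from the shell:

```sh
bilemic simulate-itc --seed 7 --out itc.csv --meta-out itc.json
bilemic fit-itc itc.csv --meta itc.json
bilemic tensio-cmc gamma.csv
bilemic corrin-harkins buffers.csv
bilemic score-predictors
bilemic logp-cmc --predict-logp 0.336
bilemic run-all --out report.json
```

`run-all` regenerates everything derivable from the packaged reference
tables (entropies, mole fractions, heat capacities, mean aggregation
numbers, the six predictor residuals) and runs the seeded synthetic round
trips, writing one deterministic JSON report.

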