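# chemoflux

Analysis toolkit for glucose-limited chemostat multiomics of *Saccharomyces
cerevisiae*: how the proteome is re-allocated as cells grow faster, where
the Crabtree switch sits, how fluxes relate to enzymes, metabolites and
phosphosites, and how much of each enzyme the metabolic network actually
needs.

It is written for systems biologists who have steady-state omics tables
(proteome, transcriptome, phosphoproteome, metabolite fold-changes) plus
chemostat physiology, and who want the full analysis chain as tested,
reusable code. A seeded synthetic-data generator reproduces the statistical
structure of such a study, so every stage is verifiable end to end without
any downloads.

## What it computes

**Allocation growth laws.** Functional-group mass fractions
f(g, c) = Σ_{i∈g} w_i x_ic / Σ_i w_i x_ic are regressed on the specific
growth rate μ (= dilution rate D at steady state). The ribosomal growth law
is the linear relation f_r = 0.35 μ + 0.13; groups that change behavior at
the critical rate get a two-segment piecewise fit with the breakpoint
either fixed or found by exhaustive grid search. The critical rate itself
is detected as the smallest μ with non-zero ethanol secretion, and the
respiratory quotient RQ = q_CO₂/|q_O₂| marks the respiratory →
respirofermentative transition.

**Quantification calibrations.** iBAQ (intensity / theoretically
observable peptides), log–log OLS against spike-in amounts, H/L
median-ratio normalization, mass fraction → copies-per-cell conversion
(13 pg cells), and FPKM → molecules/cell calibration with fold-change
propagation.

**Flux analysis.** FBA and FVA by linear programming on a JSON-schema
stoichiometric model (a mass-balanced ~25-reaction toy network of
glycolysis, fermentation, lumped TCA and oxidative phosphorylation ships
with the package). GECKO-style enzyme constraints cap each flux at
kcat·u_e, bound measured enzymes at mean + 1 SD, average complex subunits,
and put unmeasured enzymes on a shared mass pool
(protein content − measured mass) × f × σ with f = 0.4461 g/g and σ = 0.49.
Enzyme usage = required / measured abundance; models that cannot reach the
observed growth are flexibilized by doubling the bound of the
largest-shadow-price enzyme.

**Loglinear thermokinetics.** The model
j_c = J⁰/e⁰ + Σ_i a_i ln(X_ic/X_i0) links enzymatic specific flux to
metabolite ratios; the *intrinsic turnover numbers* a_i (dimension of
kcat; positive = activation, negative = inhibition) are inferred by
adaptive-Metropolis MCMC under a likelihood that integrates the normal
deviation model over each condition's FVA interval. Convergence is checked
with the Gelman–Rubin statistic.

**Regulation.** Hierarchical enzyme regulation coefficients
ρ_e = Δln e / Δln J (0.5 < ρ_e < 1.5 ⇒ flux set mainly by enzyme
abundance), growth-rate trend tests for phosphopeptides, and functional
phosphorylation events (FPE) called from the sign of the correlation
between phospho and flux fold-changes, screened at BH-FDR < 0.05.

## Worked example

```python
from chemoflux import synthdata, allocation

series = synthdata.generate_chemostat_series(seed=1)      # 9 steady states
prot = synthdata.generate_proteome(series, cv_noise=0.0, seed=2)
frac = allocation.compute_group_fractions(
    prot.table, prot.categories, weights=prot.mol_weights)
fit = allocation.fit_linear_allocation(
    frac.loc["translation"].to_numpy(), series.mu)
seg = fit.segments[0]
print(f"slope {seg.slope:.3f}, intercept {seg.intercept:.3f}, "
      f"r = {seg.pearson_r:.3f}")
print(allocation.detect_critical_rate(series))
```

prints

```
slope 0.350, intercept 0.130, r = 1.000
{'critical_rate': 0.28, 'decoupling_rate': 0.28}
```

i.e. the translation-group mass fraction follows the ribosomal growth law
exactly on noiseless data, and the Crabtree switch is detected at
0.28 h⁻¹ — the first sampled rate with aerobic ethanol secretion.

The full study is the numbered scripts in `analysis/` (run them in order;
`01_simulate.py` writes the tables every later stage reads, outputs land
under `results/`). The same stages are also available as a CLI
(`chemoflux simulate|allocate|flux|thermokin|run`).

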