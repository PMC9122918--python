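# Methods

This note records the models implemented in chemoflux, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Chemostat physiology generator

At steady state the specific growth rate μ equals the dilution rate D. The
default grid is nine rates evenly spaced on 0.025–0.4 h⁻¹ with the interior
point nearest the critical rate snapped onto it (experimenters deliberately
sample the Crabtree switch; this also makes "first rate with ethanol" a
well-defined grid value). Exchange rates are phenomenological:

* glucose uptake −(11.0 μ + 0.15) mmol·gDW⁻¹·h⁻¹ (linear Herbert–Pirt
  shape; ~1.3 mmol·gDW⁻¹·h⁻¹ at μ = 0.1);
* oxygen demand 8.0 μ + 0.5, capped at its value at the critical rate —
  the cap is what makes the faster conditions respirofermentative;
* ethanol secretion 0 below the critical rate and
  0.5 + 40 (μ − μ_crit) at and above it. The small onset value encodes
  that the critical rate is *operationally* the first sampled rate at
  which overflow is observed; a strictly continuous onset would make the
  switch undetectable on its own grid point;
* CO₂ equals |q_O₂| exactly below the decoupling rate (RQ = 1 to machine
  precision), and above it gains the fermentative CO₂ (equimolar with
  ethanol) plus a small decoupling excess, so RQ > 1 from the decoupling
  rate onward. The decoupling rate defaults to the critical rate but can
  be set earlier.

Multiplicative log-normal noise (CV 2%) is applied jointly to O₂/CO₂ and
to glucose so that RQ = 1 is preserved exactly under respiration. Cell
mass is 13 pg; protein content is (0.44 + 0.20 μ) g/gDW, i.e. 0.46 g/gDW
at the 0.1 h⁻¹ reference.

## Proteome allocation

Each functional group follows a piecewise-linear mass-fraction law in μ.
Defaults: translation 0.35 μ + 0.13 over the whole range; mitochondria
+0.20 below the critical rate and −0.14 above; amino acid biosynthesis
rising (slope 0.15) to a 13% plateau at the critical rate; glycolysis
−0.15 then constant; chaperones −0.10 then constant; lipid metabolism
constant then −0.02; four further constant housekeeping groups; "other"
absorbs the remainder, for 11 categories total. Where only some of these
numbers are experimentally established, the remaining slopes are plausible
magnitudes and all are configurable.

Group mass is split over proteins by a log-normal relative composition
(σ = 2.0 natural-log units, matching the several-orders-of-magnitude
abundance span of real proteomes) that is constant across conditions, so
noiseless tables invert exactly: molecular-weight-weighted group fractions
of the emitted copy numbers equal the law predictions to machine
precision. Molecular weights are log-normal around 50 kDa (σ = 0.25).

Piecewise fits use exhaustive grid search over interior μ values (exact
and cheap at n ≤ 9); ties resolve to the smallest breakpoint. A condition
sampled exactly at the breakpoint belongs to both segments, which is the
correct reading of a continuous piecewise law. Pearson r on zero-variance
input is reported as undefined (None), not 0, to surface degenerate fits.

## Transcriptome coupling

Per gene g, a fixed protein/mRNA log-ratio offset r_g ~ N(5.0, 2.1²)
(natural log) spans the wide ratio range seen in yeast, and

    ln m_gc = p̄_g − r_g + ρ (ln p_gc − p̄_g) + √(1−ρ²) s_g z_gc

gives within-gene (ln m, ln p) correlation exactly ρ (default 0.72). The
pooled R² of log protein on log mRNA then follows the variance
decomposition R² ≈ V_p / (V_p + σ_r² + V_η) with V_p the pooled log-protein
variance; the default offset σ_r = 2.1 was fixed from this formula so that
the default study yields a pooled R² ≈ 0.52, and is not revisited. No
translation-efficiency mechanism is simulated — downstream statistics need
only the correlation structure.

## Phosphoproteome

Peptides in trend-bearing categories decay (or rise) exponentially in μ
over the respiratory range, spanning a factor e by the critical rate, and
hold their level above it; defaults give 70% of glycolytic and chaperone
peptides a decreasing trend. Intensities carry 5% log-normal noise.

## Thermokinetic model and inference

The loglinear model j_c = J⁰/e⁰ + Σ a_i ln(X_ic/X_i0) treats the intrinsic
turnover numbers a_i as condition-independent; the reference condition
(index 0) has all ratios exactly 1. Residual variance is
δ² = Σ_c (j_pred − j_obs)² / (n − I) and the likelihood term per condition
integrates the N(j_pred, δ²) deviation model over the FVA interval of the
specific flux:

    log[(Φ(j_upper) − Φ(j_lower)) / (j_upper − j_lower)]

computed in log-space with tail reflection so both far tails are stable;
a zero-width interval degenerates continuously to the normal log-density.
δ² is floored at 1e-12 to keep exact fits finite.

The prior is the same Normal for every a_i, mean = mean_c(j_obs) and
variance = std_c(j_obs)² (the standard-error variant std²/n is an option).
Note a consequence of this prior: it is centered on the observed specific
flux, which is coherent because the derivation itself makes j⁰ a linear
combination of the a_i (j⁰ = Σ a_i ln(X_i0/X_i*)); the random-truth
generator therefore derives j⁰ from the drawn a_i and log equilibrium
displacements ~N(0,1), keeping turnover numbers and specific fluxes on a
common scale. Synthetic problems whose j⁰ is drawn independently of the
a_i can put the truth many prior SDs from the prior mean and are not
faithful to the model's own thermodynamics.

Sampling is adaptive Metropolis: Gaussian random-walk proposals, per-chain
scale adapted every 50 steps toward acceptance 0.234 during burn-in and
frozen afterwards (kept samples therefore satisfy detailed balance); all
chains run vectorized. The desk protocol is 4 chains × 5,000 kept samples,
thinning 5, burn-in 1,000 (≈ 10⁵ posterior evaluations, a few seconds per
reaction); longer protocols are a flag away. Convergence is the
Gelman–Rubin statistic (between/within-chain variance; values below 1 are
finite-sample noise and floored at 1.0) with threshold R̂ < 1.1;
unconverged posteriors are returned flagged and refuse effect
classification. Effects are called from the 95% equal-tailed credible
interval: entirely positive = activation, entirely negative = inhibition.

## Flux modeling

LP is scipy's HiGHS with dense matrices (ample for the toy scale; swap in
sparse structures for genome-scale work). Exchange fluxes are negative for
uptake. FVA fixes the growth rate to the measured/optimal value by
default; a fraction-of-optimum convention is available through the same
`fixed` mechanism. Solver tolerance 1e-9; degenerate alternate optima are
accepted — only FVA intervals are contract-stable.

The toy network: 10-step EMP glycolysis, pyruvate decarboxylase + alcohol
dehydrogenase fermentation branch, a glycerol branch as the anaerobic
redox valve, lumped TCA (pyruvate → 3 CO₂ + 4 NADH + 1 ATP, FADH₂ folded
into NADH), lumped oxidative phosphorylation with P/O = 1.5, NGAM fixed at
0.7 mmol ATP·gDW⁻¹·h⁻¹, and a biomass reaction consuming 5 G6P + 5 pyruvate
+ 40 ATP and net-producing 2 NADH (as yeast biomass equations do). Water,
phosphate and protons are omitted. The respiratory optimum is analytic:
ATP yield 19 per glucose, so v* = (19 q_glc − NGAM)/172 at glucose bound
q_glc — the test suite checks FBA against this closed form and against an
independent LP solver.

Enzyme constraints require annotated reactions to be irreversible (the
standard construction splits reversible reactions; the toy model's
annotated reactions are all irreversible and a clear error is raised
otherwise). Measured enzymes are capped at mean + 1 SD; complexes at the
average of their measured subunits; everything else shares the pool
(protein_content − measured mass) × f × σ with f = 0.4461, σ = 0.49 and
protein content 0.46 g/gDW. Because enzyme variables are degenerate at the
flux optimum, a second LP stage fixes the optimum and minimizes total
enzyme mass, so reported amounts are requirements (parsimonious usage, the
convention enzyme-constrained models use). Flexibilization interprets
"relax until the model grows" as: double the cap of the enzyme with the
largest shadow price in the growth-maximizing LP, iterate, log every
change; rule and factor are configurable. GAM fitting is a bisection on
the biomass ATP coefficient matching measured glucose uptake — an
interpretation, flagged as such.

## Statistics

Spearman correlations use average ranks; for n ≤ 9 without ties the exact
permutation p is used (the t-approximation is weak there; the null
distribution is enumerated once per n and cached), with the
t-approximation otherwise. FDR is Benjamini–Hochberg throughout.
Enrichment is the one-sided Fisher test via the hypergeometric upper tail.
Records with fewer than 3 complete pairs are suppressed;
pairwise-complete deletion with n recorded handles missing values.

ρ_e is computed on log fold-changes against the slowest-rate reference;
zero or sign-flipping fluxes give an explicit "undefined" classification.
Only ρ_e is computed; the metabolite/transcript/phosphorylation
coefficients are reserved fields without an implemented formula. FPE calls
add a BH significance screen (disable with `require_significance=False`)
so that sign is not called on noise.

The translation-rate estimate k = (μ/3600) · total residues / ribosome
count (ribosomes = translation-group residues / 12,000) deliberately
ignores the active-ribosome fraction and is labelled approximate; it is a
consistency check, not a calibrated quantity.

## What the generator does not emulate

No sequencing reads or spectra, no growth dynamics (steady states only),
no translation-efficiency mechanism, no kinase–substrate network, no
thermodynamic constants. Passing tests therefore demonstrate that the
analysis chain recovers planted structure of the kinds listed above — they
do not validate instrument-level error models or the biology of any
particular dataset.

## Problem sizes

The default test and acceptance runs use 9 conditions, 30 proteins per
functional group (227 per group, ~2,500 genes, for the pooled
mRNA–protein statistics), 20 random kinetic problems with I ≤ 3
metabolites, and the 24-reaction toy network. These sizes keep every
stage exact or statistically stable while remaining interactive.
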