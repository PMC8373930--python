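# Methods

## Thermodynamic model

The package assumes reversible two-state folding. The free energy of folding
at temperature *T* (K) and denaturant concentration *D* (M GuHCl) is

ΔG_f(T, D) = ΔH_m (1 − T/T_m) + ΔC_p (T − T_m − T ln(T/T_m)) + m·D,

the Gibbs–Helmholtz expression anchored at the zero-denaturant melting
temperature plus a linear-extrapolation denaturant term. Conventions and
assumptions:

- **Folding signs.** ΔG_f and ΔH_m are folded-minus-unfolded: negative for a
  stable, cooperative folder; m > 0 so denaturant destabilises. The
  unfolding convention is never used internally.
- **R = 0.008314 kJ mol⁻¹ K⁻¹**; temperatures are Kelvin internally, °C in
  data files (instrument convention, 273.15 offset on read/write).
- m is temperature-independent and ΔG_f is linear in D over the 0–7 M range;
  ΔH_m and ΔC_p carry no denaturant dependence. One value of each per
  variant.
- Because ΔC_p < 0 the stability curve has a maximum at
  T_s = T_m·exp(−ΔH_m/(T_m ΔC_p)) and predicts cold denaturation; the
  apparent-T_m solver deliberately returns the *heat*-denaturation root
  (bracketed above T_s) and raises a no-transition error when the protein is
  unfolded at all temperatures for the given D.

The unfolded fraction is the logistic link f_U = 1/(1 + exp(−ΔG_f/RT)):
exactly ½ wherever ΔG_f = 0, which defines both the denaturant midpoint
[D]₅₀%(T) = −ΔG_f(T, 0)/m and the apparent melting temperature T_m,app(D).

## Signal model

Measured fluorescence is F = B_N(1 − f_U) + B_U f_U with each state baseline
affine in temperature and denaturant,
B_X(T, D) = a_X + b_X·(T − 273.15) + c_X·D. The baseline form is a package
choice (standard practice for nanoDSF global fits; it keeps 6–16 series
identifiable with few parameters). Temperature slopes act on the Celsius
scale so intercepts stay on the order of the measured signal over a
15–95 °C ramp. Denaturant slopes are on by default and can be disabled
(`FitOptions.baseline_d_slopes=False`). Normalisation to a
degree-of-unfolding scale inverts the fitted baselines,
(B_N − F)/(B_N − B_U), and refuses baseline separations below a configurable
floor (default 10⁻⁸ signal units) rather than dividing by ~0; values outside
[0, 1] on noisy data are reported unclipped.

## Global fitting

All series of a variant enter one unweighted least-squares objective
(uniform σ per point — the modelled instrument export carries no per-point
uncertainties). Replicates share thermodynamic parameters and get their own
baselines. Numerical choices:

- Optimiser: trust-region reflective least squares (lmfit/scipy) with
  ftol = xtol = gtol = 10⁻¹² and a 500-iteration budget; bounds keep the
  search in the folding-sign regime (T_m ∈ [273, 420] K, ΔH_m ∈ [−1500, −1],
  ΔC_p ∈ [−30, 1], m ∈ [0.05, 40]).
- Multi-start: 5 seeded restarts jittered around the initial guess (±2 K on
  T_m, 5% multiplicative on the other thermodynamic parameters, a few
  percent of the transition amplitude on baselines); best SSR wins, ties go
  to the first index.
- Initial guesses: T_m from the extremum of the smoothed (Savitzky–Golay)
  dF/dT on the lowest-denaturant series; baselines from straight-line fits
  to the first and last 15% of that same series — the lowest-D series is
  used for both ends because at high denaturant the low-temperature end of a
  curve is already unfolded, so per-series end-fits would mix states.
  Generic starts for ΔH_m (−300), ΔC_p (−4) and m (8). A series
  indistinguishable from a straight line raises a no-transition error.
- Covariance: (JᵀJ)⁻¹·σ̂² with σ̂² = SSR/dof; a singular Jacobian
  (e.g. coincident baselines) raises a degenerate-fit error. Derived
  quantities (ΔG_f(T), [D]₅₀%(T), T_m,app(D), or any user callable) get
  delta-method errors from central-difference gradients over the
  thermodynamic block of the full covariance.
- Masking: rectangular exclusion windows in (T, D) support cases like
  aggregation above 50 °C at low denaturant; masked points simply leave the
  objective.

Joint fits group datasets by variant label and either estimate a single
shared m across variants or fix m at a supplied value. Both readings of a
"common m-value" analysis are exposed; the default pipeline averages the
fitted m-values of the variants of interest and fixes m at that average
(reported at one-decimal precision), which is the reanalysis that produces
the common-m ΔΔG_f column of the reference table. Fixing m removes its
variance from every derived quantity, so common-m standard errors are
smaller than free-fit ones and the two sources must not be mixed — stability
records carry a `source` tag and the cycle operations refuse mixed sources.

## Double-mutant cycles

ΔΔG_f = ΔG_f(variant) − ΔG_f(reference) at 298 K (configurable), and the
coupling energy is ΔΔΔG_f = ΔΔG_f(double) − ΔΔG_f(single 1) − ΔΔG_f(single 2).
Errors combine in quadrature assuming independent Gaussian records — this
reproduces the published ±0.4 and ±0.2 couplings exactly and is validated
against Monte Carlo propagation in the tests. Correlations induced by a
shared reference within one joint fit are ignored by the quadrature rule
(a slightly conservative choice). Report tables round half-away-from-zero to
one decimal.

Comparisons with external ΔΔG predictions (e.g. FoldX, Rosetta, sequence
models in arbitrary units) are Pearson correlations over label-matched
records with a fitted line; a minimum overlap of three variants is enforced
and unmatched labels are reported.

## Synthetic experiments

The generator emulates the published design: 13 GuHCl levels evenly spaced
over 0–5 M (configurable 6–16 levels over 0–7 M), a 15–95 °C ramp sampled
every 0.5 °C, and additive i.i.d. Gaussian noise. Defaults and what they
represent:

- **Noise σ = 1% of the mid-range transition amplitude.** No instrument
  noise figure is available; 1% gives a ΔG_f(298 K) reproducibility
  (SD ≈ 0.15 kJ/mol over 20 seeds on the wild-type truth) comfortably inside
  the pooled experimental reproducibility of 1.2 kJ/mol, which replicate
  scatter in real data must also absorb.
- **Truth baselines (1000, −2, 0 / 600, −1, 20 signal units)**: a
  well-separated, realistically sloped fluorescence transition.
- **0.5 °C read spacing** keeps fits well-conditioned; several analyses and
  tests use 1 °C for speed at no loss of structure (the drivers state the
  grid they use).
- Determinism: each series draws from an independent substream spawned from
  the design seed; a four-corner cycle simulation spawns one stream per
  dataset from a master seed. Identical seeds are bit-identical.

What the generator does *not* emulate: autocorrelated instrument drift,
aggregation artefacts (handled by masking, not modelled), photobleaching,
and between-replicate systematic shifts. Passing recovery tests therefore
demonstrates correctness of the estimator under the stated noise model, not
robustness to every real-data pathology.

## Design notes and limitations

- The reference table's ΔG_f values are treated as consistent with both
  readings (direct fit parameter vs post-hoc Gibbs–Helmholtz evaluation at
  298 K): re-evaluating ΔG_f(298 K) from the printed (T_m, ΔH_m, ΔC_p)
  reproduces all 26 printed values within their standard errors
  (`analysis/01_reference_stability_table.py`).
- The synthetic common-m reanalysis of wild-type vs L49I/I57V lands at
  ≈ −3.8 kJ/mol only when m is fixed at the averaged common value; jointly
  *estimating* a shared m over just these two variants gives ≈ −3.6 because
  their individual m-values (8.2, 7.9) straddle the six-variant average.
  Both procedures are available; the drivers use the fixed-average default.
- Out of scope: three-state or aggregation-coupled models, Bayesian
  posterior sampling, heteroscedastic noise, model selection (misfit shows
  up only in residual diagnostics), and recomputation of external stability
  predictors.
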