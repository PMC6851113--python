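# Methods

This note documents the models, estimators and numerical choices behind
`microtherm`, the assumptions they make, and what the synthetic-data
tests do and do not establish about real data.

## Models

**Sharpe–Schoolfield (thermal-optimum form).** Within a strain, a rate
`B(T)` rises as a Boltzmann–Arrhenius exponential with activation energy
`E` (eV) below the optimum `T_pk` (K), and falls above it at a rate set
by the deactivation energy `E_D > E`:

```
B(T) = B0 · exp(−E/k (1/T − 1/T_ref)) / (1 + E/(E_D−E) · exp(E_D/k (1/T_pk − 1/T)))
```

The peak rate has the closed form
`P_pk = B0 · exp(−E/k (1/T_pk − 1/T_ref)) · (E_D−E)/E_D`, which is also
the global maximum of the curve (property-tested against a dense grid
search). `k = 8.617e−5 eV/K` is a fixed constant, never a parameter.
The reference temperature defaults to `T_ref = 273.15 K`: low enough to
sit below essentially every observed optimum, keeping `B0` interpretable
as a baseline rate. It is overridable in `FitConfig`.

**Units.** Temperatures are Kelvin internally and degrees Celsius only
at the I/O boundary; rates are s⁻¹ internally (ingest converts h⁻¹,
min⁻¹, day⁻¹ and doubling times via `μ = ln 2 / t_d`). Absolute `B0`
values therefore depend on this unit convention; activation energies do
not.

**Boltzmann–Arrhenius.** Across strains, peak coordinates
`(T_pk, P_pk)` are modelled as `P_pk = B0 e^(−E_L/k T_pk)`. `E_L` is
unconstrained in sign: thermophile groups can be flat or inverted.

## Per-curve fitting

Ordinary NLLS on the natural rate scale (a log-scale option exists but
is off by default, matching the "ordinary non-linear least squares"
convention), by Levenberg–Marquardt with box bounds. `E_D > E` is
enforced by fitting the offset `dE = E_D − E > 0`; the reported 4×4
covariance is mapped back to the `(B0, E, E_D, T_pk)` basis with the
linear Jacobian. Bounds: `B0 > 0`, `0 < E ≤ 15 eV`, `0 < dE ≤ 50 eV`,
`T_pk` within 10 K of the observed temperature range.

The objective is multimodal, so fitting is multistart: the first start
is data-driven (`T_pk` at the largest observed rate, `E = 0.65 eV`,
`E_D = 3 eV`, `B0` at the rate nearest `T_ref`), and the remaining
`n_multistart − 1` starts jitter those values uniformly ±50%, seeded
per curve from the master seed and the curve id (so fits are
reproducible curve-by-curve and insensitive to dataset ordering).
Minimum 5 distinct temperatures (4 free parameters + 1 residual degree
of freedom); curves below that, with no positive rate, or with no
converging start are returned with a machine-readable exclusion reason
rather than dropped.

**Peak detection.** A curve informs the inter-specific analysis only if
its fitted `T_pk` lies strictly inside the observed temperature range
and the largest observed rate is not at the hottest measured
temperature; otherwise the peak is an extrapolation and the curve is
excluded from the peak-based analysis only.

**Uncertainty propagation.** 1000 parameter vectors are drawn from a
multivariate normal at the point estimates with the fit covariance;
draws violating model validity (`E ≤ 0`, `E_D ≤ E`, `B0 ≤ 0`,
non-finite `P_pk`) are discarded (simplest defensible choice — no
reflection or truncation), and the standard deviations of the surviving
draws' `E` and recomputed `P_pk` give `SD_E` and `SD_Ppk`. If fewer than
half the draws survive the fit is flagged `unstable_covariance`; fits
with no covariance at all are flagged and excluded from weighting.
Sampling the full 4-parameter vector (rather than a 2-D marginal of `E`
and the derived `P_pk`) is the well-defined realisation of
covariance-aware sampling, since `P_pk` is not itself a fit parameter.
Weights are `w = 1/(SD + 1)`, mapping zero uncertainty to 1 and decaying
smoothly — noisy fits are downweighted, not discarded.

**Replicates.** Pseudoreplicates (same strain, study and growth
conditions) are pooled into one curve before fitting. Same-species
eukaryote replicates are fitted individually and the smallest-AIC fit
retained (AIC from RSS and n with 4 parameters; ties prefer more points,
then the lexicographically first id).

## Group-level inference

`Ē_S` is the weighted arithmetic mean of per-curve `E`; `E_L` comes from
weighted NLLS of the Boltzmann–Arrhenius law through the group's peaks
(squared residuals × `w_Ppk`, natural scale), initialised from the
weighted log-linear fit. Both get percentile bootstrap CIs (2.5th/97.5th
of 1000 resamples by default), resampling `(E, w)` pairs or
`(T_pk, P_pk, w)` triplets respectively and re-estimating each time.

**Verdicts.** Overlap between two CIs is quantified as
`len(intersection) / len(shorter interval)`. The decision rule, in
order: `E_L` CI containing 0 → *equalisation*; overlap ≥ 0.5 →
*hotter_is_better*; 0 < overlap < 0.5 → *ambiguous*; disjoint with
`E_L < Ē_S` → *partial_constraint* (disjoint the other way is flagged
`super_arrhenius`). The 0.5 threshold operationalises "significant
overlap" and is configurable. Ties at the mesophile/thermophile boundary
classify as mesophile; no lower bound separates psychrophiles.

**Break point.** On Arrhenius coordinates `x = 1/(kT_pk)`,
`y = ln P_pk`, a continuous two-segment (hinge) model is profiled over
candidate break temperatures on a 0.1 °C grid between the 3rd-smallest
and 3rd-largest observed optima (extremes excluded so neither segment is
degenerate); the minimum-RSS break is tested against the single line by
an F-test with 2 numerator degrees of freedom at α = 0.05. Because the
break is profiled, this test's type-I error is somewhat above nominal;
it is used as the splitting heuristic it is meant to be, not as a
calibrated significance statement. Requires ≥ 8 peaks spanning ≥ 15 °C.
Perfectly collinear data (single-line RSS at numerical zero) report no
break.

**Adaptation regression.** `T_pk` on `T_lab` (both °C) by unweighted
OLS, one point per curve, with the 95% slope CI and a flag for whether
it excludes slope 1 (optima falling short of culture temperature at the
hot end).

## Ecosystem flux model

Night-time ecosystem carbon flux is a biomass-weighted sum of three
Boltzmann–Arrhenius compartments (autotrophic eukaryotes, heterotrophic
prokaryotes, heterotrophic eukaryotes; shares `δ` heterotroph, `β`
prokaryote-within-heterotroph). The warming fold change is
`F_x = F(T+x)/F(T)`; the reported amplification is
`(F_{x,2}/F_{x,1} − 1)·100` against a reference ecosystem with every
compartment at 0.65 eV (the canonical heterotroph value under metabolic
theory). Emergent quantities: biomass-weighted mean energy and
`Q10 = F_{x,2}^{10/x}`. Biomass is held constant over the warming
interval — only mass-specific rates respond.

The compartment normalisation constants are not identifiable from the
model statement, so they are fixed by the convention that all
compartments have equal mass-specific rates at the baseline temperature
(`c_i e^{−E_i/kT_base}` equal). This makes the biomass proportions the
only composition knobs, makes the reference ratio `F_{x,1}` exactly
composition-invariant, and makes the amplification exactly linear in
`δ·β` (both property-tested). Explicit `c_i` overrides are available.
Defaults: `T_base = 293.15 K` (20 °C); short-term scenario `x = 10 K`
(upper end of daily fluctuation) with `E_hp = 0.87 eV` (the mesophilic
bacterial short-term mean); long-term scenario `x = 4 K` (upper
century-scale projection) with `E_hp = 0.98 eV` (the inter-specific
value). At these settings the amplifications are 8.32% and 4.81%, and
the per-percentage-point sensitivity to `β` runs 0.048–0.144% across
`δ ∈ [0.25, 0.75]`. Autotrophic prokaryotes are not modelled (negligible
flux share in the terrestrial ecosystems the defaults describe).

## Synthetic data

The generator emulates the assumed data-generating process: optima
uniform over a configurable range (default 5–45 °C, the mesophile
range); per-strain `E ~ Normal(0.9, 0.15²) eV` (clipped at 0.1);
`E_D = E + 2.5 eV` (sharply peaked curves, as empirical TPCs typically
are); true peak rates `P_pk = A e^{−E_L/kT_pk}` × lognormal(0, 0.3²)
scatter, with `A` anchored so a 300 K-optimum strain peaks at 2×10⁻⁴ s⁻¹
(≈ 0.7 h⁻¹, a typical mesophile maximum); `B0` back-solved so each curve
attains its peak exactly; 7 observation temperatures from `T_pk − 20 K`
to `T_pk + 8 K` (asymmetric, mirroring experimental designs that sample
the falling limb sparsely); multiplicative lognormal observation noise
with sd 0.05. The scenario knob sets the true `E_L`: the mean of `E`
(hotter-is-better), 0 (equalisation), or a third of it (weak
constraint). Culture temperatures come from inverting a linear
adaptation map `T_pk = a + b·T_lab + ε` (defaults `a = 8.2`, `b = 0.88`,
`ε` sd 1.5 °C).

What the generator does **not** emulate: phylogenetic correlation among
strains, heterogeneous temperature designs and digitisation error,
right-skewed `E` distributions, unit heterogeneity across studies, and
real mesophile/thermophile physiology (the mixture fixture builds its
break in by construction). Passing tests therefore establish that the
estimators recover the truth under the assumed generative structure —
not that real datasets satisfy that structure.

Two statistical caveats surfaced by the simulations and worth knowing:

* the percentile bootstrap CI for `E_L` undercovers (≈ 89% rather than
  95% at n = 100, scatter 0.3, as measured by the coverage simulation in
  the test suite) because the natural-scale weighted fit concentrates
  leverage on the hottest strains, so the bootstrap SD underestimates
  the sampling SD by several percent. This is a property of the
  percentile-bootstrap-of-weighted-NLLS procedure itself, not of its
  implementation (the estimator is unbiased); increasing the number of
  bootstrap resamples does not change it. Fitting on the log scale or
  using bias-corrected (BCa) intervals would restore nominal coverage
  at the cost of departing from the standard procedure implemented
  here;
* assigning `T_lab` by inverting the adaptation map makes the
  `T_pk`-on-`T_lab` regression a reverse regression, attenuating the
  slope by `σ_ε²/(σ_ε² + b²·var(T_lab))` — negligible over the full
  prokaryote thermal range, visible over a narrow one. The regression's
  nominal CI coverage is asserted on the forward design.

## Problem sizes and seeds

All randomness flows from explicit integer seeds (per-curve fit seeds
are derived from the master seed plus a CRC of the curve id). Simulation
sizes in the test suite are chosen to characterise the estimators at the
scales they are used at: parameter recovery on 50 noisy curves; `E_L`
CI coverage over 500 ensembles of 100 peaks (300 bootstrap resamples
each); scenario-verdict recovery over 100 seeds with ensembles of 264
(hotter-is-better), 114 (equalisation) and 150 (weak) strains —
mirroring the group sizes such analyses encounter — with 2 optimiser
starts per synthetic curve (their data-driven start is reliable) and
400 bootstrap resamples.

## Known limitations

* The fit bounds (`E ≤ 15 eV`, `T_pk` within 10 K of the observed
  range) are pragmatic, not physical; curves whose optimum lies far
  outside the measured range are excluded by peak detection anyway.
* The break-point F-test is approximate (profiled break); a
  Davies-type correction is not implemented.
* Weighted fits treat the Monte-Carlo weights as fixed constants; the
  bootstrap resamples them jointly with the estimates but does not model
  their own sampling error.
* The flux model's equal-rate normalisation is a convention; with
  measured compartment rates the `c_i` overrides should be used.
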