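# microtherm

Tools for analysing the temperature dependence of prokaryotic growth and
metabolic rates, on two timescales at once: the *short-term* response of a
single strain across its thermal performance curve (TPC), and the
*long-term*, across-strain response that emerges as lineages adapt to
hotter niches. The package is aimed at microbial thermal ecologists who
have rate-versus-temperature tables for many strains and want a tested,
reproducible pipeline from raw observations to a hotter-is-better verdict
and its ecosystem-level consequences.

## What it computes

**Within a strain** — each TPC is fitted with the four-parameter
Sharpe–Schoolfield model (thermal-optimum parameterisation):

```
B(T) = B0 · exp(−E/k · (1/T − 1/T_ref)) /
       (1 + E/(E_D − E) · exp(E_D/k · (1/T_pk − 1/T)))
```

where `E` (eV) is the activation energy of the sub-peak rise, `E_D` the
deactivation energy of the post-peak fall, `T_pk` the thermal optimum and
`k = 8.617e−5 eV/K`. The fit is multistart Levenberg–Marquardt NLLS; the
covariance matrix of each fit is propagated by Monte-Carlo sampling into
standard deviations of `E` and of the peak rate `P_pk = B(T_pk)`, which
become downweights `w = 1/(SD + 1)` for noisy fits.

**Across strains** — peak coordinates `(T_pk, P_pk)` are pooled per group
and fitted with a weighted Boltzmann–Arrhenius model `B = B0 e^(−E/kT)`,
giving the long-term activation energy `E_L`. Bootstrap percentile CIs
for the weighted mean short-term energy `Ē_S` and for `E_L` decide between
three hypotheses: *hotter-is-better* (`Ē_S ≈ E_L > 0`), *equalisation of
fitness* (`E_L ≈ 0`) and a *partial thermodynamic constraint*
(`Ē_S > E_L > 0`). A break-point analysis on the Arrhenius plot of the
peaks locates the mesophile/thermophile transition, and an OLS regression
of `T_pk` on culture temperature `T_lab` checks thermal adaptation.

**Ecosystem scaling** — a three-compartment carbon-flux model (autotrophic
eukaryotes, heterotrophic prokaryotes, heterotrophic eukaryotes, biomass
shares `δ` and `β`) converts the estimated energies into the warming
amplification of ecosystem respiration, an emergent whole-ecosystem
activation energy, and a Q10.

A seeded synthetic-data generator produces strain ensembles under each
generative scenario with a ground-truth table, so the entire pipeline is
testable without any external dataset.

## Worked example

```python
import microtherm as mt

# 1. simulate a hotter-is-better ensemble of 40 strains
cfg = mt.SynthConfig(n_strains=40, scenario="hib", seed=0)
records, truth = mt.generate_strain_ensemble(cfg)

# 2. run the full pipeline (fit -> break point -> group verdicts)
result = mt.run_pipeline(records, mt.PipelineConfig(
    fit=mt.FitConfig(n_multistart=2, seed=0), n_boot=300, seed=0))
g = result.group_results[0]
print(f"{g.label}: n={g.n}  E_S_bar={g.E_S_bar:.3f} "
      f"CI=({g.E_S_ci[0]:.3f},{g.E_S_ci[1]:.3f})  "
      f"E_L={g.E_L:.3f} CI=({g.E_L_ci[0]:.3f},{g.E_L_ci[1]:.3f})  "
      f"verdict={g.verdict}")

# 3. scale the energies up to ecosystem flux under 10 K warming
pct = mt.percent_flux_change(mt.short_term_scenario())
print(f"short-term flux amplification: {pct:.2f}%")
```

prints

```
Bacteria:all: n=40  E_S_bar=0.917 CI=(0.861,0.970)  E_L=0.816 CI=(0.679,0.983)  verdict=hotter_is_better
short-term flux amplification: 8.32%
```

The first line says the ensemble's mean within-curve activation energy is
0.92 eV, the across-strain energy 0.84 eV, and their bootstrap CIs
overlap without covering zero — hotter is better. The second line: an
ecosystem that is 50% heterotroph, half of that bacterial with `E` =
0.87 eV instead of the canonical 0.65 eV, respires 8.3% more extra carbon
under a 10 K short-term warming than a uniform-0.65 eV ecosystem would.

The same stages are available from a shell:

```
microtherm simulate --scenario hib --n 40 --seed 0 --out-dir data/
microtherm analyse data/hib.csv --out-prefix out/hib --seed 0
microtherm ecosystem --scenario long --out out/grid_long.csv
```

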