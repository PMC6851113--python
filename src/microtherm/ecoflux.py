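"""Ecosystem carbon-flux response to warming under mixed thermal sensitivities.

Night-time ecosystem carbon efflux is the biomass-weighted sum of three
respiring compartments — autotrophic eukaryotes (ae), heterotrophic
prokaryotes (hp) and heterotrophic eukaryotes (he) — each following a
Boltzmann-Arrhenius temperature dependence with its own activation
energy.  With delta the heterotroph share of biomass and beta the
prokaryote share within heterotrophs, the fold change in flux after
warming by ``x`` kelvin from baseline ``T`` is

    F_x = [ (1-d) c_ae e^{-E_ae/k(T+x)}
            + d ( b c_hp e^{-E_hp/k(T+x)} + (1-b) c_he e^{-E_he/k(T+x)} ) ]
          / [ same expression at T ]

Biomass is assumed constant over the warming interval — only
mass-specific rates respond to temperature.  Comparing an ecosystem whose
prokaryotes carry an elevated activation energy against a reference in
which every compartment sits at the canonical 0.65 eV gives the
amplification of the warming response attributable to prokaryotic
physiology, expressed as a percentage, an emergent whole-ecosystem
activation energy, and an emergent Q10.

Normalisation convention: the compartment constants ``c_i`` are set so
all compartments have equal mass-specific rates at the baseline
temperature, making the biomass proportions the only composition knobs.
Explicit ``c_i`` overrides are accepted for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import BOLTZMANN_EV

#: canonical heterotroph activation energy expected under metabolic theory
BASELINE_E_DEFAULT = 0.65
#: default baseline temperature (20 degC)
T_BASE_DEFAULT = 293.15
#: warming magnitudes: upper end of daily fluctuation (short term) and of
#: century-scale projections (long term)
X_SHORT_TERM = 10.0
X_LONG_TERM = 4.0
#: prokaryote activation energies estimated for mesophilic bacteria:
#: short-term (within-curve mean) and long-term (across-strain) values
E_HP_SHORT_TERM = 0.87
E_HP_LONG_TERM = 0.98


@dataclass(frozen=True)
class EcosystemScenario:
    """Composition, energies and warming of one model ecosystem."""

    delta: float = 0.5  # heterotroph share of biomass
    beta: float = 0.5  # prokaryote share within heterotrophs
    E_ae: float = BASELINE_E_DEFAULT
    E_hp: float = E_HP_SHORT_TERM
    E_he: float = BASELINE_E_DEFAULT
    T_base: float = T_BASE_DEFAULT  # K
    x: float = X_SHORT_TERM  # K warming
    baseline_E: float = BASELINE_E_DEFAULT
    c_ae: Optional[float] = None  # explicit normalisation overrides
    c_hp: Optional[float] = None
    c_he: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.delta <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("delta and beta must lie in [0, 1]")
        if self.T_base <= 0:
            raise ValueError("baseline temperature must be positive Kelvin")
        if self.x <= 0:
            raise ValueError("warming magnitude x must be positive")
        for name in ("c_ae", "c_hp", "c_he"):
            c = getattr(self, name)
            if c is not None and c <= 0:
                raise ValueError(f"{name} must be positive if given")


@dataclass
class FluxResult:
    F_x_reference: float
    F_x_altered: float
    percent_change: float
    emergent_E: float
    Q10: float


def _compartment_flux(c, E, T):
    return c * np.exp(-np.asarray(E) / (BOLTZMANN_EV * T))


def _normalisation(scenario: EcosystemScenario, E_ae, E_hp, E_he):
    """Compartment constants: explicit overrides, else equal rates at T_base."""
    kT = BOLTZMANN_EV * scenario.T_base
    c_ae = scenario.c_ae if scenario.c_ae is not None else np.exp(E_ae / kT)
    c_hp = scenario.c_hp if scenario.c_hp is not None else np.exp(E_hp / kT)
    c_he = scenario.c_he if scenario.c_he is not None else np.exp(E_he / kT)
    return c_ae, c_hp, c_he


def _flux_at(scenario: EcosystemScenario, E_ae, E_hp, E_he, T):
    c_ae, c_hp, c_he = _normalisation(scenario, E_ae, E_hp, E_he)
    d, b = scenario.delta, scenario.beta
    return (1 - d) * _compartment_flux(c_ae, E_ae, T) + d * (
        b * _compartment_flux(c_hp, E_hp, T)
        + (1 - b) * _compartment_flux(c_he, E_he, T)
    )


def flux_ratio(scenario: EcosystemScenario, use_baseline: bool = False) -> float:
    """Fold change in ecosystem flux after warming, ``F_x = F(T+x)/F(T)``.

    With ``use_baseline=True`` every compartment is set to the scenario's
    uniform ``baseline_E``, giving the reference ratio ``F_{x,1}``; the
    default uses the scenario energies (``F_{x,2}``).  Under the
    equal-rate normalisation the reference ratio is independent of the
    composition (delta, beta) and of any common rescaling of the c's.
    """
    if use_baseline:
        E = (scenario.baseline_E,) * 3
    else:
        E = (scenario.E_ae, scenario.E_hp, scenario.E_he)
    T = scenario.T_base
    return float(
        _flux_at(scenario, *E, T + scenario.x) / _flux_at(scenario, *E, T)
    )


def percent_flux_change(scenario: EcosystemScenario) -> float:
    """Warming amplification attributable to compartment energy differences.

    ``(F_{x,2}/F_{x,1} - 1) * 100`` where ``F_{x,1}`` has all
    compartments at ``baseline_E`` and ``F_{x,2}`` uses the scenario
    energies.
    """
    f2 = flux_ratio(scenario, use_baseline=False)
    f1 = flux_ratio(scenario, use_baseline=True)
    return (f2 / f1 - 1.0) * 100.0


def emergent_E(scenario: EcosystemScenario) -> float:
    """Biomass-weighted average activation energy of the ecosystem.

    ``E = (1-d) E_ae + d (b E_hp + (1-b) E_he)``; always lies between the
    smallest and largest compartment energy.
    """
    d, b = scenario.delta, scenario.beta
    return (1 - d) * scenario.E_ae + d * (b * scenario.E_hp + (1 - b) * scenario.E_he)


def emergent_Q10(F_x2: float, x: float) -> float:
    """Q10 implied by a fold change ``F_x2`` over ``x`` kelvin: F_x2^(10/x)."""
    if F_x2 <= 0:
        raise ValueError("flux ratio must be positive")
    if x <= 0:
        raise ValueError("warming magnitude must be positive")
    return float(F_x2 ** (10.0 / x))


def evaluate_scenario(scenario: EcosystemScenario) -> FluxResult:
    """All headline quantities for one scenario."""
    f2 = flux_ratio(scenario, use_baseline=False)
    f1 = flux_ratio(scenario, use_baseline=True)
    return FluxResult(
        F_x_reference=f1,
        F_x_altered=f2,
        percent_change=(f2 / f1 - 1.0) * 100.0,
        emergent_E=emergent_E(scenario),
        Q10=emergent_Q10(f2, scenario.x),
    )


def composition_grid(
    template: EcosystemScenario,
    delta_range: tuple[float, float] = (0.25, 0.75),
    beta_range: tuple[float, float] = (0.25, 0.75),
    step: float = 0.01,
):
    """Percent change, emergent E and Q10 over a delta x beta lattice.

    Returns a dict of 2-D arrays keyed ``percent_change``, ``emergent_E``
    and ``Q10`` plus the ``delta`` and ``beta`` axis vectors (delta along
    axis 0).  Default ranges cover the plausible span of terrestrial
    ecosystem compositions, 25-75% for both proportions.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    deltas = np.arange(delta_range[0], delta_range[1] + step / 2, step)
    betas = np.arange(beta_range[0], beta_range[1] + step / 2, step)
    if deltas.size == 0 or betas.size == 0:
        raise ValueError("empty composition grid")
    pct = np.empty((deltas.size, betas.size))
    eme = np.empty_like(pct)
    q10 = np.empty_like(pct)
    for i, d in enumerate(deltas):
        for j, b in enumerate(betas):
            s = EcosystemScenario(
                delta=float(d),
                beta=float(b),
                E_ae=template.E_ae,
                E_hp=template.E_hp,
                E_he=template.E_he,
                T_base=template.T_base,
                x=template.x,
                baseline_E=template.baseline_E,
                c_ae=template.c_ae,
                c_hp=template.c_hp,
                c_he=template.c_he,
            )
            r = evaluate_scenario(s)
            pct[i, j] = r.percent_change
            eme[i, j] = r.emergent_E
            q10[i, j] = r.Q10
    return {
        "delta": deltas,
        "beta": betas,
        "percent_change": pct,
        "emergent_E": eme,
        "Q10": q10,
    }


def short_term_scenario(**overrides) -> EcosystemScenario:
    """Daily-fluctuation scenario: 10 K warming, prokaryote E = 0.87 eV."""
    kw = dict(x=X_SHORT_TERM, E_hp=E_HP_SHORT_TERM)
    kw.update(overrides)
    return EcosystemScenario(**kw)


def long_term_scenario(**overrides) -> EcosystemScenario:
    """Climate-change scenario: 4 K warming, prokaryote E = 0.98 eV."""
    kw = dict(x=X_LONG_TERM, E_hp=E_HP_LONG_TERM)
    kw.update(overrides)
    return EcosystemScenario(**kw)
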