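"""Synthetic thermal-performance datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes so
that every pipeline stage can be exercised and validated without any
external data:

* each strain has a unimodal Sharpe-Schoolfield curve observed at a
  handful of temperatures spanning its optimum, with multiplicative
  lognormal measurement noise (rates are positive and span orders of
  magnitude, so noise scales with the signal);
* across strains, peak performance follows a Boltzmann-Arrhenius law in
  the thermal optimum with lognormal scatter — the inter-specific
  activation energy ``E_L`` is the scenario knob: equal to the mean
  intra-specific energy (hotter-is-better), zero (equalisation of
  fitness), or a stated fraction of it (weak/partial constraint);
* culture temperature tracks the optimum through a linear map, mirroring
  the strong adaptation of strains to their growth temperature.

Every draw flows from a single seed; the ground truth (per-strain E,
T_pk, P_pk and the scenario's true E_L) is returned alongside the
records for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import RateObservation, TPCRecord
from .models import BOLTZMANN_EV, T_REF_DEFAULT, SharpeSchoolfieldParams, ss_evaluate

#: reference peak rate (s^-1) anchoring the inter-specific normalisation:
#: ~0.7 h^-1 at a 300 K optimum, a typical mesophile maximal growth rate
P_PK_REF = 2e-4
T_PK_REF = 300.0


@dataclass
class SynthConfig:
    """Generative parameters for a strain ensemble.

    Defaults describe a mesophile-like ensemble: optima uniform over
    5-45 degC, intra-specific energies Normal(0.9, 0.15) eV, deactivation
    energy E + 2.5 eV (sharply peaked curves), 7 observation temperatures
    from T_pk-20 to T_pk+8 K, 5% multiplicative observation noise, and
    lognormal peak-rate scatter with sd 0.3 about the inter-specific law.
    """

    n_strains: int = 100
    scenario: str = "hib"  # hib | equalisation | weak
    t_pk_low_c: float = 5.0
    t_pk_high_c: float = 45.0
    E_S_mean: float = 0.9
    E_S_sd: float = 0.15
    E_D_offset: float = 2.5  # E_D = E + offset (eV)
    ppk_scatter_sd: float = 0.3  # lognormal sd of peak rates about the law
    n_temperatures: int = 7
    temp_span_below: float = 20.0  # K below T_pk
    temp_span_above: float = 8.0  # K above T_pk
    noise_sd: float = 0.05  # multiplicative lognormal observation noise
    weak_fraction: float = 1.0 / 3.0  # true E_L as fraction of E_S_mean (weak)
    tlab_slope: float = 0.88
    tlab_intercept: float = 8.2
    tlab_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.scenario not in ("hib", "equalisation", "weak"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("E_S_sd", "ppk_scatter_sd", "noise_sd", "tlab_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def true_E_L(self) -> float:
        if self.scenario == "hib":
            return self.E_S_mean
        if self.scenario == "equalisation":
            return 0.0
        return self.E_S_mean * self.weak_fraction


def generate_tpc(
    params: SharpeSchoolfieldParams,
    temperatures_k: Sequence[float],
    noise_sd: float = 0.0,
    seed=None,
    curve_id: str = "synth-0",
    **metadata,
) -> TPCRecord:
    """One synthetic curve: model values times multiplicative lognormal noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    T = np.asarray(temperatures_k, dtype=float)
    rng = np.random.default_rng(seed)
    rates = ss_evaluate(params, T)
    if noise_sd > 0:
        rates = rates * rng.lognormal(0.0, noise_sd, size=T.size)
    obs = [RateObservation(float(t - 273.15), float(r)) for t, r in zip(T, rates)]
    meta = dict(strain_id=curve_id, species=f"Synthococcus {curve_id}",
                taxonomy={"kingdom": "Bacteria"}, study_id="synthetic")
    meta.update(metadata)
    return TPCRecord(curve_id=curve_id, observations=obs, **meta)


def _interspecific_amplitude(E_L: float) -> float:
    """Normalisation A of P_pk = A exp(-E_L/kT_pk), anchored at the reference."""
    return P_PK_REF * np.exp(E_L / (BOLTZMANN_EV * T_PK_REF))


def _b0_for_peak(P_pk, E, E_D, T_pk, t_ref=T_REF_DEFAULT):
    """Back-solve B0 so the curve attains P_pk exactly at T_pk."""
    return P_pk * E_D / (E_D - E) * np.exp(E / BOLTZMANN_EV * (1.0 / T_pk - 1.0 / t_ref))


def generate_strain_ensemble(
    config: SynthConfig,
) -> tuple[list[TPCRecord], pd.DataFrame]:
    """Strain ensemble plus ground-truth table.

    Each strain's optimum is uniform over the configured range; its true
    peak rate follows ``A exp(-E_L/k T_pk)`` with lognormal scatter; its
    intra-specific ``E`` is drawn Normal and the curve's ``B0`` is
    back-solved so the Sharpe-Schoolfield curve attains the peak rate
    exactly at the optimum.  Observation temperatures span the peak so
    every curve resolves it.
    """
    E_L = config.true_E_L
    max_E = config.E_S_mean + 6 * config.E_S_sd
    if config.E_D_offset <= 0:
        raise ValueError("E_D rule must keep E_D > E (positive offset)")
    rng = np.random.default_rng(config.seed)
    A = _interspecific_amplitude(E_L)

    records: list[TPCRecord] = []
    truth_rows = []
    for i in range(config.n_strains):
        cid = f"synth-{config.scenario}-{i:04d}"
        t_pk_c = rng.uniform(config.t_pk_low_c, config.t_pk_high_c)
        t_pk_k = t_pk_c + 273.15
        E = float(np.clip(rng.normal(config.E_S_mean, config.E_S_sd), 0.1, max_E))
        E_D = E + config.E_D_offset
        scatter = rng.lognormal(0.0, config.ppk_scatter_sd) if config.ppk_scatter_sd > 0 else 1.0
        p_pk = A * np.exp(-E_L / (BOLTZMANN_EV * t_pk_k)) * scatter
        B0 = _b0_for_peak(p_pk, E, E_D, t_pk_k)
        params = SharpeSchoolfieldParams(B0=B0, E=E, E_D=E_D, T_pk=t_pk_k)
        temps = np.linspace(
            t_pk_k - config.temp_span_below,
            t_pk_k + config.temp_span_above,
            config.n_temperatures,
        )
        rec = generate_tpc(
            params,
            temps,
            noise_sd=config.noise_sd,
            seed=rng,
            curve_id=cid,
        )
        records.append(rec)
        truth_rows.append(
            {
                "curve_id": cid,
                "true_E": E,
                "true_E_D": E_D,
                "true_T_pk_c": t_pk_c,
                "true_P_pk": p_pk,
                "true_B0": B0,
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["true_E_L"] = E_L
    truth.attrs["scenario"] = config.scenario
    return records, truth


def generate_peak_cloud(
    config: SynthConfig,
) -> np.ndarray:
    """Just the (T_pk K, P_pk, weight=1) triplets of an ensemble.

    Shortcut for tests of the inter-specific estimators that do not need
    full curves: the peaks follow the same generative law as
    :func:`generate_strain_ensemble`.
    """
    rng = np.random.default_rng(config.seed)
    E_L = config.true_E_L
    A = _interspecific_amplitude(E_L)
    t_pk_k = rng.uniform(config.t_pk_low_c, config.t_pk_high_c, config.n_strains) + 273.15
    scatter = (
        rng.lognormal(0.0, config.ppk_scatter_sd, config.n_strains)
        if config.ppk_scatter_sd > 0
        else np.ones(config.n_strains)
    )
    p_pk = A * np.exp(-E_L / (BOLTZMANN_EV * t_pk_k)) * scatter
    return np.column_stack([t_pk_k, p_pk, np.ones_like(p_pk)])


def generate_tlab_map(
    records: Sequence[TPCRecord],
    t_pk_c: Sequence[float],
    slope: float = 0.88,
    intercept: float = 8.2,
    noise_sd: float = 1.5,
    seed=None,
) -> list[TPCRecord]:
    """Assign culture temperatures consistent with ``T_pk = a + b T_lab + eps``.

    Inverts the adaptation map per strain: ``T_lab = (T_pk - a - eps)/b``.
    With zero noise the downstream regression of ``T_pk`` on ``T_lab``
    recovers the slope and intercept exactly.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero to invert the adaptation map")
    from .fitting import replace_record

    rng = np.random.default_rng(seed)
    out = []
    for rec, tpk in zip(records, t_pk_c):
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        t_lab = (float(tpk) - intercept - eps) / slope
        out.append(replace_record(rec, t_lab_c=t_lab))
    return out


def generate_mixture_ensemble(
    n_mesophiles: int = 60,
    n_thermophiles: int = 40,
    break_c: float = 40.0,
    E_L_below: float = 0.9,
    E_L_above: float = 0.0,
    t_low_c: float = 5.0,
    t_high_c: float = 85.0,
    scatter_sd: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Peak cloud with a built-in break in the inter-specific slope.

    Below ``break_c`` peaks follow a Boltzmann-Arrhenius law with energy
    ``E_L_below``; above it the law switches to ``E_L_above`` (flat by
    default, the thermophile pattern), continuous at the break.  Returns
    (T_pk K, P_pk, weight) triplets.
    """
    rng = np.random.default_rng(seed)
    t_break_k = break_c + 273.15
    A_below = _interspecific_amplitude(E_L_below)
    # continuity at the break fixes the thermophile amplitude
    level = A_below * np.exp(-E_L_below / (BOLTZMANN_EV * t_break_k))
    A_above = level * np.exp(E_L_above / (BOLTZMANN_EV * t_break_k))

    t_meso = rng.uniform(t_low_c, break_c, n_mesophiles) + 273.15
    t_thermo = rng.uniform(break_c, t_high_c, n_thermophiles) + 273.15
    p_meso = A_below * np.exp(-E_L_below / (BOLTZMANN_EV * t_meso))
    p_thermo = A_above * np.exp(-E_L_above / (BOLTZMANN_EV * t_thermo))
    T = np.concatenate([t_meso, t_thermo])
    P = np.concatenate([p_meso, p_thermo]) * rng.lognormal(0.0, scatter_sd, T.size)
    return np.column_stack([T, P, np.ones_like(P)])


def records_to_dataframe(records: Sequence[TPCRecord]) -> pd.DataFrame:
    """Long-format observation table in the ingest schema."""
    rows = []
    for rec in records:
        for obs in rec.observations:
            rows.append(
                {
                    "curve_id": rec.curve_id,
                    "strain_id": rec.strain_id,
                    "kingdom": rec.taxonomy.get("kingdom", "Bacteria"),
                    "species": rec.species,
                    "trait": rec.trait_kind,
                    "flux_name": rec.flux_name,
                    "temp_c": obs.temperature_c,
                    "rate": obs.rate,
                    "rate_unit": "s-1",
                    "t_lab_c": rec.t_lab_c,
                    "metabolism": rec.metabolism,
                    "study_id": rec.study_id,
                }
            )
    return pd.DataFrame(rows)


def write_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the standard fixture datasets as CSV plus truth JSON.

    Emits the three scenario ensembles (hib, equalisation, weak), a
    mesophile/thermophile mixture with a built-in break at 40 degC, and a
    metabolic-flux ensemble; byte-identical for the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for i, scenario in enumerate(("hib", "equalisation", "weak")):
        cfg = SynthConfig(n_strains=60, scenario=scenario, seed=seed + i)
        records, truth = generate_strain_ensemble(cfg)
        records = generate_tlab_map(
            records,
            truth["true_T_pk_c"],
            slope=cfg.tlab_slope,
            intercept=cfg.tlab_intercept,
            noise_sd=cfg.tlab_noise_sd,
            seed=np.random.SeedSequence([seed + i, 7]),
        )
        csv_path = out_dir / f"{scenario}.csv"
        records_to_dataframe(records).to_csv(csv_path, index=False, float_format="%.12g")
        truth_path = out_dir / f"{scenario}_truth.json"
        payload = {
            "scenario": scenario,
            "true_E_L": truth.attrs["true_E_L"],
            "strains": truth.to_dict(orient="records"),
        }
        truth_path.write_text(json.dumps(payload, indent=1))
        paths[scenario] = csv_path
        paths[f"{scenario}_truth"] = truth_path

    peaks = generate_mixture_ensemble(seed=seed + 11)
    mix = pd.DataFrame(
        {"t_pk_k": peaks[:, 0], "p_pk": peaks[:, 1], "weight": peaks[:, 2]}
    )
    mix_path = out_dir / "mixture_peaks.csv"
    mix.to_csv(mix_path, index=False, float_format="%.12g")
    paths["mixture"] = mix_path
    (out_dir / "mixture_truth.json").write_text(
        json.dumps({"break_c": 40.0, "E_L_below": 0.9, "E_L_above": 0.0}, indent=1)
    )
    paths["mixture_truth"] = out_dir / "mixture_truth.json"

    flux_cfg = SynthConfig(n_strains=30, scenario="hib", E_S_mean=0.82, seed=seed + 23)
    flux_records, flux_truth = generate_strain_ensemble(flux_cfg)
    flux_records = [
        r for r in flux_records
    ]
    for r in flux_records:
        r.trait_kind = "flux"
        r.flux_name = "sulfur_oxidation"
    flux_path = out_dir / "flux.csv"
    records_to_dataframe(flux_records).to_csv(flux_path, index=False, float_format="%.12g")
    (out_dir / "flux_truth.json").write_text(
        json.dumps({"true_E_L": flux_truth.attrs["true_E_L"]}, indent=1)
    )
    paths["flux"] = flux_path
    paths["flux_truth"] = out_dir / "flux_truth.json"
    return paths
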