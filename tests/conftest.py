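"""Shared fixtures and helpers for the test suite.

All synthetic data are generated at test time from seeded configurations;
nothing is read from disk except files the tests themselves write.
"""

from __future__ import annotations

import numpy as np
import pytest

import microtherm as mt


@pytest.fixture(scope="session")
def canonical_params():
    """A typical mesophile curve used across example-based tests."""
    return mt.SharpeSchoolfieldParams(B0=0.1, E=0.65, E_D=3.0, T_pk=310.15)


@pytest.fixture(scope="session")
def noiseless_ensemble():
    """Three noiseless strains with known truth, for exact round-trips."""
    cfg = mt.SynthConfig(n_strains=3, seed=11, noise_sd=0.0, ppk_scatter_sd=0.0)
    return mt.generate_strain_ensemble(cfg)


def fit_and_analyse(scenario: str, n: int, seed: int, n_boot: int = 400,
                    n_multistart: int = 2):
    """Generate an ensemble, fit every curve, and run the group comparison.

    This is the end-to-end path from raw synthetic observations to a
    hotter-is-better verdict, used by the scenario-recovery tests.
    """
    cfg = mt.SynthConfig(n_strains=n, scenario=scenario, seed=seed)
    records, truth = mt.generate_strain_ensemble(cfg)
    fits = mt.fit_dataset(records, mt.FitConfig(n_multistart=n_multistart, seed=seed))
    usable = [f for f in fits if f.usable]
    E = [f.params.E for f in usable]
    w = [f.weight_E for f in usable]
    peaks = [(f.params.T_pk, f.P_pk, f.weight_Ppk) for f in usable if f.has_peak]
    group = mt.analyse_group(scenario, E, w, peaks, n_boot=n_boot, seed=seed)
    return group, truth
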