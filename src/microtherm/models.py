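"""Rate equations for thermal performance of microbial metabolism.

Two models are used throughout the package:

* the four-parameter Sharpe-Schoolfield model (high-temperature
  deactivation form, reparameterised so the thermal optimum ``T_pk`` is an
  explicit parameter), describing the unimodal response of a biological
  rate to temperature *within* a strain, and
* the Boltzmann-Arrhenius model, describing the exponential rise of rate
  with temperature that applies below the optimum and, across strains, to
  peak rates under a hotter-is-better constraint.

Everything here is a pure function of its arguments: no fitting, no
randomness.  Temperatures are Kelvin, energies electron-volts, rates per
second (callers convert at the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Boltzmann constant in eV/K.  A physical constant, not a tunable.
BOLTZMANN_EV = 8.617e-5

#: Package-wide default reference temperature (0 degC).  Low enough to sit
#: below essentially every observed thermal optimum, which keeps B0
#: interpretable as a baseline rate.
T_REF_DEFAULT = 273.15

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + CELSIUS_OFFSET


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - CELSIUS_OFFSET


class InvalidParameterError(ValueError):
    """Model parameters describe a degenerate curve (e.g. E_D <= E)."""


@dataclass(frozen=True)
class SharpeSchoolfieldParams:
    """Parameters of the Sharpe-Schoolfield thermal performance curve.

    Attributes
    ----------
    B0 : float
        Rate at the reference temperature in the absence of deactivation
        (s^-1); must be positive.
    E : float
        Activation energy (eV) governing the sub-peak rise; must be
        positive.
    E_D : float
        Deactivation energy (eV) governing the post-peak fall; must
        exceed ``E``.
    T_pk : float
        Temperature of peak performance (K).
    T_ref : float
        Reference temperature (K) at which ``B0`` is defined.
    """

    B0: float
    E: float
    E_D: float
    T_pk: float
    T_ref: float = T_REF_DEFAULT

    def __post_init__(self):
        if not (self.B0 > 0):
            raise InvalidParameterError(f"B0 must be > 0, got {self.B0}")
        if not (self.E > 0):
            raise InvalidParameterError(f"E must be > 0, got {self.E}")
        if not (self.E_D > self.E):
            raise InvalidParameterError(
                f"E_D must exceed E, got E_D={self.E_D}, E={self.E}"
            )
        if not (self.T_pk > 0) or not (self.T_ref > 0):
            raise InvalidParameterError("temperatures must be positive Kelvin")


@dataclass(frozen=True)
class BoltzmannArrheniusParams:
    """Parameters of the Boltzmann-Arrhenius model ``B = B0 exp(-E/kT)``.

    ``E`` may be negative: inter-specific fits through thermophile peak
    rates can have a flat or inverted temperature dependence.
    """

    B0: float
    E: float

    def __post_init__(self):
        if not (self.B0 > 0):
            raise InvalidParameterError(f"B0 must be > 0, got {self.B0}")
        if not np.isfinite(self.E):
            raise InvalidParameterError(f"E must be finite, got {self.E}")


def ss_evaluate(params: SharpeSchoolfieldParams, temperature):
    """Evaluate the Sharpe-Schoolfield curve at ``temperature`` (K).

    The model is

        B(T) = B0 * exp(-E/k (1/T - 1/T_ref))
               / (1 + E/(E_D - E) * exp(E_D/k (1/T_pk - 1/T)))

    which rises as Boltzmann-Arrhenius below the optimum and falls above
    it at a rate set by ``E_D``.

    Parameters
    ----------
    params : SharpeSchoolfieldParams
    temperature : float or array
        Temperature(s) in Kelvin; must be positive.

    Returns
    -------
    float or ndarray
        Rate in the units of ``B0``; strictly positive.
    """
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive Kelvin")
    k = BOLTZMANN_EV
    p = params
    rise = p.B0 * np.exp(-p.E / k * (1.0 / T - 1.0 / p.T_ref))
    fall = 1.0 + p.E / (p.E_D - p.E) * np.exp(p.E_D / k * (1.0 / p.T_pk - 1.0 / T))
    out = rise / fall
    return float(out) if np.isscalar(temperature) else out


def ss_peak_performance(params: SharpeSchoolfieldParams) -> float:
    """Rate at the thermal optimum, ``P_pk = B(T_pk)``, in closed form.

    At ``T = T_pk`` the denominator of the model is ``E_D / (E_D - E)``,
    so

        P_pk = B0 * exp(-E/k (1/T_pk - 1/T_ref)) * (E_D - E) / E_D

    which is also the global maximum of the curve over temperature.
    """
    p = params
    k = BOLTZMANN_EV
    rise = p.B0 * np.exp(-p.E / k * (1.0 / p.T_pk - 1.0 / p.T_ref))
    return float(rise * (p.E_D - p.E) / p.E_D)


def ba_evaluate(params: BoltzmannArrheniusParams, temperature):
    """Evaluate ``B = B0 exp(-E/kT)`` at ``temperature`` (K)."""
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive Kelvin")
    out = params.B0 * np.exp(-params.E / (BOLTZMANN_EV * T))
    return float(out) if np.isscalar(temperature) else out


def arrhenius_coordinates(T_pk, P_pk):
    """Map peak coordinates onto the Arrhenius plane.

    Returns ``x = 1/(k T_pk)`` (eV^-1) and ``y = ln P_pk``.  Points drawn
    from a Boltzmann-Arrhenius law fall on a line of slope ``-E`` in
    these coordinates, which is how the inter-specific (long-term)
    activation energy is visualised and how the mesophile/thermophile
    break point is located.
    """
    T = np.asarray(T_pk, dtype=float)
    P = np.asarray(P_pk, dtype=float)
    if np.any(T <= 0):
        raise ValueError("T_pk must be positive Kelvin")
    if np.any(P <= 0):
        raise ValueError("P_pk must be positive (log undefined otherwise)")
    x = 1.0 / (BOLTZMANN_EV * T)
    y = np.log(P)
    if np.isscalar(T_pk) and np.isscalar(P_pk):
        return float(x), float(y)
    return x, y
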