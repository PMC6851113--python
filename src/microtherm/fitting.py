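"""Per-curve estimation of thermal performance parameters.

Each strain contributes one thermal performance curve (TPC): a handful of
rate measurements across temperature.  This module fits the
Sharpe-Schoolfield model to each curve by multistart Levenberg-Marquardt
non-linear least squares, decides whether the curve actually resolves a
peak (curves measured only on the rising limb cannot inform the
inter-specific analysis), propagates the fit covariance into standard
deviations of the activation energy ``E`` and the peak rate ``P_pk`` by
Monte-Carlo sampling, and converts those into the downweighting scheme
``w = 1/(SD + 1)`` used by the group-level estimators.

Replicate handling follows two policies: pseudoreplicates of the same
prokaryote strain from the same study and conditions are pooled into a
single curve before fitting, while same-species eukaryote replicates are
fitted separately and the best fit (smallest AIC) retained.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np

from .models import (
    BOLTZMANN_EV,
    T_REF_DEFAULT,
    InvalidParameterError,
    SharpeSchoolfieldParams,
    celsius_to_kelvin,
    ss_peak_performance,
)

LN2 = float(np.log(2.0))

# Recognised rate units and their conversion factors to s^-1.
_UNIT_TO_PER_SECOND = {
    "s-1": 1.0,
    "1/s": 1.0,
    "per_second": 1.0,
    "min-1": 1.0 / 60.0,
    "1/min": 1.0 / 60.0,
    "h-1": 1.0 / 3600.0,
    "1/h": 1.0 / 3600.0,
    "per_hour": 1.0 / 3600.0,
    "day-1": 1.0 / 86400.0,
    "1/day": 1.0 / 86400.0,
    "d-1": 1.0 / 86400.0,
}


def rate_unit_factor(unit: str) -> Optional[float]:
    """Conversion factor from ``unit`` to s^-1, or None if unrecognised."""
    return _UNIT_TO_PER_SECOND.get(unit.strip().lower().replace("^", ""))


@dataclass(frozen=True)
class RateObservation:
    """A single rate measurement at one temperature.

    ``temperature_c`` is degrees Celsius as measured; ``rate`` is the
    trait value already normalised to s^-1 (ingest converts units and
    doubling times, see :mod:`microtherm.interface`).
    """

    temperature_c: float
    rate: float

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15


@dataclass
class TPCRecord:
    """One strain/trait thermal performance curve plus its metadata."""

    curve_id: str
    observations: list[RateObservation]
    strain_id: str = ""
    species: str = ""
    taxonomy: dict = field(default_factory=dict)  # kingdom ... genus
    trait_kind: str = "growth"  # growth | flux
    flux_name: Optional[str] = None
    t_lab_c: Optional[float] = None
    metabolism: Optional[str] = None
    pathogen: Optional[bool] = None
    study_id: str = ""

    def __post_init__(self):
        if len(self.observations) < 1:
            raise ValueError(f"curve {self.curve_id!r} has no observations")
        if self.trait_kind not in ("growth", "flux"):
            raise ValueError(f"trait_kind must be growth|flux, got {self.trait_kind!r}")

    @property
    def kingdom(self) -> Optional[str]:
        return self.taxonomy.get("kingdom")

    def temperatures_k(self) -> np.ndarray:
        return np.array([o.temperature_k for o in self.observations])

    def rates(self) -> np.ndarray:
        return np.array([o.rate for o in self.observations])


@dataclass
class FitConfig:
    """Knobs of the per-curve fitting stage.

    t_ref_K : reference temperature of B0 (K).
    min_points : fewest distinct temperatures for a fit to be attempted
        (four free parameters plus one residual degree of freedom).
    n_multistart : total optimiser starts per curve; the first uses
        data-driven initial values, the rest jitter them +/-50%.
    n_draws : Monte-Carlo draws for covariance propagation.
    seed : master seed; per-curve child seeds are derived from it and the
        curve id so fits are reproducible curve-by-curve.
    residual_scale : 'natural' (ordinary NLLS on rates) or 'log'.
    """

    t_ref_K: float = T_REF_DEFAULT
    min_points: int = 5
    n_multistart: int = 30
    n_draws: int = 1000
    seed: int = 0
    residual_scale: str = "natural"


@dataclass
class SSFit:
    """Result of fitting one curve, plus derived uncertainty quantities."""

    curve_id: str
    params: Optional[SharpeSchoolfieldParams] = None
    P_pk: Optional[float] = None
    covariance: Optional[np.ndarray] = None  # 4x4 over (B0, E, E_D, T_pk)
    SD_E: Optional[float] = None
    SD_Ppk: Optional[float] = None
    weight_E: Optional[float] = None
    weight_Ppk: Optional[float] = None
    rss: Optional[float] = None
    n_points: int = 0
    converged: bool = False
    has_peak: bool = False
    excluded_reason: Optional[str] = None

    @property
    def usable(self) -> bool:
        """Converged, weighted, not excluded: enters group-level analysis."""
        return self.converged and self.excluded_reason is None

    def aic(self) -> float:
        """Gaussian AIC from RSS and n (4 free parameters)."""
        if self.rss is None or self.n_points == 0:
            return np.inf
        rss = max(self.rss, 1e-300)
        return self.n_points * np.log(rss / self.n_points) + 2 * 4


def compute_weight(sd: float) -> float:
    """Downweighting ``1/(sd + 1)`` for an uncertainty ``sd >= 0``.

    Maps zero uncertainty to weight 1 and decays toward 0 as the fit's
    Monte-Carlo standard deviation grows, so noisy fits contribute less
    to group means without being dropped outright.
    """
    if sd < 0:
        raise ValueError(f"standard deviation must be >= 0, got {sd}")
    return 1.0 / (sd + 1.0)


def _curve_seed(master_seed: int, curve_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), zlib.crc32(curve_id.encode())])


def _ss_model(T, B0, E, dE, T_pk, t_ref):
    k = BOLTZMANN_EV
    rise = B0 * np.exp(-E / k * (1.0 / T - 1.0 / t_ref))
    fall = 1.0 + E / dE * np.exp((E + dE) / k * (1.0 / T_pk - 1.0 / T))
    return rise / fall


def _fit_one_start(T, y, start, bounds, config) -> Optional[lmfit.minimizer.MinimizerResult]:
    pars = lmfit.Parameters()
    lo, hi = bounds["T_pk"]
    pars.add("B0", value=start["B0"], min=1e-12)
    pars.add("E", value=start["E"], min=1e-6, max=15.0)
    # E_D is fitted as the positive offset dE = E_D - E, which encodes the
    # E_D > E constraint as a simple box bound.
    pars.add("dE", value=start["dE"], min=1e-6, max=50.0)
    pars.add("T_pk", value=min(max(start["T_pk"], lo), hi), min=lo, max=hi)

    if config.residual_scale == "log":
        mask = y > 0

        def resid(p):
            m = _ss_model(T[mask], p["B0"], p["E"], p["dE"], p["T_pk"], config.t_ref_K)
            return np.log(m) - np.log(y[mask])

    else:

        def resid(p):
            return _ss_model(T, p["B0"], p["E"], p["dE"], p["T_pk"], config.t_ref_K) - y

    try:
        res = lmfit.minimize(resid, pars, method="leastsq")
    except Exception:
        return None
    if not res.success or not np.isfinite(res.chisqr):
        return None
    return res


def fit_sharpe_schoolfield(curve: TPCRecord, config: Optional[FitConfig] = None) -> SSFit:
    """Fit the Sharpe-Schoolfield model to one curve.

    Ordinary non-linear least squares (Levenberg-Marquardt) on the
    natural rate scale, with multistart initialisation because the
    objective is multimodal.  The fitted ``T_pk`` is bounded to within
    10 K of the observed temperature range.  Curves with too few points,
    no positive rate, or no converging start are returned with a
    machine-readable ``excluded_reason`` rather than raising.

    When the optimiser yields a covariance matrix, Monte-Carlo
    propagation fills in ``SD_E``/``SD_Ppk`` and the corresponding
    weights; fits without a covariance are retained but flagged
    ``no_covariance`` and excluded from downstream weighting.
    """
    config = config or FitConfig()
    T = curve.temperatures_k()
    y = curve.rates()
    fit = SSFit(curve_id=curve.curve_id, n_points=len(y))

    if len(np.unique(T)) < config.min_points:
        fit.excluded_reason = "insufficient_points"
        return fit
    if not np.any(y > 0):
        fit.excluded_reason = "no_signal"
        return fit

    t_lo, t_hi = float(T.min()) - 10.0, float(T.max()) + 10.0
    ypos = y[y > 0]
    b0_guess = float(y[np.argmin(np.abs(T - config.t_ref_K))])
    if b0_guess <= 0:
        b0_guess = float(ypos.min())
    base = {
        "B0": b0_guess,
        "E": 0.65,
        "dE": 3.0 - 0.65,
        "T_pk": float(T[np.argmax(y)]),
    }
    bounds = {"T_pk": (t_lo, t_hi)}

    rng = np.random.default_rng(_curve_seed(config.seed, curve.curve_id))
    starts = [base]
    for _ in range(max(config.n_multistart - 1, 0)):
        jitter = {k_: v * rng.uniform(0.5, 1.5) for k_, v in base.items()}
        starts.append(jitter)

    best = None
    for start in starts:
        res = _fit_one_start(T, y, start, bounds, config)
        if res is not None and (best is None or res.chisqr < best.chisqr):
            best = res

    if best is None:
        fit.excluded_reason = "no_convergence"
        return fit

    p = best.params
    try:
        fit.params = SharpeSchoolfieldParams(
            B0=float(p["B0"].value),
            E=float(p["E"].value),
            E_D=float(p["E"].value + p["dE"].value),
            T_pk=float(p["T_pk"].value),
            T_ref=config.t_ref_K,
        )
    except InvalidParameterError:
        fit.excluded_reason = "no_convergence"
        return fit
    fit.converged = True
    fit.rss = float(best.chisqr)
    fit.P_pk = ss_peak_performance(fit.params)
    fit.has_peak = detect_peak(fit, curve)

    if best.covar is not None and np.all(np.isfinite(best.covar)):
        # Map covariance from the fitted basis (B0, E, dE, T_pk) onto the
        # reported basis (B0, E, E_D, T_pk): E_D = E + dE is linear.
        J = np.array(
            [
                [1.0, 0.0, 0.0, 0.0],
                [0.0, 1.0, 0.0, 0.0],
                [0.0, 1.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        names = list(best.var_names)
        full = np.zeros((4, 4))
        order = ["B0", "E", "dE", "T_pk"]
        for i, ni in enumerate(order):
            for j, nj in enumerate(order):
                if ni in names and nj in names:
                    full[i, j] = best.covar[names.index(ni), names.index(nj)]
        cov = J @ full @ J.T
        fit.covariance = 0.5 * (cov + cov.T)
        sd_e, sd_ppk = propagate_uncertainty(fit, n_draws=config.n_draws,
                                             seed=_curve_seed(config.seed, curve.curve_id + "/mc"))
        fit.SD_E, fit.SD_Ppk = sd_e, sd_ppk
        fit.weight_E = compute_weight(sd_e)
        fit.weight_Ppk = compute_weight(sd_ppk)
    else:
        fit.excluded_reason = "no_covariance"

    return fit


def detect_peak(fit: SSFit, curve: TPCRecord) -> bool:
    """Does this curve genuinely resolve a thermal optimum?

    True only if (a) the fitted ``T_pk`` lies strictly inside the
    observed temperature range and (b) the largest observed rate is not
    at the highest measured temperature.  Curves failing either were
    measured only on the rising limb, so their peak location is an
    extrapolation; they stay in the intra-specific analysis but are
    excluded from the inter-specific (peak-based) one.
    """
    if fit.params is None:
        return False
    T = curve.temperatures_k()
    y = curve.rates()
    inside = float(T.min()) < fit.params.T_pk < float(T.max())
    max_not_at_edge = T[np.argmax(y)] < T.max()
    return bool(inside and max_not_at_edge)


class MissingCovarianceError(RuntimeError):
    """The fit produced no covariance matrix; it is excluded from weighting."""


def propagate_uncertainty(fit: SSFit, n_draws: int = 1000, seed=None) -> tuple[float, float]:
    """Monte-Carlo propagation of the fit covariance into (SD_E, SD_Ppk).

    Samples ``n_draws`` parameter vectors from a multivariate normal
    centred at the point estimates with the fit covariance, discards
    draws that violate the model's validity (E <= 0, E_D <= E, B0 <= 0,
    or non-finite peak rate), and returns the standard deviations of the
    surviving draws' ``E`` and recomputed ``P_pk``.  If fewer than half
    the draws survive the fit is flagged ``unstable_covariance``.
    """
    if fit.covariance is None:
        raise MissingCovarianceError(
            f"curve {fit.curve_id}: no covariance matrix; fit excluded from weighting"
        )
    p = fit.params
    mean = np.array([p.B0, p.E, p.E_D, p.T_pk])
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, fit.covariance, size=n_draws,
                                    method="svd", check_valid="ignore")
    B0d, Ed, EDd, Tpkd = draws.T
    k = BOLTZMANN_EV
    with np.errstate(over="ignore", invalid="ignore"):
        ppk = B0d * np.exp(-Ed / k * (1.0 / Tpkd - 1.0 / p.T_ref)) * (EDd - Ed) / EDd
    ok = (Ed > 0) & (EDd > Ed) & (B0d > 0) & (Tpkd > 0) & np.isfinite(ppk)
    n_ok = int(ok.sum())
    if n_ok < n_draws / 2 and fit.excluded_reason is None:
        fit.excluded_reason = "unstable_covariance"
    if n_ok == 0:
        return float("inf"), float("inf")
    sd_e = float(np.std(Ed[ok]))
    sd_ppk = float(np.std(ppk[ok]))
    return sd_e, sd_ppk


def _pool_key(rec: TPCRecord):
    return (rec.strain_id, rec.study_id, rec.t_lab_c, rec.metabolism)


def deduplicate_replicates(
    records: Sequence[TPCRecord],
    policy: str = "pool_pseudoreplicates",
    config: Optional[FitConfig] = None,
) -> list[TPCRecord]:
    """Collapse replicate curves according to the chosen policy.

    ``pool_pseudoreplicates`` (prokaryotes): curves from the same strain,
    study and growth conditions are pseudoreplicates; their observations
    are merged into a single curve fitted once.  Mixing trait kinds
    within a pool group is an error.

    ``best_fit`` (eukaryote same-species replicates): each candidate is
    fitted and the one with the smallest AIC is kept; ties prefer more
    observations, then the lexicographically first curve id.
    """
    if policy == "pool_pseudoreplicates":
        groups: dict = {}
        order: list = []
        for rec in records:
            key = _pool_key(rec)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(rec)
        out = []
        for key in order:
            members = sorted(groups[key], key=lambda r: r.curve_id)
            if len(members) == 1:
                out.append(members[0])
                continue
            kinds = {m.trait_kind for m in members}
            if len(kinds) > 1:
                raise ValueError(
                    f"pool group {key} mixes trait kinds {sorted(kinds)}"
                )
            first = members[0]
            pooled_obs = [o for m in members for o in m.observations]
            out.append(replace_record(first, observations=pooled_obs))
        return out

    if policy == "best_fit":
        groups = {}
        order = []
        for rec in records:
            key = rec.species or rec.curve_id
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(rec)
        out = []
        for key in order:
            members = groups[key]
            if len(members) == 1:
                out.append(members[0])
                continue
            scored = []
            for m in members:
                f = fit_sharpe_schoolfield(m, config)
                scored.append((f.aic(), -f.n_points, m.curve_id, m))
            scored.sort(key=lambda t: t[:3])
            out.append(scored[0][3])
        return out

    raise ValueError(f"unknown policy {policy!r}")


def replace_record(rec: TPCRecord, **changes) -> TPCRecord:
    """Copy a record with some fields replaced (observations most often)."""
    kwargs = dict(
        curve_id=rec.curve_id,
        observations=rec.observations,
        strain_id=rec.strain_id,
        species=rec.species,
        taxonomy=dict(rec.taxonomy),
        trait_kind=rec.trait_kind,
        flux_name=rec.flux_name,
        t_lab_c=rec.t_lab_c,
        metabolism=rec.metabolism,
        pathogen=rec.pathogen,
        study_id=rec.study_id,
    )
    kwargs.update(changes)
    return TPCRecord(**kwargs)


def fit_dataset(records: Sequence[TPCRecord], config: Optional[FitConfig] = None) -> list[SSFit]:
    """Fit every curve; every input appears exactly once in the output."""
    config = config or FitConfig()
    return [fit_sharpe_schoolfield(rec, config) for rec in records]
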