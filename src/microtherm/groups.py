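"""Group-level inference linking short- and long-term thermal responses.

The hotter-is-better (HiB) hypothesis predicts that, across strains, peak
performance ``P_pk`` rises with the thermal optimum ``T_pk`` at the same
Arrhenius rate that governs each strain's own sub-peak response.  This
module compares the two rates for a group of curves:

* the short-term (intra-specific) side is the weighted mean of the
  per-curve activation energies, ``E_S_bar = sum(w_i E_i)/sum(w_i)`` with
  ``w_i = 1/(SD_E + 1)``, bootstrapped for a percentile CI;
* the long-term (inter-specific) side is a weighted Boltzmann-Arrhenius
  fit through the cloud of ``(T_pk, P_pk)`` peaks, its activation energy
  ``E_L`` bootstrapped by resampling peaks and refitting;
* the verdict follows from CI overlap: ``E_L`` indistinguishable from
  zero means equalisation of fitness; substantial overlap of the two CIs
  supports HiB; positive but clearly smaller ``E_L`` indicates a partial
  thermodynamic constraint.

A break-point analysis on the Arrhenius plot of the peaks locates the
mesophile/thermophile transition (empirically near 40-46 degC), and a
plain regression of ``T_pk`` on culture temperature ``T_lab`` checks that
strains are adapted to the temperature they were grown at.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .models import BOLTZMANN_EV, BoltzmannArrheniusParams

# ---------------------------------------------------------------------------
# results containers


@dataclass
class GroupResult:
    """Estimates and HiB verdict for one group of curves."""

    label: str
    n: int
    E_S_bar: float
    E_S_ci: tuple[float, float]
    E_S_median: float
    E_L: Optional[float] = None
    E_L_ci: Optional[tuple[float, float]] = None
    overlap_fraction: Optional[float] = None
    verdict: str = "not_testable"
    note: Optional[str] = None


@dataclass
class Segment:
    slope: float
    intercept: float


@dataclass
class BreakpointResult:
    """Continuous two-segment fit on the Arrhenius plot of peaks."""

    break_temperature_c: Optional[float]
    left_segment: Optional[Segment]  # below the break (cooler optima)
    right_segment: Optional[Segment]  # above the break
    f_statistic: Optional[float]
    p_value: Optional[float]
    significant: bool


@dataclass
class RegressionResult:
    """T_pk vs T_lab ordinary least squares summary."""

    testable: bool
    n: int
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r_squared: Optional[float] = None
    slope_ci: Optional[tuple[float, float]] = None
    ci_excludes_unity: Optional[bool] = None


# ---------------------------------------------------------------------------
# weighted means and their bootstrap


def weighted_mean_ES(E: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted arithmetic mean ``sum(w E)/sum(w)`` of activation energies."""
    E = np.asarray(E, dtype=float)
    w = np.asarray(weights, dtype=float)
    if E.size == 0:
        raise ValueError("no activation energies to average")
    return float(np.sum(w * E) / np.sum(w))


def bootstrap_weighted_mean(
    E: Sequence[float],
    weights: Sequence[float],
    n_boot: int = 1000,
    seed=None,
) -> tuple[float, float]:
    """Percentile bootstrap CI (2.5th-97.5th) of the weighted mean.

    Resamples (E, w) pairs with replacement ``n_boot`` times and
    recomputes the weighted mean each time.  With a single curve the
    interval degenerates to the point estimate.
    """
    E = np.asarray(E, dtype=float)
    w = np.asarray(weights, dtype=float)
    if E.size == 1:
        v = weighted_mean_ES(E, w)
        return (v, v)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, E.size, size=(n_boot, E.size))
    Eb, wb = E[idx], w[idx]
    means = np.sum(wb * Eb, axis=1) / np.sum(wb, axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# inter-specific Boltzmann-Arrhenius fit through (T_pk, P_pk) peaks


def _ba_weighted_fit(T, P, w):
    """Weighted NLLS of P = B0 exp(-E/kT); returns (lnB0, E)."""
    x = 1.0 / (BOLTZMANN_EV * T)
    y = np.log(P)
    # log-linear weighted start (exact when scatter is lognormal)
    X = np.column_stack([np.ones_like(x), x])
    W = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(W[:, None] * X, W * y, rcond=None)
    p0 = np.array([beta[0], -beta[1]])

    sw = np.sqrt(w)

    def resid(p):
        return sw * (np.exp(p[0] - p[1] * x) - P)

    def jac(p):
        m = np.exp(p[0] - p[1] * x)
        return np.column_stack([sw * m, -sw * m * x])

    sol = optimize.least_squares(resid, p0, jac=jac, method="lm")
    return sol.x[0], sol.x[1]


def fit_interspecific_BA(
    peaks: Sequence[tuple[float, float, float]],
) -> tuple[BoltzmannArrheniusParams, dict]:
    """Weighted Boltzmann-Arrhenius fit through peak coordinates.

    ``peaks`` are ``(T_pk in K, P_pk, weight)`` triplets from peaked,
    non-excluded fits.  Squared residuals on the natural rate scale are
    multiplied by the peak-rate weight ``1/(SD_Ppk + 1)``.  The
    activation energy ``E_L`` is unconstrained in sign (thermophile
    groups can be flat or inverted).
    """
    arr = np.asarray(peaks, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 peaks for an inter-specific fit")
    T, P, w = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(T <= 0) or np.any(P <= 0) or np.any(w <= 0):
        raise ValueError("peaks must have positive T_pk, P_pk and weight")
    lnB0, E = _ba_weighted_fit(T, P, w)
    params = BoltzmannArrheniusParams(B0=float(np.exp(lnB0)), E=float(E))
    pred = params.B0 * np.exp(-params.E / (BOLTZMANN_EV * T))
    rss = float(np.sum(w * (P - pred) ** 2))
    return params, {"rss": rss, "n": int(T.size)}


def bootstrap_EL(
    peaks: Sequence[tuple[float, float, float]],
    n_boot: int = 1000,
    seed=None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``E_L``: resample peaks, refit each time."""
    arr = np.asarray(peaks, dtype=float)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 peaks to bootstrap E_L")
    rng = np.random.default_rng(seed)
    Es = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = arr[idx]
        # a resample can be temperature-degenerate; refit robustly
        try:
            _, E = _ba_weighted_fit(sub[:, 0], sub[:, 1], sub[:, 2])
        except np.linalg.LinAlgError:
            E = np.nan
        Es[b] = E
    Es = Es[np.isfinite(Es)]
    lo, hi = np.percentile(Es, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# break-point analysis on the linearised Arrhenius plot


def breakpoint_analysis(
    peaks: Sequence[tuple[float, float]],
    grid_step_c: float = 0.1,
    alpha: float = 0.05,
) -> BreakpointResult:
    """Locate a mesophile/thermophile transition in the peak cloud.

    Works in Arrhenius coordinates ``x = 1/(k T_pk)``, ``y = ln P_pk``
    and fits a continuous two-segment (hinge) linear model, profiling
    candidate break temperatures on a fine grid between the 3rd-smallest
    and 3rd-largest observed optima (extreme points excluded so neither
    segment is degenerate).  The break with minimum RSS is tested
    against the single-line fit with an F-test (2 extra parameters) at
    ``alpha``.  Requires >= 8 peaks spanning >= 15 degC.
    """
    arr = np.asarray(peaks, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 8:
        raise ValueError("break-point analysis needs at least 8 peaks")
    T, P = arr[:, 0], arr[:, 1]
    t_c = T - 273.15
    if t_c.max() - t_c.min() < 15.0:
        raise ValueError("break-point analysis needs >= 15 degC span in T_pk")
    x = 1.0 / (BOLTZMANN_EV * T)
    y = np.log(P)
    n = x.size

    t_sorted = np.sort(t_c)
    lo_t, hi_t = t_sorted[2], t_sorted[-3]
    if hi_t <= lo_t:
        raise ValueError("too few distinct optima to profile a break")
    candidates_c = np.arange(lo_t, hi_t + grid_step_c / 2, grid_step_c)

    ones = np.ones_like(x)
    # single-line reference fit
    X0 = np.column_stack([ones, x])
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ beta0) ** 2))

    best = None
    for tb in candidates_c:
        xb = 1.0 / (BOLTZMANN_EV * (tb + 273.15))
        X = np.column_stack([ones, x, np.maximum(x - xb, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        if best is None or rss < best[0]:
            best = (rss, tb, xb, beta)

    rss1, tb, xb, beta = best
    df_denom = n - 4
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    if rss0 <= 1e-12 * scale:
        # a single line already fits (numerically) perfectly: no break
        return BreakpointResult(None, None, None, 0.0, 1.0, False)
    if rss1 <= 0 or df_denom <= 0:
        f_stat, p_val = np.inf, 0.0
    else:
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / df_denom)
        p_val = float(stats.f.sf(f_stat, 2, df_denom))
    significant = bool(p_val < alpha)

    if not significant:
        return BreakpointResult(None, None, None, float(f_stat), float(p_val), False)

    a, b1, b2 = beta
    # x falls as temperature rises: temperatures below the break have
    # x > xb (hinge active), temperatures above have x <= xb.
    left = Segment(slope=float(b1 + b2), intercept=float(a - b2 * xb))
    right = Segment(slope=float(b1), intercept=float(a))
    return BreakpointResult(float(tb), left, right, float(f_stat), float(p_val), True)


def classify_niche(T_pk_c: float, break_T_c: float) -> str:
    """Mesophile iff the thermal optimum is at or below the break point.

    No lower bound: psychrophiles are grouped with mesophiles.  A curve
    exactly at the break counts as mesophile.
    """
    return "mesophile" if T_pk_c <= break_T_c else "thermophile"


# ---------------------------------------------------------------------------
# CI overlap and the HiB verdict


def ci_overlap_fraction(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> float:
    """Overlap of two intervals as a fraction of the shorter one.

    Returns ``len(intersection) / len(shorter)`` in [0, 1].  A
    zero-length interval lying inside the other counts as full overlap.
    """
    (a_lo, a_hi), (b_lo, b_hi) = ci_a, ci_b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("interval bounds must satisfy low <= high")
    inter = min(a_hi, b_hi) - max(a_lo, b_lo)
    if inter < 0:
        return 0.0
    shorter = min(a_hi - a_lo, b_hi - b_lo)
    if shorter == 0:
        return 1.0  # degenerate interval inside (inter >= 0) the other
    return float(min(inter / shorter, 1.0))


def hib_test(
    ES_ci: tuple[float, float],
    EL_ci: tuple[float, float],
    ES_point: Optional[float] = None,
    EL_point: Optional[float] = None,
    overlap_threshold: float = 0.5,
) -> tuple[str, float, Optional[str]]:
    """Decide between the HiB, equalisation and partial-constraint outcomes.

    Verdicts, in order of precedence:

    1. ``equalisation`` - the ``E_L`` CI contains zero: peak performance
       is temperature-invariant across strains.
    2. ``hotter_is_better`` - the CIs overlap by at least
       ``overlap_threshold`` of the shorter interval.
    3. ``ambiguous`` - some but insufficient overlap.
    4. ``partial_constraint`` - disjoint CIs with ``E_L < E_S_bar``
       (adaptation partially overcomes the thermodynamic constraint);
       disjoint with ``E_L > E_S_bar`` is flagged ``super_arrhenius`` in
       the note.

    Returns ``(verdict, overlap_fraction, note)``.
    """
    if ES_ci is None or EL_ci is None:
        return "not_testable", float("nan"), "missing confidence interval"
    frac = ci_overlap_fraction(ES_ci, EL_ci)
    if EL_ci[0] <= 0.0 <= EL_ci[1]:
        return "equalisation", frac, None
    if frac >= overlap_threshold:
        return "hotter_is_better", frac, None
    if frac > 0.0:
        return "ambiguous", frac, None
    es = ES_point if ES_point is not None else 0.5 * (ES_ci[0] + ES_ci[1])
    el = EL_point if EL_point is not None else 0.5 * (EL_ci[0] + EL_ci[1])
    note = "super_arrhenius" if el > es else None
    return "partial_constraint", frac, note


# ---------------------------------------------------------------------------
# adaptation to culture temperature


def tpk_tlab_regression(
    t_lab_c: Sequence[float],
    t_pk_c: Sequence[float],
) -> RegressionResult:
    """OLS of fitted thermal optimum on culture temperature (both degC).

    A slope near 1 means strains' optima track their growth temperature;
    the 95% CI excluding 1 signals a systematic adaptation limit (optima
    falling below culture temperature at the hot end).
    """
    import statsmodels.api as sm

    x = np.asarray(t_lab_c, dtype=float)
    y = np.asarray(t_pk_c, dtype=float)
    n = x.size
    if n < 3:
        return RegressionResult(testable=False, n=n)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    slope_ci = (float(ci[1][0]), float(ci[1][1]))
    return RegressionResult(
        testable=True,
        n=n,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_ci=slope_ci,
        ci_excludes_unity=bool(slope_ci[0] > 1.0 or slope_ci[1] < 1.0),
    )


# ---------------------------------------------------------------------------
# group summaries and the full per-group analysis


@dataclass
class GroupSummary:
    label: str
    n: int
    E_S_bar: Optional[float]
    E_S_ci: Optional[tuple[float, float]]
    E_S_median: Optional[float]


def summarise_group(
    entries: Sequence[tuple[str, float, float]],
    min_n: int = 5,
    n_boot: int = 1000,
    seed=None,
) -> list[GroupSummary]:
    """Per-group weighted mean, bootstrap CI and median of ``E_S``.

    ``entries`` are ``(group_label, E, weight)`` rows.  Groups with fewer
    than ``min_n`` curves are omitted from the report but pooled into a
    trailing ``_remainder`` row so every curve is accounted for.
    """
    groups: dict[str, list[tuple[float, float]]] = {}
    order: list[str] = []
    for label, e, w in entries:
        if label not in groups:
            groups[label] = []
            order.append(label)
        groups[label].append((float(e), float(w)))

    rng = np.random.default_rng(seed)
    out: list[GroupSummary] = []
    remainder = 0
    for label in order:
        rows = groups[label]
        if len(rows) < min_n:
            remainder += len(rows)
            continue
        E = np.array([r[0] for r in rows])
        w = np.array([r[1] for r in rows])
        ci = bootstrap_weighted_mean(E, w, n_boot=n_boot, seed=rng)
        out.append(
            GroupSummary(
                label=label,
                n=len(rows),
                E_S_bar=weighted_mean_ES(E, w),
                E_S_ci=ci,
                E_S_median=float(np.median(E)),
            )
        )
    if remainder:
        out.append(GroupSummary("_remainder", remainder, None, None, None))
    return out


def analyse_group(
    label: str,
    E: Sequence[float],
    weight_E: Sequence[float],
    peaks: Sequence[tuple[float, float, float]],
    n_boot: int = 1000,
    seed=None,
    overlap_threshold: float = 0.5,
) -> GroupResult:
    """Full short- vs long-term comparison for one group of curves.

    Combines the weighted mean of intra-specific ``E`` (with bootstrap
    CI), the weighted inter-specific Boltzmann-Arrhenius fit through the
    group's peaks (with bootstrap CI), and the CI-overlap verdict.
    Groups with fewer than 3 peaks get ``not_testable``.
    """
    E = np.asarray(E, dtype=float)
    w = np.asarray(weight_E, dtype=float)
    rng = np.random.default_rng(seed)
    es_bar = weighted_mean_ES(E, w)
    es_ci = bootstrap_weighted_mean(E, w, n_boot=n_boot, seed=rng)
    result = GroupResult(
        label=label,
        n=int(E.size),
        E_S_bar=es_bar,
        E_S_ci=es_ci,
        E_S_median=float(np.median(E)),
    )
    peaks = list(peaks)
    if len(peaks) < 3:
        result.verdict = "not_testable"
        result.note = "fewer than 3 peaked curves"
        return result
    params, _ = fit_interspecific_BA(peaks)
    el_ci = bootstrap_EL(peaks, n_boot=n_boot, seed=rng)
    result.E_L = params.E
    result.E_L_ci = el_ci
    verdict, frac, note = hib_test(
        es_ci, el_ci, ES_point=es_bar, EL_point=params.E,
        overlap_threshold=overlap_threshold,
    )
    result.verdict = verdict
    result.overlap_fraction = frac
    result.note = note
    return result
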