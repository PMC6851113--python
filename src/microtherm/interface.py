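"""Dataset ingest, result serialisation and the end-to-end pipeline.

Input is a long-format delimited table, one row per rate observation,
grouped into curves by ``curve_id``.  Units are normalised at this
boundary and nowhere else: temperatures arrive in degrees Celsius,
rates in any recognised reciprocal-time unit (converted to s^-1), and
doubling times are converted to specific growth rates via
``mu = ln(2)/t_d``.  Rows that cannot be normalised are rejected with a
reason and reported, never silently dropped.

``run_pipeline`` chains the stages in order — ingest, pseudoreplicate
pooling, per-curve fitting, break-point niche classification, per-group
hotter-is-better inference, the adaptation regression, and optionally an
ecosystem flux grid parameterised from the estimates — and returns the
full artifact bundle plus a manifest of the configuration and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .fitting import (
    LN2,
    FitConfig,
    RateObservation,
    SSFit,
    TPCRecord,
    deduplicate_replicates,
    fit_dataset,
    rate_unit_factor,
)
from .groups import (
    BreakpointResult,
    GroupResult,
    RegressionResult,
    analyse_group,
    breakpoint_analysis,
    classify_niche,
    tpk_tlab_regression,
)
from .ecoflux import composition_grid

logger = logging.getLogger("microtherm")

REQUIRED_COLUMNS = ("curve_id", "strain_id", "kingdom", "trait", "temp_c", "rate", "rate_unit")
TAXONOMY_COLUMNS = ("kingdom", "phylum", "class", "order", "family", "genus")

# time units accepted for doubling times, in seconds
_TIME_UNIT_SECONDS = {
    "s": 1.0, "sec": 1.0, "second": 1.0,
    "min": 60.0, "minute": 60.0,
    "h": 3600.0, "hr": 3600.0, "hour": 3600.0,
    "d": 86400.0, "day": 86400.0,
}


class SchemaError(ValueError):
    """The input table does not match the dataset schema."""


@dataclass
class IngestReport:
    n_rows: int = 0
    n_accepted: int = 0
    n_curves: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _normalise_rate(row) -> tuple[Optional[float], Optional[str]]:
    """Convert one row's rate to s^-1; returns (value, rejection reason)."""
    value = row.get("rate")
    unit = str(row.get("rate_unit", "")).strip()
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return None, "non_finite_rate"
    try:
        value = float(value)
    except (TypeError, ValueError):
        return None, "non_numeric_rate"
    is_td = bool(row.get("is_doubling_time", False))
    if is_td:
        secs = _TIME_UNIT_SECONDS.get(unit.lower())
        if secs is None:
            return None, f"unrecognised_time_unit:{unit}"
        if value <= 0:
            return None, "non_positive_doubling_time"
        return LN2 / (value * secs), None
    factor = rate_unit_factor(unit)
    if factor is None:
        return None, f"unrecognised_rate_unit:{unit}"
    rate = value * factor
    if rate < 0:
        return None, "negative_rate"
    return rate, None


def read_dataset(path, min_obs: int = 1) -> tuple[list[TPCRecord], IngestReport]:
    """Read a long-format observation table into curve records.

    The delimiter is auto-detected (comma or tab).  Raises
    :class:`SchemaError` if a required column is missing; individual
    rows failing unit normalisation are rejected with a reason recorded
    in the report.  Duplicate (curve, temperature, rate) rows warn but
    are kept, matching how replicated measurements appear in practice.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    report = IngestReport(n_rows=len(df))
    dup_mask = df.duplicated(subset=["curve_id", "temp_c", "rate"], keep=False)
    if dup_mask.any():
        report.warnings.append(
            f"{int(dup_mask.sum())} duplicate (curve_id, temp_c, rate) rows kept"
        )

    records: dict[str, dict] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        rowd = row.to_dict()
        temp = rowd.get("temp_c")
        try:
            temp = float(temp)
        except (TypeError, ValueError):
            report.rejected.append((int(idx), "non_numeric_temperature"))
            continue
        if not np.isfinite(temp):
            report.rejected.append((int(idx), "non_finite_temperature"))
            continue
        rate, reason = _normalise_rate(rowd)
        if reason is not None:
            report.rejected.append((int(idx), reason))
            continue
        trait = str(rowd.get("trait", "growth")).strip()
        if trait not in ("growth", "flux"):
            report.rejected.append((int(idx), f"unknown_trait:{trait}"))
            continue
        cid = str(rowd["curve_id"])
        if cid not in records:
            taxonomy = {
                c: str(rowd[c])
                for c in TAXONOMY_COLUMNS
                if c in rowd and pd.notna(rowd[c])
            }
            t_lab = rowd.get("t_lab_c")
            records[cid] = {
                "curve_id": cid,
                "strain_id": str(rowd.get("strain_id", "")),
                "species": str(rowd.get("species", "") or ""),
                "taxonomy": taxonomy,
                "trait_kind": trait,
                "flux_name": rowd.get("flux_name") if pd.notna(rowd.get("flux_name")) else None,
                "t_lab_c": float(t_lab) if t_lab is not None and pd.notna(t_lab) else None,
                "metabolism": rowd.get("metabolism") if pd.notna(rowd.get("metabolism")) else None,
                "pathogen": bool(rowd["pathogen"]) if "pathogen" in rowd and pd.notna(rowd.get("pathogen")) else None,
                "study_id": str(rowd.get("study_id", "") or ""),
                "observations": [],
            }
            order.append(cid)
        records[cid]["observations"].append(RateObservation(temp, rate))
        report.n_accepted += 1

    out = [TPCRecord(**records[cid]) for cid in order
           if len(records[cid]["observations"]) >= min_obs]
    report.n_curves = len(out)
    logger.info(
        "ingest: %d rows read, %d accepted, %d rejected, %d curves",
        report.n_rows, report.n_accepted, report.n_rejected, report.n_curves,
    )
    return out, report


# ---------------------------------------------------------------------------
# result serialisation

FLOAT_FORMAT = "%.12g"


_FIT_COLUMNS = (
    "curve_id", "B0", "E", "E_D", "T_pk_K", "T_ref_K", "P_pk", "SD_E",
    "SD_Ppk", "weight_E", "weight_Ppk", "rss", "n_points", "converged",
    "has_peak", "excluded_reason",
)


def fits_to_dataframe(fits: Sequence[SSFit]) -> pd.DataFrame:
    if not fits:
        return pd.DataFrame(columns=_FIT_COLUMNS)
    rows = []
    for f in fits:
        p = f.params
        rows.append(
            {
                "curve_id": f.curve_id,
                "B0": p.B0 if p else None,
                "E": p.E if p else None,
                "E_D": p.E_D if p else None,
                "T_pk_K": p.T_pk if p else None,
                "T_ref_K": p.T_ref if p else None,
                "P_pk": f.P_pk,
                "SD_E": f.SD_E,
                "SD_Ppk": f.SD_Ppk,
                "weight_E": f.weight_E,
                "weight_Ppk": f.weight_Ppk,
                "rss": f.rss,
                "n_points": f.n_points,
                "converged": f.converged,
                "has_peak": f.has_peak,
                "excluded_reason": f.excluded_reason or "",
            }
        )
    return pd.DataFrame(rows)


def write_fits(fits: Sequence[SSFit], path, covariance_sidecar: bool = True) -> Path:
    """Fit table as CSV; covariance matrices as a JSON sidecar per curve."""
    path = Path(path)
    fits_to_dataframe(fits).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if covariance_sidecar:
        side = {
            f.curve_id: np.asarray(f.covariance).tolist()
            for f in fits
            if f.covariance is not None
        }
        path.with_suffix(".cov.json").write_text(json.dumps(side))
    return path


def read_fits(path) -> pd.DataFrame:
    """Read a fit table back; the lossless inverse of :func:`write_fits`."""
    df = pd.read_csv(path)
    df["excluded_reason"] = df["excluded_reason"].fillna("")
    return df


def group_results_to_dataframe(results: Sequence[GroupResult]) -> pd.DataFrame:
    rows = []
    for g in results:
        rows.append(
            {
                "group": g.label,
                "n": g.n,
                "E_S_bar": g.E_S_bar,
                "E_S_ci_low": g.E_S_ci[0],
                "E_S_ci_high": g.E_S_ci[1],
                "E_S_median": g.E_S_median,
                "E_L": g.E_L,
                "E_L_ci_low": g.E_L_ci[0] if g.E_L_ci else None,
                "E_L_ci_high": g.E_L_ci[1] if g.E_L_ci else None,
                "overlap_fraction": g.overlap_fraction,
                "verdict": g.verdict,
                "note": g.note or "",
            }
        )
    return pd.DataFrame(rows)


def write_results(obj, path, fmt: str = "csv") -> Path:
    """Serialise fits, group results or composition grids.

    CSV uses 12 significant digits so a read-back reproduces every value.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(obj, indent=1, default=_json_default))
        return path
    if isinstance(obj, pd.DataFrame):
        df = obj
    elif len(obj) and isinstance(obj[0], SSFit):
        df = fits_to_dataframe(obj)
    elif len(obj) and isinstance(obj[0], GroupResult):
        df = group_results_to_dataframe(obj)
    elif isinstance(obj, dict) and "percent_change" in obj:
        df = grid_to_dataframe(obj)
    else:
        df = pd.DataFrame(obj)
    try:
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    return path


def grid_to_dataframe(grid: dict) -> pd.DataFrame:
    """Tidy (delta, beta, pct_change, emergent_E, Q10) rows from a grid."""
    deltas, betas = grid["delta"], grid["beta"]
    dd, bb = np.meshgrid(deltas, betas, indexing="ij")
    return pd.DataFrame(
        {
            "delta": dd.ravel(),
            "beta": bb.ravel(),
            "pct_change": grid["percent_change"].ravel(),
            "emergent_E": grid["emergent_E"].ravel(),
            "Q10": grid["Q10"].ravel(),
        }
    )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    if hasattr(o, "__dict__"):
        return o.__dict__
    return str(o)


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    fit: FitConfig = field(default_factory=FitConfig)
    n_boot: int = 1000
    overlap_threshold: float = 0.5
    niche_break_c: Optional[float] = None  # None -> estimate per kingdom
    min_group_n: int = 3
    pool_pseudoreplicates: bool = True
    ecosystem_grids: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    fits: list[SSFit]
    ingest_report: Optional[IngestReport]
    breakpoints: dict[str, BreakpointResult]
    group_results: list[GroupResult]
    tlab_regressions: dict[str, RegressionResult]
    grids: dict[str, dict]
    manifest: dict


def run_pipeline(
    records: Sequence[TPCRecord],
    config: Optional[PipelineConfig] = None,
    ingest_report: Optional[IngestReport] = None,
) -> PipelineResult:
    """Chain the full analysis over a set of curve records.

    Stages: pool pseudoreplicates, fit every curve, locate the
    mesophile/thermophile break per kingdom on the peaked curves,
    classify niches, run the hotter-is-better comparison per
    kingdom x niche group, regress the thermal optimum on the culture
    temperature per kingdom, and (optionally) evaluate ecosystem flux
    grids parameterised from the group estimates.  All derived seeds are
    recorded in the manifest.
    """
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    boot_seed, grid_seed = ss.spawn(2)

    if config.pool_pseudoreplicates:
        records = deduplicate_replicates(records, "pool_pseudoreplicates")
    fit_cfg = config.fit
    fits = fit_dataset(records, fit_cfg)
    by_id = {r.curve_id: r for r in records}
    n_usable = sum(f.usable for f in fits)
    n_peaked = sum(f.usable and f.has_peak for f in fits)
    logger.info(
        "fit: %d curves, %d usable, %d peaked, %d excluded",
        len(fits), n_usable, n_peaked, len(fits) - n_usable,
    )

    # break-point per kingdom on peaked curves
    kingdoms = sorted({by_id[f.curve_id].kingdom or "unknown" for f in fits})
    breakpoints: dict[str, BreakpointResult] = {}
    group_results: list[GroupResult] = []
    tlab: dict[str, RegressionResult] = {}
    rng = np.random.default_rng(boot_seed)
    for kingdom in kingdoms:
        kfits = [
            f for f in fits
            if f.usable and (by_id[f.curve_id].kingdom or "unknown") == kingdom
        ]
        peaked = [f for f in kfits if f.has_peak]
        peaks = [(f.params.T_pk, f.P_pk, f.weight_Ppk) for f in peaked]

        break_c = config.niche_break_c
        if break_c is None and len(peaks) >= 8:
            try:
                bp = breakpoint_analysis([(t, p) for t, p, _ in peaks])
                breakpoints[kingdom] = bp
                if bp.significant:
                    break_c = bp.break_temperature_c
            except ValueError as exc:
                logger.info("breakpoint (%s): %s", kingdom, exc)

        if break_c is not None:
            niches = {
                f.curve_id: classify_niche(f.params.T_pk - 273.15, break_c)
                for f in kfits
            }
        else:
            niches = {f.curve_id: "all" for f in kfits}

        for niche in sorted(set(niches.values())):
            members = [f for f in kfits if niches[f.curve_id] == niche]
            if len(members) < config.min_group_n:
                continue
            E = [f.params.E for f in members]
            w = [f.weight_E for f in members]
            gp = [
                (f.params.T_pk, f.P_pk, f.weight_Ppk)
                for f in members
                if f.has_peak
            ]
            group_results.append(
                analyse_group(
                    f"{kingdom}:{niche}",
                    E,
                    w,
                    gp,
                    n_boot=config.n_boot,
                    seed=rng,
                    overlap_threshold=config.overlap_threshold,
                )
            )

        pairs = [
            (by_id[f.curve_id].t_lab_c, f.params.T_pk - 273.15)
            for f in kfits
            if by_id[f.curve_id].t_lab_c is not None
        ]
        if pairs:
            tlab[kingdom] = tpk_tlab_regression(
                [p[0] for p in pairs], [p[1] for p in pairs]
            )

    grids: dict[str, dict] = {}
    if config.ecosystem_grids:
        from .ecoflux import long_term_scenario, short_term_scenario

        grids["short_term"] = composition_grid(short_term_scenario())
        grids["long_term"] = composition_grid(long_term_scenario())

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "boot_seed": boot_seed.entropy,
        "grid_seed": grid_seed.entropy,
        "n_curves": len(fits),
        "n_usable": n_usable,
        "n_peaked": n_peaked,
        "excluded_by_reason": _exclusion_counts(fits),
        "config": {
            "n_boot": config.n_boot,
            "overlap_threshold": config.overlap_threshold,
            "niche_break_c": config.niche_break_c,
            "min_group_n": config.min_group_n,
            "fit": vars(fit_cfg),
        },
    }
    return PipelineResult(
        fits=fits,
        ingest_report=ingest_report,
        breakpoints=breakpoints,
        group_results=group_results,
        tlab_regressions=tlab,
        grids=grids,
        manifest=manifest,
    )


def _exclusion_counts(fits: Sequence[SSFit]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for f in fits:
        if f.excluded_reason:
            counts[f.excluded_reason] = counts.get(f.excluded_reason, 0) + 1
    return counts
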