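"""Minirhizotron vs destructive-core method comparison.

Per depth stratum, minirhizotron root length is regressed against soil-core
root length density (RLD) by ordinary least squares, reporting slope,
intercept, R-squared and the two-sided t-test on the slope.  Quarter
summaries are reduced to a descriptive mean +/- sd table; the mixed-model
ANOVA such data feed into is left to dedicated statistical software — this
module emits the tidy long-format table it consumes.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEPTH_BIN_LABELS, QUARTER_LABELS, CoreRecord, RhizopipeError
from .geometry import DepthProfile, QuarterSummary

logger = logging.getLogger("rhizopipe")

#: Strata reported by default: topsoil, pooled subsoil, and each subsoil bin.
DEFAULT_STRATA: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("0-30", ("0-30",)),
    ("30-120", ("30-60", "60-90", "90-120")),
    ("30-60", ("30-60",)),
    ("60-90", ("60-90",)),
    ("90-120", ("90-120",)),
)


@dataclass
class RegressionResult:
    """OLS fit of y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    slope_p: float
    n: int
    stratum: str = ""
    fit_ok: bool = True


def fit_linear(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Closed-form OLS with R^2 and a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise RhizopipeError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise RhizopipeError(f"need at least 3 points, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise RhizopipeError("non-finite values in regression input")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise RhizopipeError("zero variance in x")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    dof = n - 2
    if ss_res == 0.0:
        slope_p = 0.0
    else:
        se = np.sqrt(ss_res / dof / sxx)
        tstat = slope / se if se > 0 else np.inf
        slope_p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return RegressionResult(
        slope=float(slope),
        intercept=intercept,
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        slope_p=slope_p,
        n=n,
    )


def _pair_observations(
    profiles: list[DepthProfile],
    cores: list[CoreRecord],
    bin_labels: tuple[str, ...],
    date_window_days: int | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair per-tube stratum lengths with core RLD by plot and nearest date.

    Returns (core RLD x, minirhizotron length y, n_dropped).  The stratum
    value of a profile is the sum over its bins; the core value is the sum
    of RLD over the same bins for the nearest sampling date within the
    window (no window -> nearest date regardless of lag).
    """
    core_by_plot: dict[str, dict[_dt.date, dict[str, float]]] = {}
    for rec in cores:
        core_by_plot.setdefault(rec.plot_id, {}).setdefault(rec.sample_date, {})[
            rec.depth_bin
        ] = rec.rld
    xs, ys = [], []
    dropped = 0
    for prof in profiles:
        plot = prof.plot_id or prof.tube_id
        dates = core_by_plot.get(plot)
        if not dates:
            dropped += 1
            continue
        prof_date = (
            prof.scan_date
            if isinstance(prof.scan_date, _dt.date)
            else _dt.date.fromisoformat(str(prof.scan_date))
        )
        best = min(dates, key=lambda d: abs((d - prof_date).days))
        if date_window_days is not None and abs((best - prof_date).days) > date_window_days:
            dropped += 1
            continue
        bins = dates[best]
        if not all(lab in bins for lab in bin_labels):
            dropped += 1
            continue
        xs.append(sum(bins[lab] for lab in bin_labels))
        ys.append(sum(prof.bins[lab] for lab in bin_labels))
    return np.asarray(xs), np.asarray(ys), dropped


def compare_methods(
    profiles: list[DepthProfile],
    cores: list[CoreRecord],
    strata: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_STRATA,
    date_window_days: int | None = 21,
) -> list[RegressionResult]:
    """One regression of minirhizotron length on core RLD per stratum.

    Unmatched plots are dropped with a logged count; a stratum with fewer
    than 3 pairs is returned flagged unfit rather than fitted.
    """
    results = []
    for name, bin_labels in strata:
        x, y, dropped = _pair_observations(profiles, cores, bin_labels, date_window_days)
        if dropped:
            logger.info("stratum %s: dropped %d unmatched profiles", name, dropped)
        if len(x) < 3 or np.var(x) == 0:
            results.append(
                RegressionResult(
                    slope=np.nan,
                    intercept=np.nan,
                    r_squared=np.nan,
                    slope_p=np.nan,
                    n=len(x),
                    stratum=name,
                    fit_ok=False,
                )
            )
            continue
        res = fit_linear(x, y)
        res.stratum = name
        results.append(res)
    return results


def quarter_contrast(summaries: list[QuarterSummary]) -> pd.DataFrame:
    """Descriptive mean +/- sd of root length per quarter across tubes x dates.

    Returns a tidy table (quarter, mean_cm, sd_cm, n); the sd of a single
    observation is reported as missing.  Suitable as input for external
    mixed-model software.
    """
    if not summaries:
        raise RhizopipeError("quarter_contrast requires at least one summary")
    rows = []
    for lab in QUARTER_LABELS:
        vals = np.asarray([s.lengths[lab] for s in summaries], dtype=np.float64)
        rows.append(
            {
                "quarter": lab,
                "mean_cm": float(vals.mean()),
                "sd_cm": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def quarter_long_table(summaries: list[QuarterSummary]) -> pd.DataFrame:
    """Long-format per-observation table for external mixed-model analysis."""
    rows = []
    for s in summaries:
        for lab in QUARTER_LABELS:
            rows.append(
                {
                    "tube_id": s.tube_id,
                    "plot_id": s.plot_id,
                    "scan_date": str(s.scan_date),
                    "quarter": lab,
                    "root_length_cm": s.lengths[lab],
                }
            )
    return pd.DataFrame(rows)


def regression_table(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "slope_p": r.slope_p,
                "n": r.n,
                "fit_ok": r.fit_ok,
            }
            for r in results
        ]
    )
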