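"""Grouped, many-instance workflows producing tidy long-format tables.

These mirror the nest/map pattern of grouped track analysis: split a
relocation table into sampling instances, apply a set of home-range
estimators to each, and flatten everything into one long table suitable for
population-level summaries (sex contrasts, land-cover covariates, weekly
space-use series).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from shapely.ops import unary_union

from .errors import DomainError, HomeRangeError
from .estimates import hr_area
from .geometric import Mcp, Locoh
from .probabilistic import Kde, Akde
from .raster import TemplateRaster
from .tracks import GroupedTracks, floor_week, group_tracks

__all__ = [
    "ESTIMATOR_LABELS",
    "batch_home_ranges",
    "sex_difference_summary",
    "zonal_proportion",
    "weekly_home_ranges",
]

#: labels accepted by the batch workflows, in canonical output order
ESTIMATOR_LABELS = ("hr_mcp", "hr_kde", "hr_locoh", "hr_akde", "hr_akde_error")


def _build_estimator(label, levels, uere, ncol):
    if label == "hr_mcp":
        return Mcp(levels=levels)
    if label == "hr_kde":
        return Kde(levels=levels, ncol=ncol)
    if label == "hr_locoh":
        return Locoh(n="auto", levels=levels)
    if label == "hr_akde":
        return Akde(levels=levels, model="auto", ncol=ncol)
    if label == "hr_akde_error":
        return Akde(levels=levels, model="auto", uere=uere, ncol=ncol)
    raise DomainError(f"unknown estimator label {label!r} (choose from {ESTIMATOR_LABELS})")


def batch_home_ranges(
    groups: GroupedTracks,
    estimators=("hr_mcp", "hr_kde", "hr_locoh", "hr_akde", "hr_akde_error"),
    levels=(0.95,),
    uere: float = 1.67,
    ncol: int = 200,
    keep_estimates: bool = False,
):
    """Apply each estimator to each group; return one long result table.

    Failures in a single group (degenerate geometry, non-convergence) are
    recorded as rows with ``what = "error"`` and the message in ``error``;
    they never abort the batch.

    Returns the long table; with ``keep_estimates=True`` also a dict mapping
    ``(group_key, estimator)`` to the fitted estimator objects.
    """
    for label in estimators:
        if label not in ESTIMATOR_LABELS:
            raise DomainError(f"unknown estimator label {label!r}")
    rows = []
    fitted = {}
    for key, track in groups.items():
        keyd = dict(zip(groups.keys, key))
        for label in estimators:
            try:
                est = _build_estimator(label, levels, uere, ncol).fit(track)
            except HomeRangeError as exc:
                rows.append(
                    {**keyd, "estimator": label, "level": np.nan, "what": "error",
                     "area": np.nan, "error": str(exc)}
                )
                continue
            if keep_estimates:
                fitted[(key, label)] = est
            for _, r in hr_area(est).iterrows():
                rows.append(
                    {**keyd, "estimator": label, "level": r["level"], "what": r["what"],
                     "area": r["area"], "error": ""}
                )
    result = pd.DataFrame(rows)
    return (result, fitted) if keep_estimates else result


def sex_difference_summary(result: pd.DataFrame, group_sex: dict, id_col: str = "id") -> pd.DataFrame:
    """Per-estimator population summary of natural-log home-range area by sex.

    Averages ln(area) of the per-animal estimates within each sex, with
    two-sided 95% t-intervals (n - 1 df), and the male-minus-female
    difference with a Welch two-sample t-interval. Sexes with fewer than two
    animals are flagged (CI undefined).

    Returns rows (estimator, group in {f, m, m-f}, n, mean, lci, uci, flagged).
    """
    est_rows = result[(result["what"] == "estimate")].copy()
    n_err = int((result["what"] == "error").sum())
    if n_err:
        warnings.warn(f"sex summary: skipping {n_err} error rows")
    est_rows["sex"] = est_rows[id_col].map(lambda i: str(group_sex[i]).lower())
    est_rows["log_area"] = np.log(est_rows["area"])
    out = []
    for (estimator, level), sub in est_rows.groupby(["estimator", "level"]):
        per_sex = {}
        for sex, ss in sub.groupby("sex"):
            vals = ss["log_area"].to_numpy()
            n = len(vals)
            mean = float(np.mean(vals))
            if n >= 2:
                half = stats.t.ppf(0.975, n - 1) * np.std(vals, ddof=1) / np.sqrt(n)
                lci, uci, flagged = mean - half, mean + half, False
            else:
                lci = uci = np.nan
                flagged = True
            per_sex[sex] = (vals, n, mean)
            out.append(
                {"estimator": estimator, "level": level, "group": sex, "n": n,
                 "mean": mean, "lci": lci, "uci": uci, "flagged": flagged}
            )
        if "m" in per_sex and "f" in per_sex:
            vm, nm, mm = per_sex["m"]
            vf, nf, mf = per_sex["f"]
            diff = mm - mf
            if nm >= 2 and nf >= 2:
                sm2, sf2 = np.var(vm, ddof=1), np.var(vf, ddof=1)
                se = np.sqrt(sm2 / nm + sf2 / nf)
                if se > 0:
                    df = (sm2 / nm + sf2 / nf) ** 2 / (
                        (sm2 / nm) ** 2 / (nm - 1) + (sf2 / nf) ** 2 / (nf - 1)
                    )
                    half = stats.t.ppf(0.975, df) * se
                else:  # degenerate: all areas identical within a sex
                    half = 0.0
                lci, uci, flagged = diff - half, diff + half, False
            else:
                lci = uci = np.nan
                flagged = True
            out.append(
                {"estimator": estimator, "level": level, "group": "m-f", "n": nm + nf,
                 "mean": diff, "lci": lci, "uci": uci, "flagged": flagged}
            )
    return pd.DataFrame(out)


def zonal_proportion(isopleths, landcover: np.ndarray, trast: TemplateRaster) -> float:
    """Mean land-cover value over cells whose centers fall in the isopleths.

    ``isopleths`` may be a fitted estimator, an isopleth table, or a
    (multi)polygon; multiple polygons are pooled. For a binary forest raster
    this is the proportion of forest within the home range. Returns NaN
    (with a warning) when no cell center falls inside.
    """
    if hasattr(isopleths, "isopleth_table"):
        isopleths = isopleths.isopleth_table()
    if isinstance(isopleths, pd.DataFrame):
        geom = unary_union(list(isopleths["geometry"]))
    else:
        geom = isopleths
    mask = trast.centers_covered_by(geom)
    if not mask.any():
        warnings.warn("no raster cell center inside the isopleths; proportion undefined")
        return float("nan")
    return float(np.asarray(landcover, dtype=float)[mask].mean())


def weekly_home_ranges(
    track_table: pd.DataFrame,
    estimators=("hr_mcp", "hr_kde", "hr_locoh", "hr_akde", "hr_akde_error"),
    min_n: int = 11,
    levels=(0.95,),
    crs: int | None = None,
    week_start: str = "monday",
    uere: float = 1.67,
    ncol: int = 200,
):
    """Per-animal, per-week home ranges from a relocation table.

    Groups fixes by (id, week) where the week is the fix time floored to the
    week boundary; weeks with fewer than ``min_n`` fixes are dropped (the
    default keeps strictly more than 10 observations). The remaining groups
    are run through :func:`batch_home_ranges`.
    """
    df = track_table.copy()
    if crs is None:
        crs = track_table.attrs.get("crs")
    t = pd.to_datetime(df["t"], utc=True)
    df["week"] = floor_week(pd.DatetimeIndex(t), week_start=week_start)
    groups = group_tracks(df, by=["id", "week"], crs=crs)
    groups = groups.filter_min_size(min_n)
    return batch_home_ranges(groups, estimators, levels=levels, uere=uere, ncol=ncol)
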