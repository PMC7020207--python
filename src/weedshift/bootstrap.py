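"""Stratified bootstrap for effort-equalized comparison of two surveys.

The 2000s survey sampled far more fields than the 1970s one (484 vs 174
across the five regional strata), so comparing raw frequencies would
confound status change with sampling effort.  Resampling the 2000s fields
with replacement *within region*, at exactly the 1970s stratum sizes,
yields the distribution of the metric that the 2000s flora would have
produced under the 1970s design; the percentile interval of that
distribution is the 95% CI against which the 1970s point value is tested.

Status codes: "+" increase (P1 below the CI), "-" decrease (P1 above),
"=" stable (inside), "N" new species (P1 below the recording floor but
present in the 2000s), "?" undeterminable.  Within-2000s trends are
classified from the Spearman rank correlation of the yearly metric with
year, with "(+)"/"(-)" marking marginal trends (alpha <= p < 0.10).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .commonness import CLASS_MIDPOINTS, field_level_scores, n_fields
from .errors import InsufficientDataError

STATUS_CODES = ("+", "-", "=", "N", "?")


def _field_matrices(table, period=None, crop=None, plot="control"):
    """Pivot a survey selection to fields x species presence/midpoint arrays.

    Returns (regions per field, field ids, species list, presence bool
    matrix, midpoint matrix).  Fields with no recorded species still count
    in the frequency denominator and are kept as all-zero rows.
    """
    sel = table
    if period is not None:
        sel = sel[sel["period"] == period]
    if crop is not None:
        sel = sel[sel["crop"] == crop]
    if plot is not None:
        sel = sel[sel["plot"] == plot]
    if sel.empty:
        raise InsufficientDataError("no survey rows match the selection")
    fields = sel[["field_id", "region"]].drop_duplicates("field_id")
    scores = field_level_scores(table, period=period, crop=crop, plot=plot)
    scores = scores.assign(mid=scores["score"].map(CLASS_MIDPOINTS))
    mid = scores.pivot_table(
        index="field_id", columns="species", values="mid", aggfunc="first"
    ).reindex(fields["field_id"]).fillna(0.0)
    presence = mid.to_numpy() > 0
    return (
        fields["region"].to_numpy(),
        fields["field_id"].to_numpy(),
        list(mid.columns),
        presence,
        mid.to_numpy(),
    )


def stratified_resample(table: pd.DataFrame, strata_sizes: dict,
                        rng: np.random.Generator, period=None, crop=None,
                        plot=None) -> pd.DataFrame:
    """One stratified resample of whole fields, with replacement per region.

    The returned table has exactly ``strata_sizes[r]`` fields in region
    ``r``; resampled duplicates receive fresh field ids (``<id>__b<k>``)
    so the result is again a valid survey table.
    """
    sel = table
    if period is not None:
        sel = sel[sel["period"] == period]
    if crop is not None:
        sel = sel[sel["crop"] == crop]
    if plot is not None:
        sel = sel[sel["plot"] == plot]
    by_region = {r: grp["field_id"].unique() for r, grp in sel.groupby("region")}
    missing = [r for r in strata_sizes if r not in by_region]
    if missing:
        raise ValueError(f"regions absent from the table: {missing}")
    rows = sel.set_index("field_id")
    pieces = []
    k = 0
    for region in sorted(strata_sizes):
        pool = np.sort(by_region[region])
        draw = rng.choice(pool, size=strata_sizes[region], replace=True)
        for fid in draw:
            piece = rows.loc[[fid]].reset_index()
            piece["field_id"] = f"{fid}__b{k}"
            pieces.append(piece)
            k += 1
    return pd.concat(pieces, ignore_index=True)


def bootstrap_ci(table: pd.DataFrame, metric: str, strata_sizes: dict,
                 B: int = 1000, level: float = 0.95,
                 rng: np.random.Generator | None = None, period=None,
                 crop=None, plot="control") -> pd.DataFrame:
    """Bootstrap mean and percentile CI of frequency or abundance per species.

    Each of the B replicates draws ``strata_sizes[r]`` fields with
    replacement within region r.  A species absent from a replicate
    contributes frequency 0 to that replicate and is excluded from its
    abundance mean (abundance is defined over fields of presence only).

    Returns a DataFrame indexed by species with columns
    ``mean, ci_low, ci_high``.
    """
    if metric not in ("frequency", "abundance"):
        raise ValueError("metric must be 'frequency' or 'abundance'")
    if B < 2:
        raise ValueError("need at least B=2 bootstrap replicates")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(rng)
    regions, _, species, presence, mid = _field_matrices(
        table, period=period, crop=crop, plot=plot
    )
    missing = [r for r in strata_sizes if not (regions == r).any()]
    if missing:
        raise ValueError(f"regions absent from the table: {missing}")
    pools = {r: np.flatnonzero(regions == r) for r in sorted(strata_sizes)}
    n_total = sum(strata_sizes.values())
    stats_out = np.empty((B, len(species)))
    for b in range(B):
        idx = np.concatenate([
            rng.choice(pools[r], size=strata_sizes[r], replace=True)
            for r in sorted(strata_sizes)
        ])
        assert idx.size == n_total  # stratum-size conservation, every replicate
        pres_b = presence[idx]
        if metric == "frequency":
            stats_out[b] = pres_b.mean(axis=0)
        else:
            n_pres = pres_b.sum(axis=0)
            with np.errstate(invalid="ignore"):
                stats_out[b] = np.where(
                    n_pres > 0, mid[idx].sum(axis=0) / n_pres, np.nan
                )
    alpha = (1 - level) / 2
    if metric == "frequency":
        mean = stats_out.mean(axis=0)
        lo, hi = np.percentile(stats_out, [100 * alpha, 100 * (1 - alpha)], axis=0)
    else:
        mean = np.nanmean(stats_out, axis=0)
        lo, hi = np.nanpercentile(
            stats_out, [100 * alpha, 100 * (1 - alpha)], axis=0
        )
    return pd.DataFrame(
        {"mean": mean, "ci_low": lo, "ci_high": hi}, index=pd.Index(species, name="species")
    )


def classify_status(point_p1, ci, detection_threshold: float = 0.0,
                    present_p2: bool = True) -> str:
    """Categorical status of one species from its 1970s point and 2000s CI.

    Parameters
    ----------
    point_p1 : float or None
        1970s value of the metric; None when unrecorded.
    ci : (low, high)
        Percentile bootstrap CI of the effort-equalized 2000s value.
    detection_threshold : float
        Recording floor of the first survey; a point below it counts as
        "not recorded" (the 1970s survey kept only the most frequent taxa).
    present_p2 : bool
        Whether the species occurs at all in the 2000s survey.
    """
    low, high = ci
    if not low <= high:
        raise ValueError(f"invalid CI ({low}, {high})")
    unknown = point_p1 is None or (
        point_p1 is not None and np.isnan(point_p1)
    ) or (point_p1 is not None and not np.isnan(point_p1)
          and point_p1 < detection_threshold)
    if unknown:
        return "N" if present_p2 else "?"
    if point_p1 < low:
        return "+"
    if point_p1 > high:
        return "-"
    return "="


def _exact_spearman_pvalue(x_rank: np.ndarray, y_rank: np.ndarray,
                           rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 9).

    Enumerates all n! orderings of one rank vector; midranks make the
    enumeration valid under ties.
    """
    n = len(x_rank)
    xs = (x_rank - x_rank.mean()) / x_rank.std()
    ys = (y_rank - y_rank.mean()) / y_rank.std()
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (xs[np.newaxis, :] * ys[perms]).mean(axis=1)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_trend_test(values, years=None, exact_max_n: int = 9):
    """Spearman rho of a yearly metric against year, with p-value.

    Exact permutation p for small series (the seven-year window makes the
    full null cheap); t-approximation with midrank ties otherwise.
    """
    values = np.asarray(values, dtype=float)
    if years is None:
        years = np.arange(len(values))
    years = np.asarray(years, dtype=float)
    n = len(values)
    if n < 4:
        raise InsufficientDataError("need at least 4 yearly values for a trend")
    if np.ptp(values) == 0 or np.ptp(years) == 0:  # constant series: no trend
        return 0.0, 1.0
    rho = stats.spearmanr(years, values).statistic
    if n <= exact_max_n:
        xr = stats.rankdata(years)
        yr = stats.rankdata(values)
        p = _exact_spearman_pvalue(xr, yr, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho * rho))
        p = 2 * stats.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


@dataclass(frozen=True)
class TrendCall:
    species: str
    rho: float
    p: float
    trend: str


def classify_trend(rho: float, p: float, alpha: float = 0.05,
                   alpha_marginal: float = 0.10) -> str:
    """Map (rho, p) to a trend code: +/- significant, (+)/(-) marginal, = none."""
    if p < alpha:
        return "+" if rho > 0 else "-"
    if p < alpha_marginal:
        return "(+)" if rho > 0 else "(-)"
    return "="


def yearly_trend(per_year_metric: dict, species: str = "",
                 alpha: float = 0.05, alpha_marginal: float = 0.10) -> TrendCall:
    """Spearman trend call for one species' yearly metric series."""
    years = sorted(per_year_metric)
    values = [per_year_metric[y] for y in years]
    rho, p = spearman_trend_test(values, years)
    return TrendCall(species, rho, p, classify_trend(rho, p, alpha, alpha_marginal))


def status_table(table: pd.DataFrame, p1_points: pd.DataFrame,
                 strata_sizes: dict, metric: str, B: int = 1000,
                 level: float = 0.95, detection_threshold: float = 0.0,
                 rng=None, crop=None, plot="control") -> pd.DataFrame:
    """Status calls for every 2000s species of a metric.

    ``p1_points`` is a Series (species -> 1970s point value); species
    missing from it are treated as unrecorded in the 1970s.
    """
    ci = bootstrap_ci(
        table, metric, strata_sizes, B=B, level=level, rng=rng,
        period="P2000s", crop=crop, plot=plot,
    )
    p1 = p1_points.reindex(ci.index)
    out = ci.copy()
    out["point_P1"] = p1
    out["status"] = [
        classify_status(
            None if np.isnan(p1.loc[sp]) else float(p1.loc[sp]),
            (row["ci_low"], row["ci_high"]),
            detection_threshold=detection_threshold,
            present_p2=True,
        )
        for sp, row in ci.iterrows()
    ]
    return out


def per_year_metric(table: pd.DataFrame, metric: str, strata_sizes: dict,
                    B: int = 200, rng=None, period="P2000s", crop=None,
                    plot="control") -> pd.DataFrame:
    """Effort-equalized yearly means of a metric (species x year).

    Applies the same stratified resampling within each year so that the
    yearly series is comparable across years despite shifting regional
    effort; strata default to the per-region minimum across years when a
    region is scarcer in some year (caller supplies the sizes).
    """
    rng = np.random.default_rng(rng)
    sel = table[table["period"] == period]
    years = sorted(sel["year"].unique())
    cols = {}
    for y in years:
        sub = sel[sel["year"] == y]
        ci = bootstrap_ci(
            sub, metric, strata_sizes, B=B, rng=rng, crop=crop, plot=plot
        )
        cols[y] = ci["mean"]
    out = pd.DataFrame(cols)
    if metric == "frequency":
        # a species unseen in a year has frequency 0, not missing
        out = out.fillna(0.0)
    return out


def trend_table(per_year: pd.DataFrame, alpha=0.05,
                alpha_marginal=0.10) -> pd.DataFrame:
    """Trend calls for every species from a species x year metric table."""
    rows = {}
    for sp, series in per_year.iterrows():
        try:
            call = yearly_trend(series.dropna().to_dict(), species=sp,
                                alpha=alpha, alpha_marginal=alpha_marginal)
            rows[sp] = {"rho": call.rho, "p": call.p, "trend": call.trend}
        except InsufficientDataError:
            # species observed in too few years for a trend call
            rows[sp] = {"rho": np.nan, "p": np.nan, "trend": "?"}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("species")
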