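"""The three facets of weed commonness, and the normalized change index.

* Regional frequency ``F``: fraction of surveyed fields in which a species
  occurs.
* Local mean abundance ``A``: mean density (individuals/m^2) over the
  fields of presence, estimated from cover-class midpoints::

      A = [11.5*n3 + 35.5*n4 + 75.5*n5 + 1.5*(N - n3 - n4 - n5)] / N

  where ``n3, n4, n5`` count fields scored 3, 4 and 5 and ``N`` is the
  total number of occurrences.  Classes "+", 1 and 2 all carry the minimum
  midpoint 1.5, which bounds ``A`` to [1.5, 75.5].
* Fidelity (specificity): percentage of a species' midpoint-estimated
  individuals found in the focal crop relative to all crops.

Change between two survey periods is expressed by the normalized index
``Ch = (S2 - S1) / (S2 + S1)``, bounded to [-1, 1] and antisymmetric under
period swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

#: density midpoint (individuals/m^2) per cover-abundance class
CLASS_MIDPOINTS = {"+": 1.5, "1": 1.5, "2": 1.5, "3": 11.5, "4": 35.5, "5": 75.5}

#: rank order of classes, used when collapsing multi-year records per field
_CLASS_ORDER = {"+": 0, "1": 1, "2": 2, "3": 3, "4": 4, "5": 5}


@dataclass(frozen=True)
class AbundanceClassCounts:
    """Counts of fields per high abundance class for one species."""

    n3: int
    n4: int
    n5: int
    N: int

    def __post_init__(self):
        if min(self.n3, self.n4, self.n5) < 0 or self.N < 0:
            raise ValueError("class counts must be nonnegative")
        if self.n3 + self.n4 + self.n5 > self.N:
            raise ValueError("n3 + n4 + n5 exceeds total occurrences N")


def field_level_scores(table: pd.DataFrame, period=None, crop=None,
                       plot="control") -> pd.DataFrame:
    """Collapse the survey to one score per (field, species).

    Fields surveyed in several years keep the maximum class recorded in
    that field (class order: + < 1 < 2 < 3 < 4 < 5); frequency and
    abundance are defined at field level, not per visit.
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
    sel = sel.assign(_rank=sel["score"].map(_CLASS_ORDER))
    idx = sel.groupby(["field_id", "species"])["_rank"].idxmax()
    return sel.loc[idx, ["field_id", "region", "species", "score"]].reset_index(
        drop=True
    )


def n_fields(table: pd.DataFrame, period=None, crop=None,
             plot="control") -> int:
    """Number of distinct fields in a selection (the frequency denominator)."""
    sel = table
    if period is not None:
        sel = sel[sel["period"] == period]
    if crop is not None:
        sel = sel[sel["crop"] == crop]
    if plot is not None:
        sel = sel[sel["plot"] == plot]
    return sel["field_id"].nunique()


def regional_frequency(table: pd.DataFrame, period=None, crop=None,
                       plot="control") -> pd.Series:
    """Per-species frequency of occurrence F over distinct fields.

    Control plots only by default: the unweeded control expresses the
    field's potential flora and is the unit both surveys share.
    """
    scores = field_level_scores(table, period=period, crop=crop, plot=plot)
    total = n_fields(table, period=period, crop=crop, plot=plot)
    counts = scores.groupby("species")["field_id"].nunique()
    return (counts / total).rename("F")


def class_counts(table: pd.DataFrame, period=None, crop=None,
                 plot="control") -> pd.DataFrame:
    """Per-species (n3, n4, n5, N) field counts for the abundance formula."""
    scores = field_level_scores(table, period=period, crop=crop, plot=plot)
    out = {}
    for sp, grp in scores.groupby("species"):
        s = grp["score"]
        out[sp] = (
            int((s == "3").sum()),
            int((s == "4").sum()),
            int((s == "5").sum()),
            int(len(s)),
        )
    return pd.DataFrame.from_dict(
        out, orient="index", columns=["n3", "n4", "n5", "N"]
    ).rename_axis("species")


def local_mean_abundance(counts) -> float:
    """Class-midpoint mean density over the fields of presence.

    ``counts`` is an :class:`AbundanceClassCounts` or anything with
    ``n3, n4, n5, N`` attributes/keys.  Undefined (raises) when N = 0:
    a species never observed has no abundance, not abundance zero.
    """
    if isinstance(counts, dict):
        n3, n4, n5, N = counts["n3"], counts["n4"], counts["n5"], counts["N"]
    else:
        n3, n4, n5, N = counts.n3, counts.n4, counts.n5, counts.N
    if N < 1:
        raise InsufficientDataError("abundance undefined for N = 0 occurrences")
    return (11.5 * n3 + 35.5 * n4 + 75.5 * n5 + 1.5 * (N - n3 - n4 - n5)) / N


def local_mean_abundance_table(table: pd.DataFrame, period=None, crop=None,
                               plot="control") -> pd.Series:
    """Per-species A over a survey selection."""
    cc = class_counts(table, period=period, crop=crop, plot=plot)
    return pd.Series(
        {sp: local_mean_abundance(row) for sp, row in cc.iterrows()},
        name="A",
    ).rename_axis("species")


def fidelity(table: pd.DataFrame, species: str, focal_crop: str,
             period=None, plot="control") -> float:
    """Percentage of a species' estimated individuals found in the focal crop.

    Individuals are estimated from class midpoints (the only density
    estimate class data afford), summed over fields of presence in every
    crop of the table.  100 means a strict specialist of the focal crop.
    """
    scores = field_level_scores_all_crops(table, period=period, plot=plot)
    scores = scores[scores["species"] == species]
    if scores.empty:
        raise InsufficientDataError(f"species {species!r} absent from the table")
    mids = scores["score"].map(CLASS_MIDPOINTS)
    total = mids.sum()
    focal = mids[scores["crop"] == focal_crop].sum()
    return 100.0 * focal / total


def fidelity_table(table: pd.DataFrame, focal_crop: str, period=None,
                   plot="control") -> pd.Series:
    """Fidelity to the focal crop for every species in the table."""
    scores = field_level_scores_all_crops(table, period=period, plot=plot)
    scores = scores.assign(mid=scores["score"].map(CLASS_MIDPOINTS))
    total = scores.groupby("species")["mid"].sum()
    focal = (
        scores[scores["crop"] == focal_crop].groupby("species")["mid"].sum()
    ).reindex(total.index, fill_value=0.0)
    return (100.0 * focal / total).rename("fidelity")


def field_level_scores_all_crops(table: pd.DataFrame, period=None,
                                 plot="control") -> pd.DataFrame:
    """One max score per (field, species) keeping the crop column."""
    sel = table
    if period is not None:
        sel = sel[sel["period"] == period]
    if plot is not None:
        sel = sel[sel["plot"] == plot]
    if sel.empty:
        raise InsufficientDataError("no survey rows match the selection")
    sel = sel.assign(_rank=sel["score"].map(_CLASS_ORDER))
    idx = sel.groupby(["field_id", "species"])["_rank"].idxmax()
    return sel.loc[
        idx, ["field_id", "region", "crop", "species", "score"]
    ].reset_index(drop=True)


def species_summary(table: pd.DataFrame, period, crop, plot="control",
                    fidelity_period=None) -> pd.DataFrame:
    """F, A, fidelity and class counts per species for one period and crop.

    Fidelity is computed over all crops present in the table (it is 100
    everywhere when the table holds a single crop).
    """
    freq = regional_frequency(table, period=period, crop=crop, plot=plot)
    cc = class_counts(table, period=period, crop=crop, plot=plot)
    ab = local_mean_abundance_table(table, period=period, crop=crop, plot=plot)
    fid = fidelity_table(
        table, focal_crop=crop,
        period=period if fidelity_period is None else fidelity_period,
        plot=plot,
    )
    out = pd.concat([freq, ab, fid], axis=1).join(cc)
    return out


def change_index(s_old: float, s_new: float) -> float:
    """Normalized change Ch = (S2 - S1)/(S2 + S1) in [-1, 1].

    Undefined (raises) when both values are zero; +1 marks a colonizer
    absent in the first period, -1 a local extinction.
    """
    if s_old < 0 or s_new < 0:
        raise ValueError("metric values must be nonnegative")
    denom = s_old + s_new
    if denom == 0:
        raise InsufficientDataError("change undefined when both values are 0")
    return (s_new - s_old) / denom


def change_index_table(old: pd.Series, new: pd.Series) -> pd.Series:
    """Vectorized change index over the species present in both series."""
    common = old.index.intersection(new.index)
    o = old.loc[common].astype(float)
    n = new.loc[common].astype(float)
    denom = o + n
    keep = denom > 0
    return ((n - o) / denom)[keep].rename("ch")
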