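"""Nonparametric contrasts of PGLS residuals across species groupings.

Species whose local abundance sits above the frequency-abundance
regression line are "more abundant than expected"; comparing those
residuals across taxonomic groups (Dicots vs Pooideae vs Panicoideae),
origin classes (native / archaeophyte / neophyte) and herbicide-resistance
status asks which kinds of weeds beat the relationship.  Rank-based tests
are used because residual distributions need not be normal within groups:

* Kruskal-Wallis H with midrank tie correction, chi-square reference;
* Dunn pairwise z tests on the pooled midranks (two-sided, optional
  Bonferroni/Holm adjustment);
* a compact letter display summarizing the pairwise significance graph.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _pooled_ranks(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = {g: int((groups == g).sum()) for g in labels}
    empty = [g for g, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    ranks = stats.rankdata(values)  # midranks
    # tie correction sum over tied sets: sum (t^3 - t)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    return values, groups, labels, counts, ranks, tie_sum


def kruskal_wallis(values, groups):
    """Kruskal-Wallis rank test: returns (H, df, p).

    H uses midranks with the standard tie correction and is referred to a
    chi-square with (groups - 1) degrees of freedom.  Identical group
    distributions give H = 0, p = 1.
    """
    values, groups, labels, counts, ranks, tie_sum = _pooled_ranks(
        values, groups
    )
    N = len(values)
    mean_rank = (N + 1) / 2.0
    H = 0.0
    for g in labels:
        rbar = ranks[groups == g].mean()
        H += counts[g] * (rbar - mean_rank) ** 2
    H *= 12.0 / (N * (N + 1))
    correction = 1.0 - tie_sum / (N**3 - N)
    if correction <= 0:  # all values identical
        return 0.0, len(labels) - 1, 1.0
    H /= correction
    df = len(labels) - 1
    p = float(stats.chi2.sf(H, df)) if H > 0 else 1.0
    return float(H), df, p


def dunn_posthoc(values, groups, adjust: str = "none") -> pd.DataFrame:
    """Dunn pairwise z tests on pooled midranks, with tie correction.

    Returns a DataFrame with one row per unordered group pair:
    ``group_i, group_j, z, p_raw, p`` (p adjusted per ``adjust`` in
    {"none", "bonferroni", "holm"}).
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    values, groups, labels, counts, ranks, tie_sum = _pooled_ranks(
        values, groups
    )
    N = len(values)
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    rows = []
    for gi, gj in itertools.combinations(labels, 2):
        ri = ranks[groups == gi].mean()
        rj = ranks[groups == gj].mean()
        se = np.sqrt(var_base * (1.0 / counts[gi] + 1.0 / counts[gj]))
        z = 0.0 if se == 0 else (ri - rj) / se
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append({"group_i": gi, "group_j": gj, "z": z, "p_raw": p_raw})
    out = pd.DataFrame(rows)
    if adjust == "none":
        out["p"] = out["p_raw"]
    else:
        out["p"] = multipletests(out["p_raw"], method=adjust)[1]
    return out


def letter_display(pairwise: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display from a Dunn pairwise table.

    Groups that are *not* significantly different share at least one
    letter; significantly different groups share none.  Letters are the
    maximal cliques of the non-significance graph, greedily pruned of
    redundant cliques and ordered deterministically by group name.
    """
    labels = sorted(
        set(pairwise["group_i"]).union(pairwise["group_j"])
    )
    G = nx.Graph()
    G.add_nodes_from(labels)
    for _, row in pairwise.iterrows():
        if row["p"] >= alpha:
            G.add_edge(row["group_i"], row["group_j"])
    kept = sorted(tuple(sorted(c)) for c in nx.find_cliques(G))
    # drop cliques fully covered (edges and vertices) by the remaining ones,
    # one at a time so coverage is never lost
    changed = True
    while changed:
        changed = False
        for c in list(kept):
            others = [o for o in kept if o != c]
            covered_e = {e for o in others for e in itertools.combinations(o, 2)}
            covered_v = {v for o in others for v in o}
            edges = set(itertools.combinations(c, 2))
            if not (edges - covered_e) and not (set(c) - covered_v):
                kept.remove(c)
                changed = True
                break
    kept.sort(key=lambda c: (min(c), c))
    letters = {g: "" for g in labels}
    for i, c in enumerate(kept):
        letter = chr(ord("a") + i)
        for g in c:
            letters[g] += letter
    return letters


def residual_group_tests(residuals: pd.Series, annotations: pd.DataFrame,
                         groupings=("group_taxo", "origin", "resistant_pops"),
                         adjust: str = "none", alpha: float = 0.05) -> dict:
    """Kruskal-Wallis + Dunn + letters for each annotation grouping.

    Returns a dict grouping -> {"H", "df", "p", "pairwise", "letters"}.
    """
    out = {}
    ann = annotations.loc[residuals.index]
    for col in groupings:
        groups = ann[col].astype(str).to_numpy()
        H, df, p = kruskal_wallis(residuals.to_numpy(), groups)
        pairwise = dunn_posthoc(residuals.to_numpy(), groups, adjust=adjust)
        out[col] = {
            "H": H,
            "df": df,
            "p": p,
            "pairwise": pairwise,
            "letters": letter_display(pairwise, alpha=alpha),
        }
    return out
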