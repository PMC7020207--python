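"""Hill-Smith ordination of a mixed quantitative/qualitative trait table.

A PCA-like weighted eigendecomposition that accepts both numeric traits
and categorical traits in one analysis.  Quantitative columns are z-scored
(population variance, uniform row weights); each level k of a qualitative
trait becomes the centered indicator column (I_k - p_k) / sqrt(p_k), where
p_k is the level frequency.  Under this coding a quantitative trait
contributes inertia 1 and a qualitative trait with K observed levels
contributes K - 1, so the total inertia is comparable across trait types
and the analysis reduces exactly to correlation-matrix PCA when every
trait is quantitative.

Axis signs are arbitrary in any eigenanalysis; here each axis is oriented
so that its largest-|loading| column loads positively, which makes runs
reproducible but means published axis signs are matched only up to
per-axis reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError


@dataclass
class MixedDesign:
    """Centered/scaled design built from a mixed trait table.

    ``Z`` holds one column per quantitative trait and per observed
    qualitative level; ``col_trait`` maps each design column back to its
    source trait; ``row_weights`` are uniform (1/n) unless supplied.
    """

    Z: pd.DataFrame
    col_trait: dict
    row_weights: np.ndarray
    quantitative: list = field(default_factory=list)
    qualitative: list = field(default_factory=list)


def split_trait_types(traits: pd.DataFrame, quantitative=None,
                      qualitative=None):
    """Infer quantitative vs qualitative columns unless declared."""
    if quantitative is None and qualitative is None:
        quantitative = [
            c for c in traits.columns
            if pd.api.types.is_numeric_dtype(traits[c])
        ]
        qualitative = [c for c in traits.columns if c not in quantitative]
    elif quantitative is None:
        quantitative = [c for c in traits.columns if c not in qualitative]
    elif qualitative is None:
        qualitative = [c for c in traits.columns if c not in quantitative]
    return list(quantitative), list(qualitative)


def build_mixed_design(traits: pd.DataFrame, quantitative=None,
                       qualitative=None, row_weights=None) -> MixedDesign:
    """Build the Hill-Smith design from a species x trait table.

    Raises on constant quantitative traits (their z-score is undefined);
    declared-but-unobserved qualitative levels simply produce no column.
    """
    if len(traits) < 2:
        raise InsufficientDataError("need at least 2 species for an ordination")
    quant, qual = split_trait_types(traits, quantitative, qualitative)
    n = len(traits)
    if row_weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(row_weights, dtype=float)
        w = w / w.sum()
    cols = {}
    col_trait = {}
    for c in quant:
        x = traits[c].to_numpy(dtype=float)
        mu = float(w @ x)
        sd = float(np.sqrt(w @ (x - mu) ** 2))
        if sd == 0:
            raise ValueError(f"quantitative trait {c!r} is constant")
        cols[c] = (x - mu) / sd
        col_trait[c] = c
    for c in qual:
        levels = sorted(map(str, traits[c].astype(str).unique()))
        vals = traits[c].astype(str).to_numpy()
        for lev in levels:
            ind = (vals == lev).astype(float)
            p = float(w @ ind)
            name = f"{c}::{lev}"
            cols[name] = (ind - p) / np.sqrt(p)
            col_trait[name] = c
    Z = pd.DataFrame(cols, index=traits.index)
    return MixedDesign(Z=Z, col_trait=col_trait, row_weights=w,
                       quantitative=quant, qualitative=qual)


class OrdinationResults:
    """Eigenvalues, species scores, column loadings and contributions.

    Attributes
    ----------
    eigenvalues : pandas.Series
        Nonincreasing positive eigenvalues of the weighted cross-product.
    pct_inertia : pandas.Series
        Percentage of total inertia per retained axis (percentages of all
        axes sum to 100).
    row_scores : DataFrame (species x axes)
        Principal coordinates; their weighted variance equals the
        eigenvalue of the axis.
    col_scores : DataFrame (design column x axes)
        Loadings scaled by sqrt(eigenvalue).
    """

    def __init__(self, design: MixedDesign, n_axes: int):
        Z = design.Z.to_numpy(dtype=float)
        w = design.row_weights
        C = (Z * w[:, None]).T @ Z
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
        tol = max(C.shape[0], 1) * np.finfo(float).eps * max(evals.max(), 1.0)
        rank = int((evals > tol).sum())
        self.total_inertia = float(np.trace(C))
        self.n_axes = min(n_axes, rank)
        if n_axes > rank:
            import warnings

            warnings.warn(
                f"requested {n_axes} axes but rank is {rank}; truncated",
                stacklevel=2,
            )
        evals = evals[: self.n_axes]
        U = evecs[:, : self.n_axes]
        # orient: largest-|loading| column of each axis loads positively
        for k in range(self.n_axes):
            j = int(np.argmax(np.abs(U[:, k])))
            if U[j, k] < 0:
                U[:, k] = -U[:, k]
        axes = [f"Axis{k + 1}" for k in range(self.n_axes)]
        self.eigenvalues = pd.Series(evals, index=axes, name="eigenvalue")
        self.pct_inertia = pd.Series(
            100.0 * evals / self.total_inertia, index=axes, name="pct_inertia"
        )
        self._U = pd.DataFrame(U, index=design.Z.columns, columns=axes)
        self.col_scores = self._U * np.sqrt(evals)
        self.row_scores = pd.DataFrame(
            Z @ U, index=design.Z.index, columns=axes
        )
        self.design = design

    def contributions(self) -> pd.DataFrame:
        """Signed relative contribution (%) of each design column per axis.

        The magnitude is the column's share of the axis eigenvalue (squared
        loading); the sign is the loading direction.  Absolute values sum
        to 100 within each axis.
        """
        U = self._U
        return 100.0 * np.sign(U) * U**2

    def trait_contributions(self) -> pd.DataFrame:
        """Contributions aggregated per source trait (signed sums of levels)."""
        contrib = self.contributions()
        groups = pd.Series(self.design.col_trait)
        return contrib.groupby(groups.reindex(contrib.index)).sum()

    def axes_as_predictors(self, which_axes=None) -> pd.DataFrame:
        """Species x axis score table, keyed for joining with responses."""
        if which_axes is None:
            return self.row_scores.copy()
        cols = []
        for a in which_axes:
            name = a if isinstance(a, str) else f"Axis{a}"
            if name not in self.row_scores.columns:
                raise ValueError(f"unknown axis {a!r}")
            cols.append(name)
        return self.row_scores[cols].copy()

    def summary(self) -> str:
        df = pd.DataFrame({
            "eigenvalue": self.eigenvalues,
            "pct_inertia": self.pct_inertia,
            "cum_pct": self.pct_inertia.cumsum(),
        })
        return (
            "Hill-Smith ordination\n"
            f"total inertia: {self.total_inertia:.4f}\n"
            + df.to_string(float_format=lambda v: f"{v:8.3f}")
        )


class HillSmith:
    """Hill-Smith ordination model over a mixed species x trait table."""

    def __init__(self, traits: pd.DataFrame, quantitative=None,
                 qualitative=None, row_weights=None):
        self.design = build_mixed_design(
            traits, quantitative=quantitative, qualitative=qualitative,
            row_weights=row_weights,
        )

    def fit(self, n_axes: int = 6) -> OrdinationResults:
        return OrdinationResults(self.design, n_axes)


def hill_smith(design: MixedDesign, n_axes: int = 6) -> OrdinationResults:
    """Functional entry point over a prebuilt design."""
    return OrdinationResults(design, n_axes)
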