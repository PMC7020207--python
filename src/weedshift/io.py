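"""Readers and writers for the survey, trait, annotation and tree inputs.

All tabular data are plain UTF-8, comma-separated CSV with a mandatory
header row and "." as decimal mark.  Tables are carried in memory as
:class:`pandas.DataFrame` objects with fixed column names; trees as
:class:`dendropy.Tree`.  Every reader validates its invariants and reports
the offending rows instead of silently dropping them.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

#: canonical survey columns, long format: one row per observed species score
SURVEY_COLUMNS = [
    "field_id",
    "year",
    "period",
    "region",
    "crop",
    "plot",
    "species",
    "score",
]

#: the six-class cover-abundance alphabet ("+" = one individual per plot)
SCORE_ALPHABET = ("+", "1", "2", "3", "4", "5")

PERIODS = ("P1970s", "P2000s")
PLOTS = ("control", "treated")

ANNOTATION_COLUMNS = ["species", "group_taxo", "origin", "resistant_pops"]
TAXO_GROUPS = ("Dicot", "Pooideae", "Panicoideae")
ORIGINS = ("native", "archaeophyte", "neophyte")


def _normalize_score(value) -> str:
    """Map raw score spellings to the canonical alphabet.

    The presence class may be written "+" or "0.5" (convenient in numeric
    columns); integer classes may carry a trailing ".0" from spreadsheet
    round-trips.
    """
    s = str(value).strip()
    if s in ("+", "0.5"):
        return "+"
    if s.endswith(".0"):
        s = s[:-2]
    return s


def read_survey(path, schema: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-format survey table.

    Parameters
    ----------
    path : str or Path
        CSV file with one row per (field, year, plot, species) observation.
    schema : dict, optional
        Mapping from canonical column names (``SURVEY_COLUMNS``) to the
        column names actually used in the file.

    Returns
    -------
    pandas.DataFrame
        Validated table with canonical columns, scores normalized to
        {"+", "1".."5"}.

    Raises
    ------
    SchemaError
        If a declared column is absent.
    ValidationError
        If scores fall outside the six-class alphabet, if
        (field_id, year, plot, species) rows are duplicated, or if a field
        maps to more than one region or period.  Offending 1-based data row
        numbers are listed in the message and on ``exc.rows``.
    """
    df = pd.read_csv(path, dtype=str)
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    df = df.rename(columns=rename)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey file {path} is missing columns: {missing}")
    df = df[SURVEY_COLUMNS].copy()
    df["score"] = df["score"].map(_normalize_score)
    df["year"] = df["year"].astype(int)
    return validate_survey(df)


def validate_survey(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory survey table (see :func:`read_survey`)."""
    bad = ~df["score"].isin(SCORE_ALPHABET)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        offending = sorted(set(df.loc[bad, "score"]))
        raise ValidationError(
            f"unknown score symbol(s) {offending} in data rows {rows}", rows
        )
    bad = ~df["period"].isin(PERIODS)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        raise ValidationError(f"unknown period in data rows {rows}", rows)
    bad = ~df["plot"].isin(PLOTS)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        raise ValidationError(f"unknown plot type in data rows {rows}", rows)

    key = ["field_id", "year", "plot", "species"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = (np.flatnonzero(dup.to_numpy()) + 1).tolist()
        raise ValidationError(
            f"duplicate (field_id, year, plot, species) rows: {rows}", rows
        )
    for col in ("region", "period"):
        n_per_field = df.groupby("field_id")[col].nunique()
        multi = n_per_field[n_per_field > 1]
        if len(multi):
            raise ValidationError(
                f"field(s) mapped to more than one {col}: "
                f"{sorted(multi.index.tolist())}"
            )
    return df.reset_index(drop=True)


def read_traits(path, quantitative=None, qualitative=None) -> pd.DataFrame:
    """Read a species-by-trait table mixing quantitative and qualitative traits.

    The trait schema must be total: after validation no species has a
    missing value for any declared trait.  Columns not named in either list
    are inferred quantitative if they parse as numbers, qualitative
    otherwise.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise SchemaError(f"trait file {path} has no 'species' column")
    df = df.set_index("species")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].tolist())
        raise ValidationError(f"duplicate species in trait table: {dups}")
    if quantitative:
        missing = [c for c in quantitative if c not in df.columns]
        if missing:
            raise SchemaError(f"declared quantitative traits absent: {missing}")
        df[quantitative] = df[quantitative].astype(float)
    if qualitative:
        missing = [c for c in qualitative if c not in df.columns]
        if missing:
            raise SchemaError(f"declared qualitative traits absent: {missing}")
    na = df.isna()
    if na.to_numpy().any():
        cells = [
            (sp, col) for sp, row in na.iterrows() for col, v in row.items() if v
        ]
        raise ValidationError(f"missing trait values: {cells[:20]}")
    return df


def read_annotations(path) -> pd.DataFrame:
    """Read the species annotation table (taxonomy group, origin, resistance)."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation file {path} is missing columns: {missing}")
    df = df[ANNOTATION_COLUMNS].set_index("species")
    bad = ~df["group_taxo"].isin(TAXO_GROUPS)
    if bad.any():
        raise ValidationError(
            f"unknown group_taxo for species {sorted(df.index[bad])}"
        )
    bad = ~df["origin"].isin(ORIGINS)
    if bad.any():
        raise ValidationError(f"unknown origin for species {sorted(df.index[bad])}")
    df["resistant_pops"] = df["resistant_pops"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes")
    )
    return df


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick phylogeny with branch lengths.

    Raises
    ------
    FormatError
        Unparseable Newick, or any non-root edge missing a branch length.
    ValidationError
        Duplicate or missing tip labels, or negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        if "uplicate" in str(exc):
            raise ValidationError(
                f"duplicate tip labels in {path}: {exc}"
            ) from exc
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Check tip-label uniqueness and branch-length sanity on a tree."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate tip labels: {dups}")
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise ValidationError("tree has unlabeled tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("tree has an edge with no branch length")
        if not np.isfinite(edge.length) or edge.length < 0:
            raise ValidationError(f"invalid branch length {edge.length}")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    """Write a tree as Newick (branch lengths kept verbatim)."""
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def check_species_consistency(survey, traits, tree, annotations,
                              species=None) -> list:
    """Cross-file check that every analyzed species is present everywhere.

    Species tokens are case-sensitive exact keys; silent name mismatches in
    trait–tree joins are the dominant failure mode, so this runs before any
    analysis.  Returns the sorted species list on success.
    """
    if species is None:
        species = sorted(set(survey["species"]))
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    problems = []
    for sp in species:
        if sp not in traits.index:
            problems.append(f"{sp}: missing from trait table")
        if sp not in tips:
            problems.append(f"{sp}: missing from tree")
        if sp not in annotations.index:
            problems.append(f"{sp}: missing from annotation table")
    if problems:
        raise ValidationError(
            "species inconsistency across inputs:\n  " + "\n  ".join(problems)
        )
    return list(species)


def config_hash(config: dict) -> str:
    """Deterministic short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(tables: dict, out_dir, seed=None, config=None) -> dict:
    """Write one CSV per result table plus a JSON run manifest.

    Parameters
    ----------
    tables : dict
        Mapping table name -> DataFrame (status table, PGLS coefficient
        tables, contribution table, ...).  May be empty.
    out_dir : path
        Created if absent.
    seed, config
        Recorded in the manifest for provenance.

    Returns
    -------
    dict
        The manifest (also written to ``manifest.json``).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    import scipy

    from . import __version__

    manifest = {
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config or {}),
        "tables": {},
        "versions": {
            "weedshift": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, float_format="%.10g")
        manifest["tables"][name] = {"file": fname, "rows": int(len(table))}
    if not os.access(out_dir, os.W_OK):
        raise IOError(f"output directory {out_dir} is not writable")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
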