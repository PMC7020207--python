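"""End-to-end diachronic weed-survey analysis under one seeded config.

Stages, in order: ingest or simulate the four inputs -> cross-file species
check -> per-species commonness summary (F, A, fidelity) -> stratified-
bootstrap status calls against the 1970s points -> within-2000s Spearman
trends -> normalized change indices -> per-trait PGLS (frequency,
abundance, specificity) -> Hill-Smith ordination and axis PGLS ->
frequency-abundance PGLS with residual group tests -> change regression ->
CSV report with a provenance manifest.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import bootstrap as bs
from . import commonness as cm
from . import io as wio
from .errors import InsufficientDataError
from .group_tests import residual_group_tests
from .ordination import HillSmith
from .pgls import PGLS, lrt_lambda, vcv_from_tree
from .synthetic import (
    SurveyGenConfig,
    gen_annotations,
    gen_survey,
    gen_traits,
    gen_tree,
)

logger = logging.getLogger("weedshift")

#: traits log-transformed before entering the models (heavy right skew)
LOG_TRAITS = ("plant_height", "seed_weight", "fecundity", "seed_longevity")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; ``seed`` is mandatory."""

    seed: int
    survey_path: str | None = None
    traits_path: str | None = None
    tree_path: str | None = None
    annotations_path: str | None = None
    simulate: bool = True
    sim_overrides: dict = dc_field(default_factory=dict)
    focal_crop: str = "maize"
    strata_p1: dict | None = None  # derived from the P1970s survey if None
    B: int = 1000
    trend_B: int = 200
    level: float = 0.95
    detection_threshold: float = 0.023  # 1970s recording floor (frequency)
    min_occurrences: int = 5  # species-inclusion rule for the trait models
    ml_lambda: bool = True
    ml_delta: bool = False
    n_axes: int = 6

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["strata_p1"] = dict(self.strata_p1) if self.strata_p1 else None
        return d


@dataclass
class RunReport:
    """All result tables of one pipeline run plus the provenance manifest."""

    summary: pd.DataFrame
    status_frequency: pd.DataFrame
    status_abundance: pd.DataFrame
    trends_frequency: pd.DataFrame
    trends_abundance: pd.DataFrame
    changes: pd.DataFrame
    pgls_traits: pd.DataFrame
    contributions: pd.DataFrame
    trait_contributions: pd.DataFrame
    pgls_axes: pd.DataFrame
    freq_abun_fit: object
    group_tests: dict
    change_fit: object | None
    manifest: dict

    def tables(self) -> dict:
        out = {
            "summary": self.summary,
            "status_frequency": self.status_frequency,
            "status_abundance": self.status_abundance,
            "trends_frequency": self.trends_frequency,
            "trends_abundance": self.trends_abundance,
            "changes": self.changes,
            "pgls_traits": self.pgls_traits,
            "contributions": self.contributions,
            "trait_contributions": self.trait_contributions,
            "pgls_axes": self.pgls_axes,
            "group_tests": group_tests_table(self.group_tests),
        }
        return out

    def write(self, out_dir):
        return wio.write_report(
            self.tables(), out_dir, seed=self.manifest.get("seed"),
            config=self.manifest.get("config"),
        )


def group_tests_table(results: dict) -> pd.DataFrame:
    rows = []
    for grouping, res in results.items():
        letters = ";".join(f"{g}={l}" for g, l in sorted(res["letters"].items()))
        rows.append({
            "grouping": grouping, "H": res["H"], "df": res["df"],
            "p": res["p"], "letters": letters,
        })
    return pd.DataFrame(rows).set_index("grouping")


def simulate_inputs(seed: int, sim_overrides: dict | None = None,
                    min_occurrences: int = 5) -> dict:
    """Generate a coherent survey + traits + tree + annotations quadruple.

    The tree, traits and annotations cover the species passing the
    inclusion rule (at least ``min_occurrences`` occurrences in the 2000s
    control plots of the focal crop), mirroring how an analysis pool is
    assembled from a survey.
    """
    overrides = dict(sim_overrides or {})
    overrides.setdefault("seed", seed)
    config = SurveyGenConfig(**overrides)
    survey = gen_survey(config)
    scores = cm.field_level_scores(
        survey, period="P2000s", crop=config.focal_crop, plot="control"
    )
    occ = scores.groupby("species")["field_id"].nunique()
    included = sorted(occ[occ >= min_occurrences].index)
    if len(included) < 3:
        raise InsufficientDataError(
            f"only {len(included)} species pass the inclusion rule"
        )
    tree = gen_tree(len(included), seed=seed, taxon_labels=included)
    traits = gen_traits(len(included), seed=seed, species=included)
    annotations = gen_annotations(included, seed=seed)
    return {
        "survey": survey, "traits": traits, "tree": tree,
        "annotations": annotations, "species": included, "config": config,
    }


def load_inputs(config: RunConfig) -> dict:
    survey = wio.read_survey(config.survey_path)
    traits = wio.read_traits(config.traits_path)
    tree = wio.read_tree(config.tree_path)
    annotations = wio.read_annotations(config.annotations_path)
    scores = cm.field_level_scores(
        survey, period="P2000s", crop=config.focal_crop, plot="control"
    )
    occ = scores.groupby("species")["field_id"].nunique()
    included = sorted(occ[occ >= config.min_occurrences].index)
    return {
        "survey": survey, "traits": traits, "tree": tree,
        "annotations": annotations, "species": included,
    }


def trait_design(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-trait model matrices: log-transform skewed quantitative traits,
    dummy-code qualitative traits against an alphabetical baseline."""
    out = {}
    for col in traits.columns:
        if pd.api.types.is_numeric_dtype(traits[col]):
            x = traits[col].astype(float)
            if col in LOG_TRAITS:
                x = np.log(x)
            out[col] = x.to_frame(col)
        else:
            dummies = pd.get_dummies(traits[col].astype(str), prefix=col,
                                     prefix_sep="=").astype(float)
            out[col] = dummies.iloc[:, 1:]  # first level is the baseline
    return out


def per_trait_pgls(responses: pd.DataFrame, traits: pd.DataFrame, V,
                   ml_lambda=True, ml_delta=False) -> pd.DataFrame:
    """One PGLS per (response, trait); rows = non-intercept coefficients."""
    designs = trait_design(traits)
    rows = []
    for resp in responses.columns:
        y = responses[resp].dropna()
        for trait, X in designs.items():
            model = PGLS(y, X.loc[y.index],
                         V=V.loc[y.index, y.index])
            fit = model.fit(lam="ml" if ml_lambda else 1.0,
                            delta="ml" if ml_delta else 1.0)
            for name in fit.params.index:
                if name == "Intercept":
                    continue
                rows.append({
                    "response": resp, "trait": trait, "term": name,
                    "estimate": fit.params[name], "std_error": fit.bse[name],
                    "t_value": fit.tvalues[name], "p_value": fit.pvalues[name],
                    "lambda": fit.lambda_hat, "adj_r2": fit.rsquared_adj,
                })
    return pd.DataFrame(rows)


def frequency_abundance_regression(summary: pd.DataFrame, tree=None, V=None,
                                   ml_lambda=True):
    """PGLS of log regional frequency on log local abundance (+ LRT vs
    lambda = 0); residuals feed the group contrasts."""
    data = summary[["F", "A"]].dropna()
    data = data[(data["F"] > 0) & (data["A"] > 0)]
    if len(data) < 3:
        raise InsufficientDataError("need >= 3 species with F and A")
    if V is None:
        V = vcv_from_tree(tree)
    V = V.loc[data.index, data.index]
    y = np.log(data["F"])
    X = np.log(data[["A"]]).rename(columns={"A": "log_A"})
    model = PGLS(y.rename("log_F"), X, V=V)
    fit = model.fit(lam="ml" if ml_lambda else 1.0)
    if ml_lambda:
        stat, p = lrt_lambda(fit, model.fit(lam=0.0))
    else:  # LRT against lambda = 0 requires the ML fit
        stat, p = float("nan"), float("nan")
    return fit, {"lrt_stat": stat, "lrt_p": p}


def change_regression(changes: pd.DataFrame, tree=None, V=None,
                      ml_lambda=True):
    """PGLS of frequency change on abundance change (species with both
    periods observed; undeterminable-status species are excluded upstream
    because their change index is undefined)."""
    data = changes[["ch_frequency", "ch_abundance"]].dropna()
    if len(data) < 3:
        raise InsufficientDataError(
            f"only {len(data)} species have both change indices"
        )
    if V is None:
        V = vcv_from_tree(tree)
    V = V.loc[data.index, data.index]
    model = PGLS(data["ch_frequency"], data[["ch_abundance"]], V=V)
    return model.fit(lam="ml" if ml_lambda else 1.0)


def run(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the full analysis; see the module docstring for the stages."""
    t0 = time.time()
    stage = "ingest"
    try:
        if config.simulate:
            inputs = simulate_inputs(config.seed, config.sim_overrides,
                                     config.min_occurrences)
        else:
            inputs = load_inputs(config)
        survey = inputs["survey"]
        species = inputs["species"]
        traits, tree = inputs["traits"], inputs["tree"]
        annotations = inputs["annotations"]

        stage = "pre-flight species check"
        wio.check_species_consistency(survey, traits, tree, annotations,
                                      species=species)
        V = vcv_from_tree(tree, tip_order=species)

        stage = "strata"
        p1 = survey[survey["period"] == "P1970s"]
        if config.strata_p1 is not None:
            strata = dict(config.strata_p1)
        else:
            strata = (
                p1[p1["plot"] == "control"]
                .groupby("region")["field_id"].nunique().to_dict()
            )
        logger.info("strata: %s (total %d)", strata, sum(strata.values()))

        stage = "commonness summary"
        summary = cm.species_summary(survey, period="P2000s",
                                     crop=config.focal_crop)

        stage = "bootstrap status"
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 10)))
        f1 = cm.regional_frequency(survey, period="P1970s",
                                   crop=config.focal_crop)
        a1 = cm.local_mean_abundance_table(survey, period="P1970s",
                                           crop=config.focal_crop)
        status_f = bs.status_table(
            survey, f1, strata, "frequency", B=config.B, level=config.level,
            detection_threshold=config.detection_threshold, rng=rng,
            crop=config.focal_crop,
        )
        status_a = bs.status_table(
            survey, a1, strata, "abundance", B=config.B, level=config.level,
            detection_threshold=0.0, rng=rng, crop=config.focal_crop,
        )
        # an abundance point exists only for species recorded in the 1970s;
        # inherit "N"/"?" from the frequency call when the point is absent
        absent = status_a["point_P1"].isna()
        status_a.loc[absent, "status"] = status_f["status"].reindex(
            status_a.index
        )[absent].map(lambda s: s if s in ("N", "?") else "?")

        stage = "yearly trends"
        year_strata = (
            survey[(survey["period"] == "P2000s")
                   & (survey["crop"] == config.focal_crop)
                   & (survey["plot"] == "control")]
            .groupby(["year", "region"])["field_id"].nunique()
            .groupby("region").min().to_dict()
        )
        trends = {}
        for metric in ("frequency", "abundance"):
            per_year = bs.per_year_metric(
                survey, metric, year_strata, B=config.trend_B, rng=rng,
                crop=config.focal_crop,
            )
            trends[metric] = bs.trend_table(per_year)

        stage = "change indices"
        f2_eq = status_f["mean"] * 1.0  # effort-equalized 2000s frequency
        a2_eq = status_a["mean"]
        recorded = f1[f1 >= config.detection_threshold]
        ch_f = cm.change_index_table(recorded, f2_eq)
        ch_a = cm.change_index_table(a1.reindex(recorded.index).dropna(), a2_eq)
        changes = pd.DataFrame({"ch_frequency": ch_f, "ch_abundance": ch_a})

        stage = "per-trait PGLS"
        resp = pd.DataFrame({
            "log_frequency": np.log(summary.loc[species, "F"]),
            "log_abundance": np.log(summary.loc[species, "A"]),
            "specificity": summary.loc[species, "fidelity"],
        })
        pgls_traits = per_trait_pgls(resp, traits.loc[species], V,
                                     ml_lambda=config.ml_lambda,
                                     ml_delta=config.ml_delta)

        stage = "ordination"
        ord_res = HillSmith(traits.loc[species]).fit(n_axes=config.n_axes)
        axes = ord_res.axes_as_predictors()

        stage = "axis PGLS"
        rows = []
        for r in resp.columns:
            model = PGLS(resp[r].dropna(), axes.loc[resp[r].dropna().index],
                         V=V.loc[resp[r].dropna().index,
                                 resp[r].dropna().index])
            fit = model.fit(lam="ml" if config.ml_lambda else 1.0)
            for name in fit.params.index:
                if name == "Intercept":
                    continue
                rows.append({
                    "response": r, "axis": name,
                    "estimate": fit.params[name], "std_error": fit.bse[name],
                    "t_value": fit.tvalues[name], "p_value": fit.pvalues[name],
                    "lambda": fit.lambda_hat,
                })
        pgls_axes = pd.DataFrame(rows)

        stage = "frequency-abundance regression"
        fa_fit, fa_lrt = frequency_abundance_regression(
            summary.loc[species], V=V, ml_lambda=config.ml_lambda
        )

        stage = "residual group tests"
        gt = residual_group_tests(fa_fit.resid, annotations)

        stage = "change regression"
        try:
            ch_fit = change_regression(
                changes.loc[changes.index.intersection(species)],
                V=V.loc[changes.index.intersection(species),
                        changes.index.intersection(species)],
                ml_lambda=config.ml_lambda,
            )
        except InsufficientDataError:
            ch_fit = None

        stage = "report"
        manifest = {
            "seed": config.seed,
            "config": config.as_dict(),
            "strata": strata,
            "n_species_included": len(species),
            "fa_regression": {
                "slope": float(fa_fit.params.iloc[1]),
                "lambda": fa_fit.lambda_hat,
                "adj_r2": fa_fit.rsquared_adj,
                "F": fa_fit.fvalue,
                **fa_lrt,
            },
            "runtime_s": None,
            "low_replicate": config.B < 200,
        }
        report = RunReport(
            summary=summary,
            status_frequency=status_f,
            status_abundance=status_a,
            trends_frequency=trends["frequency"],
            trends_abundance=trends["abundance"],
            changes=changes,
            pgls_traits=pgls_traits,
            contributions=ord_res.contributions(),
            trait_contributions=ord_res.trait_contributions(),
            pgls_axes=pgls_axes,
            freq_abun_fit=fa_fit,
            group_tests=gt,
            change_fit=ch_fit,
            manifest=manifest,
        )
        manifest["runtime_s"] = round(time.time() - t0, 2)
        if out_dir is not None:
            report.write(out_dir)
        return report
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
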