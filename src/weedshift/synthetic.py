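"""Synthetic two-period weed surveys, trait tables and phylogenies.

The raw French maize monitoring data were never released, so every
downstream stage is exercised on generated data reproducing the structure
the analysis assumes:

* two survey periods with the historical regional strata (East 26,
  South-West 64, North-Parisian basin 41, West 26, South-East 17 fields in
  the 1970s; 484 fields spread proportionally in the 2000s);
* right-skewed occupancies (lognormal, truncated below 1) giving the
  few-common/many-rare shape of real weed floras;
* a positive interspecific coupling between occupancy and local density
  (log mean density = a + b log occupancy + noise), the classical
  abundance-occupancy relationship, with per-field densities discretized
  to the six-class cover scale ("+" = one individual per 2000 m^2 plot;
  1 = <1, 2 = 1-2, 3 = 3-20, 4 = 21-50, 5 = >50 individuals/m^2);
* Brownian trait evolution on a pure-birth tree with tunable Pagel lambda,
  for parameter-recovery tests of the comparative models.

These are stand-ins: no interspecific abundance model is asserted by the
source surveys, and the generator makes no claim about real spatial or
temporal autocorrelation (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import NumericalError
from .pgls import pagel_transform, vcv_from_tree
from .refdata import N_FIELDS_2000S, STRATA_1970S

#: herbicide-treated plot area (m^2); "+" means one individual in the plot
PLOT_AREA_M2 = 2000.0

YEARS_2000S = tuple(range(2002, 2009))
YEAR_1970S = 1974


def default_strata() -> dict:
    """Per-region (n_1970s, n_2000s) field counts.

    The 1970s sizes are the historical strata; the 484 fields of the 2000s
    are spread across regions by largest-remainder apportionment on the
    1970s shares.
    """
    total_p1 = sum(STRATA_1970S.values())
    quotas = {
        r: N_FIELDS_2000S * n / total_p1 for r, n in STRATA_1970S.items()
    }
    base = {r: int(np.floor(q)) for r, q in quotas.items()}
    shortfall = N_FIELDS_2000S - sum(base.values())
    order = sorted(quotas, key=lambda r: (-(quotas[r] - base[r]), r))
    for r in order[:shortfall]:
        base[r] += 1
    return {r: (STRATA_1970S[r], base[r]) for r in STRATA_1970S}


@dataclass
class SurveyGenConfig:
    """Configuration of the survey generator.

    Attributes
    ----------
    n_fields_per_region_per_period : dict
        region -> (n fields in P1970s, n fields in P2000s).
    n_species : int
        Size of the simulated species pool.
    occupancy_meanlog, occupancy_sdlog : float
        Lognormal occupancy probabilities, truncated to (0, occupancy_max];
        median exp(meanlog).
    coupling_intercept, coupling_slope : float
        log mean density = intercept + slope * log occupancy (+ noise);
        slope b > 0 produces the positive abundance-occupancy relationship,
        b = 0 decouples the two facets.
    density_noise_sd : float
        Interspecific lognormal scatter around the coupling line.
    within_field_sd : float
        Lognormal spread of per-field density around the species mean.
    period_effects : dict
        species -> multiplicative occupancy shift applied in the 2000s
        (e.g. 2.0 doubles the colonization probability).
    other_crops : dict
        crop -> number of extra 2000s fields, for fidelity/specificity;
        per-species crop affinities are drawn lognormally.
    """

    n_fields_per_region_per_period: dict = field(default_factory=default_strata)
    n_species: int = 120
    occupancy_meanlog: float = -3.0
    occupancy_sdlog: float = 1.3
    occupancy_max: float = 0.95
    coupling_intercept: float = 2.9
    coupling_slope: float = 0.7
    density_noise_sd: float = 0.5
    within_field_sd: float = 0.9
    period_effects: dict = field(default_factory=dict)
    other_crops: dict = field(default_factory=dict)
    focal_crop: str = "maize"
    include_treated: bool = True
    treated_occupancy_factor: float = 0.4
    seed: int = 0

    def __post_init__(self):
        for r, (n1, n2) in self.n_fields_per_region_per_period.items():
            if n1 <= 0 or n2 <= 0:
                raise ValueError(f"non-positive field count for region {r}")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if not np.isfinite(self.coupling_slope):
            raise ValueError("coupling slope must be finite")


@dataclass
class TraitEvolConfig:
    """Brownian trait-evolution settings for PGLS recovery tests."""

    n_tips: int = 95
    lambda_true: float = 1.0
    sigma2: float = 1.0
    beta_true: tuple = (0.0,)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def species_names(n: int) -> list:
    return [f"sp{i + 1:03d}" for i in range(n)]


def discretize_density(density: float, plot_area: float = PLOT_AREA_M2) -> str:
    """Map a density (individuals/m^2) to the six-class cover scale.

    A literal singleton in the plot scores "+"; otherwise direct
    thresholds: <1 -> 1, [1, 2] -> 2, (2, 20] -> 3, (20, 50] -> 4,
    >50 -> 5 (the printed class bounds, made exhaustive).
    """
    if density <= 0:
        raise ValueError("density must be positive for a presence record")
    if density * plot_area <= 1.0:
        return "+"
    if density < 1.0:
        return "1"
    if density <= 2.0:
        return "2"
    if density <= 20.0:
        return "3"
    if density <= 50.0:
        return "4"
    return "5"


def species_occupancies(config: SurveyGenConfig,
                        rng: np.random.Generator) -> pd.Series:
    """Draw truncated-lognormal occupancy probabilities per species."""
    q = np.exp(
        rng.normal(config.occupancy_meanlog, config.occupancy_sdlog,
                   size=config.n_species)
    )
    q = np.clip(q, 1e-6, config.occupancy_max)
    return pd.Series(q, index=species_names(config.n_species), name="occupancy")


def gen_survey(config: SurveyGenConfig) -> pd.DataFrame:
    """Generate a validated two-period long-format survey table."""
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("occupancy", "density", "presence", "years", "crops"),
            ss.spawn(5),
        )
    }
    sp = species_names(config.n_species)
    q = species_occupancies(config, streams["occupancy"]).to_numpy()
    log_mean_density = (
        config.coupling_intercept
        + config.coupling_slope * np.log(q)
        + streams["density"].normal(0, config.density_noise_sd, len(sp))
    )
    shift = np.array([config.period_effects.get(s, 1.0) for s in sp])

    rng_p = streams["presence"]
    rng_y = streams["years"]
    records = []

    def emit_field(field_id, year, period, region, crop, occ):
        # occurrence tables cannot represent a weed-free field, so presence
        # vectors are redrawn until nonempty; with realistic pool sizes an
        # all-absent draw is vanishingly rare
        if not np.any(occ > 0):
            raise ValueError("all-zero occupancy vector")
        present = rng_p.random(len(sp)) < occ
        while not present.any():
            present = rng_p.random(len(sp)) < occ
        for j in np.flatnonzero(present):
            d = float(np.exp(
                rng_p.normal(log_mean_density[j], config.within_field_sd)
            ))
            records.append((
                field_id, year, period, region, crop, "control", sp[j],
                discretize_density(d),
            ))
            if config.include_treated and period == "P2000s":
                if rng_p.random() < config.treated_occupancy_factor:
                    dt = d * float(np.exp(rng_p.normal(-0.7, 0.5)))
                    records.append((
                        field_id, year, period, region, crop, "treated",
                        sp[j], discretize_density(dt),
                    ))

    for region in sorted(config.n_fields_per_region_per_period):
        n1, n2 = config.n_fields_per_region_per_period[region]
        for i in range(n1):
            emit_field(f"P1_{region}_{i:04d}", YEAR_1970S, "P1970s", region,
                       config.focal_crop, q)
        q2 = np.clip(q * shift, 0, config.occupancy_max)
        years = YEARS_2000S
        for i in range(n2):
            year = int(years[rng_y.integers(len(years))])
            emit_field(f"P2_{region}_{i:04d}", year, "P2000s", region,
                       config.focal_crop, q2)

    if config.other_crops:
        rng_c = streams["crops"]
        regions = sorted(config.n_fields_per_region_per_period)
        for crop in sorted(config.other_crops):
            n = config.other_crops[crop]
            affinity = np.clip(
                np.exp(rng_c.normal(0.0, 0.7, len(sp))), 0, None
            )
            q_crop = np.clip(q * affinity, 0, config.occupancy_max)
            for i in range(n):
                region = regions[i % len(regions)]
                year = int(YEARS_2000S[rng_y.integers(len(YEARS_2000S))])
                emit_field(f"P2_{crop}_{region}_{i:04d}", year, "P2000s",
                           region, crop, q_crop)

    df = pd.DataFrame(records, columns=[
        "field_id", "year", "period", "region", "crop", "plot", "species",
        "score",
    ])
    from .io import validate_survey

    return validate_survey(df)


def gen_tree(n_tips: int, seed: int = 0, taxon_labels=None) -> dendropy.Tree:
    """Random pure-birth (Yule) ultrametric tree, depth normalized to 1.

    The process starts from a root bifurcation and splits a uniformly
    chosen lineage after Exp(k)-distributed waiting times (k = current
    lineage count); a final waiting time after the last split keeps every
    terminal branch strictly positive, so the phylogenetic covariance
    matrix is nonsingular.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    labels = list(taxon_labels) if taxon_labels else species_names(n_tips)
    if len(labels) != n_tips:
        raise ValueError("taxon_labels length must equal n_tips")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    t = 0.0
    open_lineages = []  # (node, birth time) of each extant lineage
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        open_lineages.append((child, 0.0))
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / k)
        node, birth = open_lineages.pop(int(rng.integers(k)))
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            open_lineages.append((child, t))
        k += 1
    t += rng.exponential(1.0 / k)
    for (node, birth), lab in zip(open_lineages, labels):
        node.edge.length = (t - birth) / t
        node.taxon = ns.new_taxon(lab)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.length is None:
            continue
        edge.length /= t
    return tree


def gen_brownian_traits(tree, config: TraitEvolConfig):
    """Simulate (response, predictors) under Brownian evolution on a tree.

    Predictors are i.i.d. standard normal; the response is
    X @ beta_true + eps with eps ~ MVN(0, sigma2 * V(lambda_true)), V the
    shared-branch-length covariance of the tree.
    """
    V = vcv_from_tree(tree)
    if len(V) < 3:
        raise ValueError("need at least 3 tips")
    Vl = pagel_transform(V, lam=config.lambda_true).to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = len(V)
    p = len(config.beta_true)
    X = rng.standard_normal((n, p))
    try:
        L = np.linalg.cholesky(config.sigma2 * Vl)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular trait covariance; check for zero-length cherries "
            f"(lambda={config.lambda_true})"
        ) from exc
    eps = L @ rng.standard_normal(n)
    y = X @ np.asarray(config.beta_true, dtype=float) + eps
    species = list(V.index)
    return (
        pd.Series(y, index=species, name="response"),
        pd.DataFrame(X, index=species,
                     columns=[f"x{i + 1}" for i in range(p)]),
    )


#: observed modality frequencies of the qualitative traits (out of 95 spp.)
LIFE_FORMS = {"Geophyte": 10, "Hemicryptophyte": 12, "Therophyte": 73}
EMERGENCE_PERIODS = {
    "All-year-round": 29,
    "Autumn-Winter-Spring": 15,
    "Spring": 9,
    "Spring-Summer": 24,
    "Summer": 18,
}
DISPERSAL_MODES = {"Animal": 25, "Gravity": 33, "Wind": 37}
PATHWAYS = {"C3": 70, "C4": 25}

#: plausible ranges of the quantitative traits (min, max, published units)
TRAIT_RANGES = {
    "SLA": (10.9, 53.7),            # cm^2/g
    "plant_height": (20.0, 500.0),  # cm
    "seed_weight": (0.05, 39.9),    # g (per 1000 seeds scale of the source)
    "flowering_onset": (1, 8),      # month
    "flowering_duration": (1, 12),  # months
    "fecundity": (30.0, 40000.0),   # seeds per plant
    "seed_longevity": (3.0, 100.0), # years
    "ellenberg_L": (5, 9),
    "ellenberg_N": (1, 9),
    "ellenberg_T": (5, 9),
    "herbicide_sensitivity": (1.5, 6.0),
}

QUANTITATIVE_TRAITS = list(TRAIT_RANGES)
QUALITATIVE_TRAITS = ["life_form", "emergence_period", "dispersal_mode",
                      "pathway"]


def _categ(rng, n, table):
    levels = sorted(table)
    p = np.array([table[k] for k in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def gen_traits(n_species: int, seed: int = 0, species=None) -> pd.DataFrame:
    """Complete mixed trait table with plausible ranges and modalities."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    idx = pd.Index(species or species_names(n_species), name="species")

    def bounded_lognormal(median, sdlog, lo, hi):
        return np.clip(
            np.exp(rng.normal(np.log(median), sdlog, n_species)), lo, hi
        )

    df = pd.DataFrame(index=idx)
    df["SLA"] = np.clip(rng.normal(28.1, 8.0, n_species), *TRAIT_RANGES["SLA"])
    df["plant_height"] = bounded_lognormal(80, 0.6, *TRAIT_RANGES["plant_height"])
    df["seed_weight"] = bounded_lognormal(0.8, 1.2, *TRAIT_RANGES["seed_weight"])
    df["flowering_onset"] = rng.integers(1, 9, n_species)
    df["flowering_duration"] = rng.integers(1, 13, n_species)
    df["fecundity"] = bounded_lognormal(4000, 1.1, *TRAIT_RANGES["fecundity"])
    df["seed_longevity"] = bounded_lognormal(26, 0.7,
                                             *TRAIT_RANGES["seed_longevity"])
    df["ellenberg_L"] = rng.integers(5, 10, n_species)
    df["ellenberg_N"] = rng.integers(1, 10, n_species)
    df["ellenberg_T"] = rng.integers(5, 10, n_species)
    df["herbicide_sensitivity"] = np.round(
        rng.uniform(1.5, 6.0, n_species), 1
    )
    df["life_form"] = _categ(rng, n_species, LIFE_FORMS)
    df["emergence_period"] = _categ(rng, n_species, EMERGENCE_PERIODS)
    df["dispersal_mode"] = _categ(rng, n_species, DISPERSAL_MODES)
    df["pathway"] = _categ(rng, n_species, PATHWAYS)
    return df


def gen_annotations(species, seed: int = 0) -> pd.DataFrame:
    """Taxonomic group, origin class and resistance flag per species."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    idx = pd.Index(list(species), name="species")
    n = len(idx)
    return pd.DataFrame({
        "group_taxo": rng.choice(
            ["Dicot", "Pooideae", "Panicoideae"], size=n, p=[0.7, 0.12, 0.18]
        ),
        "origin": rng.choice(
            ["native", "archaeophyte", "neophyte"], size=n, p=[0.5, 0.35, 0.15]
        ),
        "resistant_pops": rng.random(n) < 0.15,
    }, index=idx)
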