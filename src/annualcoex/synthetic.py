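"""Synthetic pot-experiment and field-survey data with known ground truth.

Everything downstream (model fitting, coexistence metrics, field GLMs) is
testable against these generators because the generating parameters are
known exactly.  The pot generator mirrors the published experimental
design: per focal species x watering treatment, 16 pots with no
neighbours, 12 + 12 pots with 4 conspecific/heterospecific neighbours,
8 + 8 with 10, and 8 + 8 with 20.  Seed counts are drawn from an NB2
negative binomial whose mean follows the Beverton--Holt annual-plant form

    mu = lambda_focal / (1 + alpha_intra * N_intra + alpha_inter * N_inter)

Neighbour densities are the exact post-thinning germinant counts, not a
random realisation, mirroring a thinned experiment.  All randomness flows
from a single integer seed through a named :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionParams",
    "ExperimentDesign",
    "FieldParams",
    "FieldSurvey",
    "make_design",
    "simulate_seed_production",
    "simulate_germination",
    "simulate_field_survey",
    "DEFAULT_REPLICATES",
]

#: Default replicate counts per neighbour density (per neighbour type for
#: positive densities; the N = 0 pots are shared by both neighbour types).
DEFAULT_REPLICATES: dict[int, int] = {0: 16, 4: 12, 10: 8, 20: 8}

SPECIES = ("i", "j")
TREATMENTS = ("dry", "wet")

SEED_TABLE_COLUMNS = [
    "pot",
    "treatment",
    "focal",
    "neighbour",
    "neighbour_density",
    "seeds",
]
GERMINATION_COLUMNS = ["species", "pot", "sown", "germinated"]


@dataclass(frozen=True)
class CompetitionParams:
    """Ground-truth Beverton--Holt parameters for a two-species pair.

    ``lambda_x`` is per-germinant fecundity with no neighbours (seeds per
    plant, > 0); ``alpha_xy`` is the per-neighbour interaction coefficient
    (effect on species x of one y individual, dimensionless per plant);
    ``g_x`` is a germination fraction in [0, 1]; ``theta`` is the NB2
    dispersion (> 0; variance = mu + mu^2 / theta).  There is no seed-bank
    survival parameter: the model assumes no between-year seed carryover,
    so no temporal storage effect is possible.
    """

    lambda_i: float
    lambda_j: float
    alpha_ii: float
    alpha_ij: float
    alpha_jj: float
    alpha_ji: float
    g_i: float = 0.670
    g_j: float = 0.891
    theta: float = 5.0

    def __post_init__(self) -> None:
        if not (self.lambda_i > 0 and self.lambda_j > 0):
            raise ValueError("fecundities lambda_i, lambda_j must be > 0")
        if not self.theta > 0:
            raise ValueError("dispersion theta must be > 0")
        for name in ("g_i", "g_j"):
            g = getattr(self, name)
            if not (0.0 <= g <= 1.0):
                raise ValueError(f"{name}={g} outside [0, 1]")
        for name in ("alpha_ii", "alpha_ij", "alpha_jj", "alpha_ji"):
            a = getattr(self, name)
            if not math.isfinite(a):
                raise ValueError(f"{name} must be finite")

    def lam(self, species: str) -> float:
        return self.lambda_i if species == "i" else self.lambda_j

    def alphas(self, focal: str) -> tuple[float, float]:
        """(alpha_intra, alpha_inter) for the given focal species."""
        if focal == "i":
            return self.alpha_ii, self.alpha_ij
        return self.alpha_jj, self.alpha_ji

    def g(self, species: str) -> float:
        return self.g_i if species == "i" else self.g_j


@dataclass(frozen=True)
class ExperimentDesign:
    """Pot layout: one row per (focal, neighbour type, density, treatment) cell."""

    cells: pd.DataFrame  # columns: treatment, focal, neighbour, density, n_pots

    @property
    def n_pots(self) -> int:
        return int(self.cells["n_pots"].sum())

    def pots(self) -> pd.DataFrame:
        """Expand cells to one row per pot, with stable pot identifiers."""
        rows = self.cells.loc[self.cells.index.repeat(self.cells["n_pots"])]
        rows = rows.drop(columns="n_pots").reset_index(drop=True)
        rows.insert(0, "pot", np.arange(1, len(rows) + 1))
        return rows


def make_design(
    replicates: dict[int, int] | None = None,
    species: tuple[str, ...] = SPECIES,
    treatments: tuple[str, ...] = TREATMENTS,
) -> ExperimentDesign:
    """Build the full factorial pot design over focal species x treatments.

    ``replicates`` maps neighbour density to replicate count; the count for
    density 0 is the number of shared no-neighbour pots, while counts at
    positive densities apply to each neighbour type (conspecific and
    heterospecific) separately.  Defaults reproduce the published scheme of
    72 pots per focal species per treatment (16 + 12+12 + 8+8 + 8+8).
    """
    reps = dict(DEFAULT_REPLICATES if replicates is None else replicates)
    for dens, n in reps.items():
        if not (isinstance(dens, (int, np.integer)) and dens >= 0):
            raise ValueError(f"neighbour density {dens!r} must be a non-negative integer")
        if not (isinstance(n, (int, np.integer)) and n > 0):
            raise ValueError(f"replicate count {n!r} for density {dens} must be a positive integer")
    if 0 not in reps:
        raise ValueError("design must include density-0 (no-neighbour) pots")

    records = []
    for trt in treatments:
        for focal in species:
            records.append((trt, focal, "none", 0, reps[0]))
            for dens in sorted(d for d in reps if d > 0):
                for neigh in ("conspecific", "heterospecific"):
                    records.append((trt, focal, neigh, dens, reps[dens]))
    cells = pd.DataFrame(
        records, columns=["treatment", "focal", "neighbour", "density", "n_pots"]
    )
    return ExperimentDesign(cells=cells)


def _bh_mean(params: CompetitionParams, focal: str, neighbour: str, density: int) -> float:
    a_intra, a_inter = params.alphas(focal)
    n_intra = density if neighbour == "conspecific" else 0
    n_inter = density if neighbour == "heterospecific" else 0
    return params.lam(focal) / (1.0 + a_intra * n_intra + a_inter * n_inter)


def simulate_seed_production(
    design: ExperimentDesign,
    params: CompetitionParams | dict[str, CompetitionParams],
    rng_seed: int,
) -> pd.DataFrame:
    """Draw one seed count per pot from NB2 around the Beverton--Holt mean.

    ``params`` is either a single :class:`CompetitionParams` (applied to
    every treatment) or a mapping treatment -> params.  Returns a tidy
    table with columns ``pot, treatment, focal, neighbour,
    neighbour_density, seeds``.  Identical seed => identical table.
    """
    rng = np.random.default_rng(rng_seed)
    pots = design.pots()
    by_treatment = isinstance(params, dict)

    mu = np.empty(len(pots))
    theta = np.empty(len(pots))
    for k, row in enumerate(pots.itertuples(index=False)):
        p = params[row.treatment] if by_treatment else params
        m = _bh_mean(p, row.focal, row.neighbour, row.density)
        if not (math.isfinite(m) and m > 0):
            raise ValueError(
                f"non-positive or non-finite Beverton-Holt mean {m} for pot "
                f"{row.pot} (focal={row.focal}, treatment={row.treatment}, "
                f"neighbour={row.neighbour}, density={row.density})"
            )
        mu[k] = m
        theta[k] = p.theta

    # NB2 via the (n, p) parameterisation: n = theta, p = theta/(theta+mu)
    seeds = rng.negative_binomial(theta, theta / (theta + mu))
    out = pots.rename(columns={"density": "neighbour_density"}).copy()
    out["seeds"] = seeds.astype(int)
    return out[SEED_TABLE_COLUMNS]


def simulate_germination(
    params: CompetitionParams,
    pots_per_species: int = 72,
    seeds_per_pot: int = 3,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Binomial germination trials, by default 72 pots x 3 seeds per species."""
    if pots_per_species <= 0 or seeds_per_pot <= 0:
        raise ValueError("pots_per_species and seeds_per_pot must be positive")
    rng = np.random.default_rng(rng_seed)
    frames = []
    for sp in SPECIES:
        germ = rng.binomial(seeds_per_pot, params.g(sp), size=pots_per_species)
        frames.append(
            pd.DataFrame(
                {
                    "species": sp,
                    "pot": np.arange(1, pots_per_species + 1),
                    "sown": seeds_per_pot,
                    "germinated": germ,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[GERMINATION_COLUMNS]


# ---------------------------------------------------------------------------
# Field survey generator


@dataclass(frozen=True)
class FieldParams:
    """Generative parameters for the two-scale field survey.

    Plot abundances are NB2 on the log scale with random intercepts for
    site and transect; the introduced species' log-abundance is linear in
    the native species' plot count with slope ``cross_effect`` (negative by
    default, emulating the observed inverse abundance pattern).  Individual
    seed output depends on plant height (both species) and, for the
    introduced species only, negatively on heterospecific plot density.
    """

    n_plots_1m: int = 70
    n_sites: int = 2
    transects_per_site: int = 5
    # abundance model (1-m^2 scale)
    log_abundance_i: float = math.log(15.0)
    log_abundance_j: float = math.log(10.0)
    cross_effect: float = -0.04  # d log E[count_j] / d count_i
    theta_abundance: float = 2.0
    sd_site: float = 0.25
    sd_transect: float = 0.25
    # individual fecundity model (log scale)
    fec_intercept_i: float = math.log(40.0)
    fec_intercept_j: float = math.log(40.0)
    height_effect: float = 0.04  # per cm, both species
    infl_effect_j: float = 0.0
    size_effect_j: float = 0.0
    dd_intra_i: float = 0.0
    dd_inter_i: float = 0.0
    dd_intra_j: float = 0.0
    dd_inter_j: float = -0.02  # heterospecific density depresses j fecundity
    theta_fecundity: float = 5.0
    max_individuals_per_plot: int = 10
    # covariates
    mean_height: float = 18.0
    sd_height: float = 5.0
    mean_inflorescences: float = 4.0
    vwc_mean: float = 20.0
    vwc_sd: float = 6.0
    p_deep_soil: float = 0.5

    def __post_init__(self) -> None:
        if self.theta_abundance <= 0 or self.theta_fecundity <= 0:
            raise ValueError("negative-binomial dispersions must be > 0")
        if self.n_plots_1m <= 0 or self.n_sites <= 0 or self.transects_per_site <= 0:
            raise ValueError("plot/site/transect counts must be positive")


@dataclass(frozen=True)
class FieldSurvey:
    """Two tidy tables: plot-level counts/covariates and per-individual records."""

    plots: pd.DataFrame
    individuals: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    return rng.negative_binomial(theta, theta / (theta + mu))


def simulate_field_survey(field_params: FieldParams | None = None, rng_seed: int = 0) -> FieldSurvey:
    """Generate nested field-survey plots and per-individual fecundity records.

    Defaults emulate the published survey shape: 70 plots of 1 m^2, each
    containing two nested 0.1-m^2 subplots (140 rows at the small scale),
    soil moisture (%VWC) at two probe depths and a binary soil-depth class.
    Subplot counts are binomial area-thinnings of the parent plot counts.
    """
    fp = field_params or FieldParams()
    rng = np.random.default_rng(rng_seed)

    n = fp.n_plots_1m
    n_transects = fp.n_sites * fp.transects_per_site
    transect_of_plot = np.arange(n) % n_transects
    site_of_transect = np.arange(n_transects) // fp.transects_per_site
    u_site = rng.normal(0.0, fp.sd_site, size=fp.n_sites)
    u_transect = rng.normal(0.0, fp.sd_transect, size=n_transects)
    plot_re = u_site[site_of_transect[transect_of_plot]] + u_transect[transect_of_plot]

    count_i = _nb_draw(rng, np.exp(fp.log_abundance_i + plot_re), fp.theta_abundance)
    mu_j = np.exp(fp.log_abundance_j + plot_re + fp.cross_effect * count_i)
    count_j = _nb_draw(rng, mu_j, fp.theta_abundance)

    vwc76 = np.clip(rng.normal(fp.vwc_mean, fp.vwc_sd, size=n), 0.0, 100.0)
    vwc12 = np.clip(vwc76 + rng.normal(2.0, 2.0, size=n), 0.0, 100.0)
    deep = rng.random(n) < fp.p_deep_soil

    plot_ids = [f"p{k + 1:03d}" for k in range(n)]
    base = pd.DataFrame(
        {
            "site": [f"s{site_of_transect[transect_of_plot[k]] + 1}" for k in range(n)],
            "transect": [f"t{transect_of_plot[k] + 1:02d}" for k in range(n)],
            "plot": plot_ids,
            "parent_plot": plot_ids,
            "area_m2": 1.0,
            "count_i": count_i,
            "count_j": count_j,
            "vwc_7_6cm": np.round(vwc76, 1),
            "vwc_12cm": np.round(vwc12, 1),
            "soil_depth_class": np.where(deep, ">12cm", "<12cm"),
        }
    )

    # two nested 0.1-m^2 subplots per plot, counts thinned at area ratio 0.1
    sub_counts = {}
    sub_frames = []
    for s in (1, 2):
        sub = base.copy()
        sub["plot"] = [f"{p}.{s}" for p in plot_ids]
        sub["area_m2"] = 0.1
        sub_counts[s] = {
            "i": rng.binomial(count_i, 0.1),
            "j": rng.binomial(count_j, 0.1),
        }
        sub["count_i"] = sub_counts[s]["i"]
        sub["count_j"] = sub_counts[s]["j"]
        sub_frames.append(sub)
    plots = pd.concat([base, *sub_frames], ignore_index=True)

    # per-individual records in subplots, up to max_individuals_per_plot each;
    # neighbour densities are the parent 1-m^2 plot counts
    sites = base["site"].to_numpy()
    transects = base["transect"].to_numpy()
    parent_counts = {"i": count_i, "j": count_j}
    ind_rows = []
    for s in (1, 2):
        for k in range(n):
            for sp in SPECIES:
                n_ind = min(int(sub_counts[s][sp][k]), fp.max_individuals_per_plot)
                if n_ind == 0:
                    continue
                other = "j" if sp == "i" else "i"
                dens_con = int(parent_counts[sp][k])
                dens_het = int(parent_counts[other][k])
                height = rng.normal(fp.mean_height, fp.sd_height, size=n_ind).clip(1.0)
                infl = rng.poisson(fp.mean_inflorescences, size=n_ind) + 1
                size = rng.lognormal(1.0, 0.3, size=n_ind)
                if sp == "i":
                    eta = (
                        fp.fec_intercept_i
                        + fp.height_effect * height
                        + fp.dd_intra_i * dens_con
                        + fp.dd_inter_i * dens_het
                    )
                else:
                    eta = (
                        fp.fec_intercept_j
                        + fp.height_effect * height
                        + fp.infl_effect_j * infl
                        + fp.size_effect_j * size
                        + fp.dd_intra_j * dens_con
                        + fp.dd_inter_j * dens_het
                    )
                seeds = _nb_draw(rng, np.exp(eta), fp.theta_fecundity)
                for m in range(n_ind):
                    ind_rows.append(
                        (
                            sites[k],
                            transects[k],
                            f"{plot_ids[k]}.{s}",
                            sp,
                            round(float(height[m]), 1),
                            int(infl[m]),
                            round(float(size[m]), 2),
                            dens_con,
                            dens_het,
                            int(seeds[m]),
                        )
                    )
    individuals = pd.DataFrame(
        ind_rows,
        columns=[
            "site",
            "transect",
            "plot",
            "species",
            "height_cm",
            "inflorescences",
            "infl_size",
            "density_conspecific",
            "density_heterospecific",
            "seeds",
        ],
    )
    return FieldSurvey(plots=plots, individuals=individuals)
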