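"""Synthetic stem-mapped stands, traits, climate and growth with known truth.

The generators emulate a lowland tropical-forest census network: square
plots fully mapped every two years, every stem >= 10 cm DBH, a
rank-abundance species pool with log-normal trait variation, and a
seasonal climate (3-month dry season) with AR(1) interannual anomalies.
``simulate_growth`` then forward-simulates diameter growth from the same
hierarchical model the package fits — species coefficient vectors drawn
from a multivariate normal around community means, plot and individual
intercepts, Gaussian residual — recording every covariate and draw so that
parameter recovery can be tested against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .climate import ClimatologyScaler, interval_anomaly
from .neighbourhood import TRAITS, NeighbourhoodConfig, compute_indices

__all__ = [
    "StandConfig",
    "ClimateGenConfig",
    "SimulationTruth",
    "GrowthSimConfig",
    "generate_stand",
    "generate_traits",
    "generate_climate",
    "simulate_growth",
    "DEFAULT_TRAIT_MEANS",
    "DEFAULT_TRAIT_SDS",
    "DEFAULT_CLIMATE_NORMALS",
]

#: realistic species-level trait means for a Guianan-type tree community
DEFAULT_TRAIT_MEANS = {
    "d13C": -31.5,   # permil
    "pi_tlp": -1.8,  # MPa (negative support)
    "LSWC": 120.0,   # %
    "g_min": 4.5,    # mmol m-2 s-1
    "LA": 80.0,      # cm2
    "SLA": 12.0,     # m2 kg-1
    "L_thick": 0.25,  # mm
    "L_tough": 1.5,  # N
    "WSG": 0.65,     # unitless
}
DEFAULT_TRAIT_SDS = {
    "d13C": 1.5, "pi_tlp": 0.35, "LSWC": 30.0, "g_min": 2.0, "LA": 60.0,
    "SLA": 3.5, "L_thick": 0.08, "L_tough": 0.8, "WSG": 0.12,
}

#: 12-month climatological means and SDs per variable: wet-season plateau
#: with an Aug-Nov dry season (heat, high VPD, positive water deficit)
DEFAULT_CLIMATE_NORMALS = {
    "T_max": (
        [30.1, 30.2, 30.4, 30.5, 30.2, 29.9, 30.3, 31.0, 31.8, 32.0, 31.4, 30.4],
        [0.5] * 12,
    ),
    "VPD": (
        [0.55, 0.58, 0.62, 0.60, 0.55, 0.50, 0.60, 0.80, 1.00, 1.05, 0.90, 0.65],
        [0.10] * 12,
    ),
    "CWD": (
        [0.0, 0.0, 10.0, 0.0, 0.0, 0.0, 5.0, 40.0, 80.0, 90.0, 60.0, 10.0],
        [5.0, 5.0, 8.0, 5.0, 5.0, 5.0, 6.0, 15.0, 25.0, 25.0, 20.0, 8.0],
    ),
}


@dataclass(frozen=True)
class StandConfig:
    """Stem map geometry and composition.

    The defaults give two ~1.2 ha plots at a typical terra-firme stem
    density, about 1 500 stems over 20 species — the scale used throughout
    the package's recovery experiments.
    """

    n_plots: int = 2
    plot_side: float = 110.0         # m
    stem_density: float = 625.0      # stems ha-1, DBH >= 10 cm
    n_species: int = 20
    abundance_skew: float = 0.9      # geometric rank-abundance ratio in (0, 1]
    dbh_lognormal_mu: float = 2.89   # log-cm (median ~18 cm before truncation)
    dbh_lognormal_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.plot_side <= 0 or self.stem_density <= 0:
            raise ValueError("plot_side and stem_density must be positive")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if not 0 < self.abundance_skew <= 1:
            raise ValueError("abundance_skew must lie in (0, 1]")

    @property
    def plot_area_ha(self) -> float:
        return self.plot_side ** 2 / 1e4

    @property
    def total_area_ha(self) -> float:
        return self.n_plots * self.plot_area_ha

    @property
    def stems_per_plot(self) -> int:
        return round(self.stem_density * self.plot_area_ha)


@dataclass(frozen=True)
class ClimateGenConfig:
    """Seasonal climatology plus AR(1) standardised anomalies."""

    start_year: int = 1990
    end_year: int = 2021
    monthly_means: dict = field(default_factory=lambda: {
        v: list(m) for v, (m, _) in DEFAULT_CLIMATE_NORMALS.items()})
    monthly_sds: dict = field(default_factory=lambda: {
        v: list(s) for v, (_, s) in DEFAULT_CLIMATE_NORMALS.items()})
    anomaly_ar_coef: float = 0.6     # month-to-month persistence
    anomaly_sd: float = 1.0          # stationary SD of the anomaly process
    seed: int = 0

    def __post_init__(self):
        if self.end_year - self.start_year < 2:
            raise ValueError("need at least a three-year climate series")
        if not 0 <= self.anomaly_ar_coef < 1:
            raise ValueError("anomaly_ar_coef must lie in [0, 1)")
        for var, sds in self.monthly_sds.items():
            if len(sds) != 12 or len(self.monthly_means[var]) != 12:
                raise ValueError(f"{var}: means/sds must be 12-vectors")
            if any(s <= 0 for s in sds):
                raise ValueError(f"{var}: monthly SDs must be positive")


def _default_sigma() -> np.ndarray:
    return 0.15 ** 2 * np.eye(7)


@dataclass
class SimulationTruth:
    """Ground-truth hyperparameters of the generative growth model.

    ``alpha`` is the community intrinsic log-growth; the six slopes are the
    community responses to size, climate anomaly, crowding, the trait
    index, and the two climate interactions.  Species coefficient vectors
    are MVN(mean=(alpha, beta1..6), cov=Sigma).  Defaults sit in the
    qualitative regime of interest: crowding depresses growth, trait
    dissimilarity raises it, climate anomalies depress it.
    """

    alpha: float = -0.1
    beta: tuple = (0.3, -0.2, -0.4, 0.1, 0.15, 0.1)
    Sigma: np.ndarray = field(default_factory=_default_sigma)
    sigma_resid: float = 0.6
    sigma_plot: float = 0.1
    sigma_indiv: float = 0.3
    species_coefs: np.ndarray | None = None

    def __post_init__(self):
        self.Sigma = np.asarray(self.Sigma, float)
        if self.Sigma.shape != (7, 7) or not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be a symmetric 7x7 matrix")
        if np.linalg.eigvalsh(self.Sigma).min() < -1e-10:
            raise ValueError("Sigma must be positive semidefinite")
        if len(self.beta) != 6:
            raise ValueError("beta must have six entries")

    @property
    def mean_vector(self) -> np.ndarray:
        return np.array([self.alpha, *self.beta], float)

    def draw_species_coefs(self, n_species: int, rng: np.random.Generator
                           ) -> np.ndarray:
        """n_species x 7 coefficient matrix from the species-level MVN."""
        # eigen square root tolerates a PSD (possibly singular) Sigma
        vals, vecs = np.linalg.eigh(self.Sigma)
        root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
        z = rng.standard_normal((n_species, 7))
        return self.mean_vector + z @ root.T


def generate_stand(config: StandConfig, *, census_year: int = 1991) -> pd.DataFrame:
    """Census-0 stem map: uniform positions, rank-abundance species, DBH >= 10.

    Stem counts per plot are round(density x area); positions are i.i.d.
    uniform within each plot (homogeneous Poisson conditioned on the
    count); DBH is truncated log-normal at 10 cm via inverse-CDF sampling.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_per_plot = config.stems_per_plot
    ranks = np.arange(config.n_species)
    probs = config.abundance_skew ** ranks
    probs /= probs.sum()
    species_ids = np.array([f"sp{r + 1:03d}" for r in ranks])

    from scipy import stats
    dist = stats.lognorm(s=config.dbh_lognormal_sigma,
                         scale=np.exp(config.dbh_lognormal_mu))
    f10 = dist.cdf(10.0)

    rows = []
    counter = 0
    for p in range(config.n_plots):
        plot_id = f"p{p + 1:02d}"
        xy = rng.uniform(0.0, config.plot_side, size=(n_per_plot, 2))
        species = rng.choice(species_ids, size=n_per_plot, p=probs)
        u = rng.uniform(f10, 1.0, size=n_per_plot)
        dbh = dist.ppf(u)
        for i in range(n_per_plot):
            counter += 1
            rows.append({
                "tree_id": f"t{counter:06d}",
                "plot_id": plot_id,
                "species_id": species[i],
                "x_m": xy[i, 0],
                "y_m": xy[i, 1],
                "census_year": census_year,
                "dbh_cm": dbh[i],
                "status": "alive",
                "focal_eligible": True,
            })
    return pd.DataFrame(rows)


def generate_traits(n_species: int,
                    trait_means: dict | None = None,
                    trait_sds: dict | None = None,
                    trait_corr: np.ndarray | None = None,
                    seed: int = 0,
                    n_unmeasured: int = 0) -> pd.DataFrame:
    """Species x trait table drawn MVN on a latent scale, back-transformed.

    Positive-support traits (everything except d13C and pi_tlp) are
    moment-matched log-normal, pi_tlp is the negative of a log-normal
    matched to its magnitude, d13C is plain normal; column means and SDs
    therefore converge to the requested targets as ``n_species`` grows.
    The last ``n_unmeasured`` species are flagged as lacking measurements
    (candidates for community-weighted-mean gap-filling downstream).
    """
    trait_means = dict(DEFAULT_TRAIT_MEANS, **(trait_means or {}))
    trait_sds = dict(DEFAULT_TRAIT_SDS, **(trait_sds or {}))
    k = len(TRAITS)
    corr = np.eye(k) if trait_corr is None else np.asarray(trait_corr, float)
    if corr.shape != (k, k) or not np.allclose(corr, corr.T) \
            or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("trait_corr must be a symmetric correlation matrix with unit diagonal")
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ValueError("trait_corr is not positive semidefinite")

    rng = np.random.default_rng(seed)
    vals, vecs = np.linalg.eigh(corr)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
    z = rng.standard_normal((n_species, k)) @ root.T

    data = {}
    for j, trait in enumerate(TRAITS):
        mean, sd = trait_means[trait], trait_sds[trait]
        if trait == "d13C":
            data[trait] = mean + sd * z[:, j]
        else:
            sign = -1.0 if trait == "pi_tlp" else 1.0
            mag = abs(mean)
            if sd == 0:
                data[trait] = np.full(n_species, mean)
                continue
            s2 = np.log1p((sd / mag) ** 2)
            mu = np.log(mag) - s2 / 2
            data[trait] = sign * np.exp(mu + np.sqrt(s2) * z[:, j])
    table = pd.DataFrame(data, index=pd.Index(
        [f"sp{i + 1:03d}" for i in range(n_species)], name="species_id"))
    measured = np.ones(n_species, bool)
    if n_unmeasured:
        measured[n_species - n_unmeasured:] = False
    table["measured"] = measured
    return table


def generate_climate(config: ClimateGenConfig) -> pd.DataFrame:
    """Monthly series: climatology plus AR(1) standardised anomalies.

    value(y, m) = mean_m + sd_m * a(y, m), where a is a stationary AR(1)
    with the configured lag-1 coefficient and stationary SD.  Variables
    get independent anomaly streams; deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    years = range(config.start_year, config.end_year + 1)
    n_months = 12 * (config.end_year - config.start_year + 1)
    phi, sd = config.anomaly_ar_coef, config.anomaly_sd
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    rows = []
    for var in config.monthly_means:
        a = np.empty(n_months)
        prev = rng.standard_normal() * sd
        for t in range(n_months):
            prev = phi * prev + innov_sd * rng.standard_normal()
            a[t] = prev
        means = config.monthly_means[var]
        sds = config.monthly_sds[var]
        t = 0
        for year in years:
            for month in range(1, 13):
                rows.append({"variable": var, "year": year, "month": month,
                             "value": means[month - 1] + sds[month - 1] * a[t]})
                t += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GrowthSimConfig:
    """Knobs of the forward growth simulation.

    The response scale is a z-like log-growth: AGR is recovered as
    ``exp(response * log_scale + log_mean) - shift`` (then floored at zero
    for the DBH update), so the simulator's transform is exactly
    invertible and known to recovery tests.
    """

    climate_var: str = "T_max"
    trait: str = "pi_tlp"
    index_family: str = "dissimilarity"   # or "hierarchy"
    first_census_year: int = 1991
    census_step: int = 2
    baseline: tuple[int, int] = (1991, 2021)
    response_shift: float = 0.1           # cm yr-1
    response_log_mean: float = -1.5       # log cm yr-1, centres AGR near 0.12
    response_log_scale: float = 1.0
    neighbourhood: NeighbourhoodConfig = field(default_factory=NeighbourhoodConfig)
    round_dbh: bool = False               # emulate 0.5 cm circumference precision

    def __post_init__(self):
        if self.index_family not in ("hierarchy", "dissimilarity"):
            raise ValueError("index_family must be 'hierarchy' or 'dissimilarity'")
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")


def _round_to_tape(dbh: np.ndarray) -> np.ndarray:
    """Round to the DBH grid implied by 0.5 cm circumference precision."""
    step = 0.5 / np.pi
    return np.round(dbh / step) * step


def simulate_growth(stand: pd.DataFrame, traits: pd.DataFrame,
                    climate: pd.DataFrame, truth: SimulationTruth,
                    n_intervals: int = 5,
                    config: GrowthSimConfig = GrowthSimConfig(),
                    *, plot_side: float | None = None,
                    seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Forward-simulate biennial censuses from the hierarchical growth model.

    Each interval recomputes the climate anomaly and the neighbourhood
    indices with the package's own modules, builds the standardised design
    row for every tree (reference standardisation constants frozen at the
    first census), draws the log-growth response, inverts the response
    transform to an AGR and advances DBH by two years of growth.  The
    returned truth log carries the full design matrix, the drawn species
    coefficients and intercepts, and every response draw.

    The population is closed: no recruitment or mortality, and AGR is
    floored at zero for the DBH update so log-size stays defined.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    missing = set(stand["species_id"]) - set(traits.index)
    if missing:
        raise ValueError(f"species missing from trait table: {sorted(missing)}")
    rng = np.random.default_rng(seed)

    scaler = ClimatologyScaler(baseline=config.baseline).fit(climate)
    std_anoms = scaler.transform(climate)
    std_var = std_anoms[std_anoms["variable"] == config.climate_var]

    species_levels = pd.Index(sorted(stand["species_id"].unique()))
    if truth.species_coefs is None:
        coefs = truth.draw_species_coefs(len(species_levels), rng)
    else:
        coefs = np.asarray(truth.species_coefs, float)
        if coefs.shape != (len(species_levels), 7):
            raise ValueError("species_coefs shape must be (n_species, 7)")

    plot_levels = pd.Index(sorted(stand["plot_id"].unique()))
    gamma = rng.normal(0.0, truth.sigma_plot, size=len(plot_levels))
    tree_levels = pd.Index(stand["tree_id"])
    epsilon = rng.normal(0.0, truth.sigma_indiv, size=len(tree_levels))

    current = stand.copy().reset_index(drop=True)
    censuses = [current.copy()]
    design_rows = []
    standardisation: dict = {}
    ni_col = ("nid_" if config.index_family == "dissimilarity" else "nih_") + config.trait

    for m in range(n_intervals):
        t_start = config.first_census_year + m * config.census_step
        t_end = t_start + config.census_step
        ca = interval_anomaly(std_var, t_end, window=12 * config.census_step)

        idx = compute_indices(current, traits, config.neighbourhood,
                              t_start=t_start, plot_side=plot_side)
        idx = idx.set_index("tree_id").loc[current["tree_id"]]
        log_nci = np.log(idx["nci"].to_numpy(float) + 1.0)
        ni = idx[ni_col].to_numpy(float)
        ni = np.where(np.isnan(ni), 0.0, ni)  # isolated trees: neutral neighbourhood

        log_dbh = np.log(current["dbh_cm"].to_numpy(float))
        sp_code = species_levels.get_indexer(current["species_id"])
        if m == 0:
            sp_mean = np.zeros(len(species_levels))
            for s in range(len(species_levels)):
                sp_mean[s] = log_dbh[sp_code == s].mean()
            centred0 = log_dbh - sp_mean[sp_code]
            standardisation = {
                "species_log_dbh_mean": dict(zip(species_levels, sp_mean)),
                "log_dbh_sd": float(centred0.std(ddof=1)),
                "log_nci_mean": float(log_nci.mean()),
                "log_nci_sd": float(log_nci.std(ddof=1)),
                "ni_mean": float(ni.mean()),
                "ni_sd": float(ni.std(ddof=1)) or 1.0,
            }
        x_dbh = (log_dbh - np.array([standardisation["species_log_dbh_mean"][s]
                                     for s in current["species_id"]])) \
            / standardisation["log_dbh_sd"]
        x_nci = (log_nci - standardisation["log_nci_mean"]) / standardisation["log_nci_sd"]
        x_ni = (ni - standardisation["ni_mean"]) / standardisation["ni_sd"]
        X = np.column_stack([
            np.ones_like(x_dbh), x_dbh, np.full_like(x_dbh, ca), x_nci, x_ni,
            ca * x_nci, ca * x_ni,
        ])
        p_code = plot_levels.get_indexer(current["plot_id"])
        i_code = tree_levels.get_indexer(current["tree_id"])
        mu = np.einsum("nk,nk->n", X, coefs[sp_code]) + gamma[p_code] + epsilon[i_code]
        response = mu + rng.normal(0.0, truth.sigma_resid, size=len(mu))
        agr = np.exp(response * config.response_log_scale
                     + config.response_log_mean) - config.response_shift
        agr_applied = np.maximum(agr, 0.0)
        new_dbh = current["dbh_cm"].to_numpy(float) + config.census_step * agr_applied
        if config.round_dbh:
            new_dbh = _round_to_tape(new_dbh)

        design_rows.append(pd.DataFrame({
            "tree_id": current["tree_id"].to_numpy(),
            "species_id": current["species_id"].to_numpy(),
            "plot_id": current["plot_id"].to_numpy(),
            "t_start": t_start, "t_end": t_end,
            "x_dbh": x_dbh, "x_ca": ca, "x_nci": x_nci, "x_ni": x_ni,
            "x_ca_nci": ca * x_nci, "x_ca_ni": ca * x_ni,
            "mu": mu, "response": response, "agr": agr,
            "agr_applied": agr_applied,
        }))
        current = current.copy()
        current["census_year"] = t_end
        current["dbh_cm"] = new_dbh
        current["below_min_dbh"] = new_dbh < 10.0
        censuses.append(current.copy())

    records = pd.concat(censuses, ignore_index=True)
    truth_log = {
        "truth": {
            "alpha": truth.alpha, "beta": list(truth.beta),
            "Sigma": truth.Sigma.tolist(),
            "sigma_resid": truth.sigma_resid,
            "sigma_plot": truth.sigma_plot,
            "sigma_indiv": truth.sigma_indiv,
        },
        "species_levels": list(species_levels),
        "species_coefs": coefs,
        "gamma_plot": dict(zip(plot_levels, gamma)),
        "epsilon": dict(zip(tree_levels, epsilon)),
        "design": pd.concat(design_rows, ignore_index=True),
        "standardisation": standardisation,
        "response_transform": {
            "shift": config.response_shift,
            "log_mean": config.response_log_mean,
            "log_scale": config.response_log_scale,
        },
        "config": asdict(config),
    }
    return records, truth_log
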