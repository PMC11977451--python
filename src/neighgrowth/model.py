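"""Hierarchical Bayesian model of individual growth.

The transformed log-growth response of tree *i* (species *s*, plot *p*) is

    y_i ~ Normal(mu_i, sigma^2)
    mu_i = alpha_s + beta1_s x_dbh + beta2_s x_ca + beta3_s x_nci
         + beta4_s x_ni + beta5_s x_ca*x_nci + beta6_s x_ca*x_ni
         + gamma_p + eps_tree(i)

with the 7-vector of species coefficients drawn from a multivariate normal
around community-level means with covariance S (correlated species-level
responses), and Gaussian plot and individual intercepts.

Because every layer of this hierarchy is conditionally Gaussian (and the
variance components conditionally inverse-gamma / inverse-Wishart), the
posterior is sampled with a blocked Gibbs sampler drawing each block from
its exact full conditional.  Priors are the conjugate weakly-informative
family: Normal(0, 1) on community coefficients, inverse-Wishart on S and
inverse-gamma on the three variances.  Multiple chains are run from
overdispersed starts and convergence is gated on split-Rhat (via arviz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ModelConfig",
    "ModelData",
    "PosteriorFit",
    "build_design",
    "log_likelihood",
    "HierarchicalGrowthModel",
    "fit_model",
]

#: community-level parameter names in design-column order
COEF_NAMES = ("alpha", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6")

DESIGN_COLUMNS = ("x_dbh", "x_ca", "x_nci", "x_ni", "x_ca_nci", "x_ca_ni")


@dataclass(frozen=True)
class ModelConfig:
    """One cell of the model grid plus sampler settings."""

    index_family: str = "dissimilarity"   # 'hierarchy' | 'dissimilarity'
    climate_var: str = "T_max"
    trait: str = "pi_tlp"
    chains: int = 4
    iterations: int = 3000
    warmup: int = 1500
    seed: int = 0
    rhat_max: float = 1.05

    def __post_init__(self):
        if self.index_family not in ("hierarchy", "dissimilarity"):
            raise ValueError("index_family must be 'hierarchy' or 'dissimilarity'")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("need at least two chains for convergence diagnostics")


@dataclass
class ModelData:
    """Aligned design arrays for one model configuration.

    ``X`` holds the intercept column followed by the six standardised
    covariates; the index arrays are dense integer codes into the
    level lists.
    """

    y: np.ndarray
    X: np.ndarray                     # (n, 7), column 0 = intercept
    species_idx: np.ndarray
    plot_idx: np.ndarray
    indiv_idx: np.ndarray
    species_levels: list
    plot_levels: list
    indiv_levels: list
    frame: pd.DataFrame | None = None
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return len(self.species_levels)

    @property
    def n_plots(self) -> int:
        return len(self.plot_levels)

    @property
    def n_indiv(self) -> int:
        return len(self.indiv_levels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, response: str = "response"
                   ) -> "ModelData":
        """Build from a long table with design columns and group labels."""
        need = set(DESIGN_COLUMNS) | {response, "species_id", "plot_id", "tree_id"}
        missing = need - set(frame.columns)
        if missing:
            raise ValueError(f"design frame lacks columns {sorted(missing)}")
        clean = frame.dropna(subset=list(need)).reset_index(drop=True)
        n_dropped = len(frame) - len(clean)
        X = np.column_stack([np.ones(len(clean))]
                            + [clean[c].to_numpy(float) for c in DESIGN_COLUMNS])
        for name, col in zip(COEF_NAMES[1:], X.T[1:]):
            if len(clean) > 1 and col.std() <= 1e-10 * max(1.0, np.abs(col).max()):
                raise ValueError(f"zero-variance design column for {name}")
        sp_code, sp_levels = pd.factorize(clean["species_id"], sort=True)
        pl_code, pl_levels = pd.factorize(clean["plot_id"], sort=True)
        tr_code, tr_levels = pd.factorize(clean["tree_id"], sort=True)
        return cls(y=clean[response].to_numpy(float), X=X,
                   species_idx=sp_code, plot_idx=pl_code, indiv_idx=tr_code,
                   species_levels=list(sp_levels), plot_levels=list(pl_levels),
                   indiv_levels=list(tr_levels), frame=clean, n_dropped=n_dropped)


def build_design(growth_obs: pd.DataFrame, anomalies: pd.DataFrame,
                 index_sets: pd.DataFrame, config: ModelConfig) -> ModelData:
    """Join response, size, anomaly and neighbourhood tables into a design.

    ``growth_obs`` must already carry ``response`` and ``log_dbh_std``;
    ``index_sets`` should be the coverage-filtered focal subset.  The
    crowding covariate is the z-score of log(NCI + 1) and the trait index
    the z-score of the configured NIh/NId column; interactions are formed
    after standardisation.  Rows losing any covariate in the join are
    dropped (count reported on the result).
    """
    ni_col = ("nid_" if config.index_family == "dissimilarity" else "nih_") + config.trait
    idx_cols = index_sets[["tree_id", "t_start", "nci", ni_col]].rename(
        columns={ni_col: "ni_raw"})
    ca = anomalies[anomalies["variable"] == config.climate_var][["t_end", "ca"]]
    merged = (growth_obs.merge(idx_cols, on=["tree_id", "t_start"], how="inner")
              .merge(ca, on="t_end", how="left"))
    merged = merged.dropna(subset=["response", "log_dbh_std", "nci", "ni_raw", "ca"])
    n_dropped = len(growth_obs) - len(merged)

    def zscore(v):
        v = np.asarray(v, float)
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        if sd == 0:
            raise ValueError("zero-variance design column")
        return (v - v.mean()) / sd

    merged = merged.copy()
    merged["x_dbh"] = merged["log_dbh_std"]
    merged["x_ca"] = merged["ca"]
    merged["x_nci"] = zscore(np.log(merged["nci"].to_numpy(float) + 1.0))
    merged["x_ni"] = zscore(merged["ni_raw"])
    merged["x_ca_nci"] = merged["x_ca"] * merged["x_nci"]
    merged["x_ca_ni"] = merged["x_ca"] * merged["x_ni"]
    data = ModelData.from_frame(merged)
    data.n_dropped += n_dropped
    return data


def log_likelihood(data: ModelData, params: dict) -> float:
    """Gaussian log-likelihood of the observations under explicit parameters.

    ``params`` needs ``species_coefs`` (n_species x 7), ``gamma``
    (n_plots,), ``epsilon`` (n_indiv,) and ``sigma``.
    """
    sigma = float(params["sigma"])
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    coefs = np.asarray(params["species_coefs"], float)
    gamma = np.asarray(params["gamma"], float)
    eps = np.asarray(params["epsilon"], float)
    if coefs.shape != (data.n_species, 7):
        raise ValueError("species_coefs has the wrong shape")
    mu = np.einsum("nk,nk->n", data.X, coefs[data.species_idx]) \
        + gamma[data.plot_idx] + eps[data.indiv_idx]
    r = data.y - mu
    n = data.n_obs
    return float(-0.5 * n * np.log(2 * np.pi) - n * np.log(sigma)
                 - 0.5 * np.sum(r ** 2) / sigma ** 2)


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one fitted configuration.

    Community draws (``alpha``..``beta6``), the per-draw species
    coefficient matrix, covariance ``Sigma``, intercepts and scales are
    stored with a leading (chain, draw) shape.
    """

    draws: dict
    species_levels: list
    plot_levels: list
    indiv_levels: list
    rhat: dict
    diagnostics: dict
    config: ModelConfig

    @property
    def converged(self) -> bool:
        return self.diagnostics["converged"]

    @property
    def n_draws(self) -> int:
        a = self.draws["alpha"]
        return a.shape[0] * a.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws with chain and iteration dimensions merged."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def community_draws(self) -> pd.DataFrame:
        return pd.DataFrame({name: self.flat(name) for name in COEF_NAMES})

    def to_inference_data(self):
        import arviz as az
        return az.from_dict(posterior={k: v for k, v in self.draws.items()})

    def draws_table(self) -> pd.DataFrame:
        """Long (parameter, chain, iteration, value) table of scalar draws."""
        rows = []
        for name in (*COEF_NAMES, "sigma", "sigma_plot", "sigma_indiv"):
            d = self.draws[name]
            for c in range(d.shape[0]):
                rows.append(pd.DataFrame({
                    "parameter": name, "chain": c,
                    "iteration": np.arange(d.shape[1]), "value": d[c]}))
        return pd.concat(rows, ignore_index=True)


class HierarchicalGrowthModel(BaseEstimator, RegressorMixin):
    """Multivariate random-slopes Gaussian growth model, Gibbs-sampled.

    Scikit-learn style estimator: ``fit`` takes either a
    :class:`ModelData` or a design frame (with the six standardised
    covariates, ``species_id``/``plot_id``/``tree_id`` labels) plus a
    response vector, and populates ``posterior_``, ``rhat_`` and
    ``converged_``.  ``predict`` returns posterior-mean expected responses.

    Parameters
    ----------
    chains, iterations, warmup, seed, rhat_max :
        Sampler settings; defaults follow the package's standard protocol
        of four chains of 3000 iterations with 1500 warmup and a 1.05
        split-Rhat gate.
    prior_coef_sd : float
        SD of the Normal(0, .) prior on the seven community coefficients.
    prior_var_shape, prior_var_scale : float
        Inverse-gamma prior on the residual, plot and individual variances.
    prior_cov_df, prior_cov_scale : float
        Inverse-Wishart prior on the species covariance: df and the value
        of its diagonal scale matrix.
    """

    def __init__(self, chains: int = 4, iterations: int = 3000,
                 warmup: int = 1500, seed: int = 0, rhat_max: float = 1.05,
                 prior_coef_sd: float = 1.0,
                 prior_var_shape: float = 2.0, prior_var_scale: float = 0.25,
                 prior_cov_df: float = 9.0, prior_cov_scale: float = 0.04,
                 store_epsilon: bool = True):
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.seed = seed
        self.rhat_max = rhat_max
        self.prior_coef_sd = prior_coef_sd
        self.prior_var_shape = prior_var_shape
        self.prior_var_scale = prior_var_scale
        self.prior_cov_df = prior_cov_df
        self.prior_cov_scale = prior_cov_scale
        self.store_epsilon = store_epsilon

    # ------------------------------------------------------------------
    def _as_data(self, X, y) -> ModelData:
        if isinstance(X, ModelData):
            return X
        frame = X.copy()
        if y is not None:
            frame = frame.assign(response=np.asarray(y, float))
        return ModelData.from_frame(frame)

    def fit(self, X, y=None) -> "HierarchicalGrowthModel":
        data = self._as_data(X, y)
        if data.n_species < 2:
            raise ValueError("the multivariate species layer needs >= 2 species")
        n_keep = self.iterations - self.warmup
        draws = {name: np.empty((self.chains, n_keep)) for name in COEF_NAMES}
        draws.update({
            "sigma": np.empty((self.chains, n_keep)),
            "sigma_plot": np.empty((self.chains, n_keep)),
            "sigma_indiv": np.empty((self.chains, n_keep)),
            "species_coefs": np.empty((self.chains, n_keep, data.n_species, 7)),
            "Sigma": np.empty((self.chains, n_keep, 7, 7)),
            "gamma": np.empty((self.chains, n_keep, data.n_plots)),
        })
        if self.store_epsilon:
            draws["epsilon"] = np.empty((self.chains, n_keep, data.n_indiv),
                                        dtype=np.float32)
        for c in range(self.chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(self.seed) % (2 ** 31),
                                       spawn_key=(c,)))
            self._run_chain(data, rng, draws, c, n_keep)

        rhat = self._compute_rhat(draws)
        diagnostics = {
            "rhat": rhat,
            "max_rhat": max(rhat.values()),
            "converged": max(rhat.values()) <= self.rhat_max,
            "divergences": 0,  # exact full-conditional draws cannot diverge
            "n_draws": self.chains * n_keep,
            "seed": self.seed,
            "sampler": "blocked-gibbs",
        }
        self.posterior_ = PosteriorFit(
            draws=draws, species_levels=data.species_levels,
            plot_levels=data.plot_levels, indiv_levels=data.indiv_levels,
            rhat=rhat, diagnostics=diagnostics,
            config=ModelConfig(chains=self.chains, iterations=self.iterations,
                               warmup=self.warmup, seed=self.seed,
                               rhat_max=self.rhat_max))
        self.rhat_ = rhat
        self.converged_ = diagnostics["converged"]
        self.data_ = data
        self.coef_ = {name: float(draws[name].mean()) for name in COEF_NAMES}
        return self

    # ------------------------------------------------------------------
    def _run_chain(self, data: ModelData, rng, draws, chain: int, n_keep: int):
        y, X = data.y, data.X
        sp, pl, iv = data.species_idx, data.plot_idx, data.indiv_idx
        S, P, I, n = data.n_species, data.n_plots, data.n_indiv, data.n_obs
        a0, b0 = self.prior_var_shape, self.prior_var_scale
        nu0 = self.prior_cov_df
        Psi0 = self.prior_cov_scale * np.eye(7)
        prior_prec = np.eye(7) / self.prior_coef_sd ** 2

        XtX = np.zeros((S, 7, 7))
        np.add.at(XtX, sp, X[:, :, None] * X[:, None, :])
        n_plot = np.bincount(pl, minlength=P).astype(float)
        n_indiv = np.bincount(iv, minlength=I).astype(float)
        # species of each individual (a tree belongs to exactly one species)
        indiv_species = np.zeros(I, int)
        indiv_species[iv] = sp
        n_trees_sp = np.bincount(indiv_species, minlength=S).astype(float)
        indiv_plot = np.zeros(I, int)
        indiv_plot[iv] = pl
        n_trees_pl = np.bincount(indiv_plot, minlength=P).astype(float)

        # overdispersed start
        mu_B = rng.normal(0.0, 0.5, size=7)
        B = mu_B + rng.normal(0.0, 0.3, size=(S, 7))
        Sigma = 0.1 ** 2 * np.eye(7)
        gamma = np.zeros(P)
        eps = np.zeros(I)
        sig2 = float(np.var(y)) * rng.uniform(0.5, 2.0)
        sig2_p, sig2_i = 0.05, 0.1

        for it in range(self.iterations):
            Lam = np.linalg.inv(Sigma)
            # species coefficient vectors
            resid = y - gamma[pl] - eps[iv]
            Xty = np.column_stack([
                np.bincount(sp, weights=X[:, k] * resid, minlength=S)
                for k in range(7)])
            prior_mean_term = Lam @ mu_B
            for s in range(S):
                prec = XtX[s] / sig2 + Lam
                L = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, Xty[s] / sig2 + prior_mean_term)
                B[s] = mean + np.linalg.solve(L.T, rng.standard_normal(7))
            # community means
            prec = S * Lam + prior_prec
            mean = np.linalg.solve(prec, Lam @ B.sum(axis=0))
            L = np.linalg.cholesky(prec)
            mu_B = mean + np.linalg.solve(L.T, rng.standard_normal(7))
            # species covariance
            dev = B - mu_B
            Sigma = stats.invwishart.rvs(df=nu0 + S, scale=Psi0 + dev.T @ dev,
                                         random_state=rng)
            # group intercepts
            fixed = np.einsum("nk,nk->n", X, B[sp])
            r = y - fixed - eps[iv]
            var = 1.0 / (n_plot / sig2 + 1.0 / sig2_p)
            mean = var * np.bincount(pl, weights=r, minlength=P) / sig2
            gamma = mean + np.sqrt(var) * rng.standard_normal(P)
            sig2_p = stats.invgamma.rvs(a0 + P / 2.0,
                                        scale=b0 + 0.5 * np.sum(gamma ** 2),
                                        random_state=rng)
            r = y - fixed - gamma[pl]
            var = 1.0 / (n_indiv / sig2 + 1.0 / sig2_i)
            mean = var * np.bincount(iv, weights=r, minlength=I) / sig2
            eps = mean + np.sqrt(var) * rng.standard_normal(I)
            sig2_i = stats.invgamma.rvs(a0 + I / 2.0,
                                        scale=b0 + 0.5 * np.sum(eps ** 2),
                                        random_state=rng)
            # translation moves along the flat intercept directions.  The
            # likelihood is unchanged when a species' intercept B[s, 0]
            # gains delta_s while the individual effects of its trees lose
            # it, or when every B[:, 0] gains delta while the plot
            # intercepts lose it; each delta has a Gaussian full
            # conditional from the priors, and sampling these shifts
            # decouples the otherwise near-unidentified intercept split.
            dev = B - mu_B
            eps_sum_sp = np.bincount(indiv_species, weights=eps, minlength=S)
            A_sp = n_trees_sp / sig2_i + Lam[0, 0]
            lin_sp = eps_sum_sp / sig2_i - dev @ Lam[0]
            delta_sp = lin_sp / A_sp + rng.standard_normal(S) / np.sqrt(A_sp)
            eps -= delta_sp[indiv_species]
            B[:, 0] += delta_sp
            # three-way shift: plot intercepts vs (species intercepts and
            # their community mean together), resisted only by the priors
            # on gamma and on the community intercept
            A = P / sig2_p + 1.0 / self.prior_coef_sd ** 2
            lin = gamma.sum() / sig2_p - mu_B[0] / self.prior_coef_sd ** 2
            delta = lin / A + rng.standard_normal() / np.sqrt(A)
            gamma -= delta
            B[:, 0] += delta
            mu_B[0] += delta
            # and per plot between its intercept and its trees' effects
            eps_sum_pl = np.bincount(indiv_plot, weights=eps, minlength=P)
            A_pl = 1.0 / sig2_p + n_trees_pl / sig2_i
            lin_pl = -gamma / sig2_p + eps_sum_pl / sig2_i
            delta_pl = lin_pl / A_pl + rng.standard_normal(P) / np.sqrt(A_pl)
            gamma += delta_pl
            eps -= delta_pl[indiv_plot]
            # residual variance
            fixed = np.einsum("nk,nk->n", X, B[sp])
            r = y - fixed - gamma[pl] - eps[iv]
            sig2 = stats.invgamma.rvs(a0 + n / 2.0,
                                      scale=b0 + 0.5 * np.sum(r ** 2),
                                      random_state=rng)
            k = it - self.warmup
            if k >= 0:
                for j, name in enumerate(COEF_NAMES):
                    draws[name][chain, k] = mu_B[j]
                draws["sigma"][chain, k] = np.sqrt(sig2)
                draws["sigma_plot"][chain, k] = np.sqrt(sig2_p)
                draws["sigma_indiv"][chain, k] = np.sqrt(sig2_i)
                draws["species_coefs"][chain, k] = B
                draws["Sigma"][chain, k] = Sigma
                draws["gamma"][chain, k] = gamma
                if self.store_epsilon:
                    draws["epsilon"][chain, k] = eps

    # ------------------------------------------------------------------
    def _compute_rhat(self, draws) -> dict:
        import arviz as az
        scalars = {name: draws[name] for name in
                   (*COEF_NAMES, "sigma", "sigma_plot", "sigma_indiv")}
        ds = az.from_dict(posterior=scalars)
        rh = az.rhat(ds)
        return {name: float(rh[name].values) for name in scalars}

    def sample_prior(self, n_draws: int = 1000, seed: int = 0) -> pd.DataFrame:
        """Community-coefficient draws from the prior (no likelihood)."""
        rng = np.random.default_rng(seed)
        z = rng.normal(0.0, self.prior_coef_sd, size=(n_draws, 7))
        return pd.DataFrame(z, columns=list(COEF_NAMES))

    def predict(self, X) -> np.ndarray:
        """Posterior-mean expected response for new design rows.

        Species unseen in fitting fall back on the community coefficients;
        known plots contribute their mean intercept; individual intercepts
        are marginalised (zero).
        """
        if not hasattr(self, "posterior_"):
            raise ValueError("model is not fitted")
        data = self._as_data(X.assign(response=0.0) if "response" not in X else X,
                             None) if not isinstance(X, ModelData) else X
        post = self.posterior_
        B_mean = post.flat("species_coefs").mean(axis=0)
        mu_mean = np.array([post.flat(n).mean() for n in COEF_NAMES])
        gamma_mean = post.flat("gamma").mean(axis=0)
        sp_map = {s: i for i, s in enumerate(post.species_levels)}
        pl_map = {p: i for i, p in enumerate(post.plot_levels)}
        frame = data.frame
        coefs = np.array([B_mean[sp_map[s]] if s in sp_map else mu_mean
                          for s in frame["species_id"]])
        gam = np.array([gamma_mean[pl_map[p]] if p in pl_map else 0.0
                        for p in frame["plot_id"]])
        return np.einsum("nk,nk->n", data.X, coefs) + gam


def fit_model(data: ModelData, config: ModelConfig = ModelConfig(),
              **prior_overrides) -> PosteriorFit:
    """Fit one grid configuration and return its posterior."""
    est = HierarchicalGrowthModel(chains=config.chains,
                                  iterations=config.iterations,
                                  warmup=config.warmup, seed=config.seed,
                                  rhat_max=config.rhat_max, **prior_overrides)
    est.fit(data)
    fit = est.posterior_
    fit.config = config
    return fit
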