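"""Posterior summaries, effect classification and diagnostic checks.

Effects are summarised by the posterior median and highest posterior
density intervals (HPDI, the shortest contiguous interval holding the
requested mass).  A community slope is a *clear* effect when its 95% HPDI
excludes zero and a *trend* when only its 90% HPDI does.  Goodness of fit
is a Bayesian conditional/marginal R-squared; species deviations from the
community response, index cross-correlations and a Moran's I residual
check mirror the standard battery of sanity checks for neighbourhood
growth models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import COEF_NAMES, ModelData, PosteriorFit
from .neighbourhood import TRAITS

__all__ = [
    "EffectSummary",
    "hpdi",
    "classify_effect",
    "bayes_r2",
    "species_deviation",
    "diagnostic_correlations",
    "residual_spatial_check",
    "posterior_mean_residuals",
]


def hpdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    x = np.sort(np.asarray(draws, float).ravel())
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least two finite draws")
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


@dataclass(frozen=True)
class EffectSummary:
    """Median, 95%/90% HPDIs and the sign classification of one parameter."""

    parameter: str
    median: float
    hpdi95: tuple[float, float]
    hpdi90: tuple[float, float]
    classification: str  # clear_positive | clear_negative | trend_positive | trend_negative | unclear


def classify_effect(draws, parameter: str = "", *, clear_mass: float = 0.95,
                    trend_mass: float = 0.90) -> EffectSummary:
    """Hierarchical sign rule: clear if the 95% HPDI excludes zero, else a
    trend if the 90% HPDI does, else unclear."""
    lo95, hi95 = hpdi(draws, clear_mass)
    lo90, hi90 = hpdi(draws, trend_mass)
    if lo95 > 0:
        label = "clear_positive"
    elif hi95 < 0:
        label = "clear_negative"
    elif lo90 > 0:
        label = "trend_positive"
    elif hi90 < 0:
        label = "trend_negative"
    else:
        label = "unclear"
    return EffectSummary(parameter=parameter,
                         median=float(np.median(draws)),
                         hpdi95=(lo95, hi95), hpdi90=(lo90, hi90),
                         classification=label)


def summarize_community(fit: PosteriorFit) -> pd.DataFrame:
    """Effect summaries for the seven community-level parameters."""
    rows = []
    for name in COEF_NAMES:
        s = classify_effect(fit.flat(name), name)
        rows.append({"parameter": name, "median": s.median,
                     "hpdi95_lo": s.hpdi95[0], "hpdi95_hi": s.hpdi95[1],
                     "hpdi90_lo": s.hpdi90[0], "hpdi90_hi": s.hpdi90[1],
                     "classification": s.classification})
    return pd.DataFrame(rows)


def bayes_r2(fit: PosteriorFit, data: ModelData, mode: str = "conditional"
             ) -> np.ndarray:
    """Per-draw Bayesian R-squared.

    Conditional predictions include the plot and individual intercepts and
    the denominator adds only the residual variance; marginal predictions
    drop the group terms, whose variances join the residual variance in
    the denominator.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError("mode must be 'conditional' or 'marginal'")
    B = fit.flat("species_coefs")          # (d, S, 7)
    sigma = fit.flat("sigma")
    n_draws = B.shape[0]
    conditional = mode == "conditional"
    if conditional:
        gamma = fit.flat("gamma")
        if "epsilon" not in fit.draws:
            raise ValueError("fit lacks stored individual intercepts "
                             "(store_epsilon=False)")
        eps = fit.draws["epsilon"].reshape(n_draws, -1)
        extra = np.zeros(n_draws)
    else:
        extra = fit.flat("sigma_plot") ** 2 + fit.flat("sigma_indiv") ** 2
    var_pred = np.empty(n_draws)
    # chunk over draws: pred is (chunk, n_obs), built species-block-wise
    groups = [np.flatnonzero(data.species_idx == s) for s in range(data.n_species)]
    for start in range(0, n_draws, 500):
        sl = slice(start, min(start + 500, n_draws))
        pred = np.empty((sl.stop - sl.start, data.n_obs))
        for s, idx in enumerate(groups):
            if idx.size:
                pred[:, idx] = B[sl, s, :] @ data.X[idx].T
        if conditional:
            pred += gamma[sl][:, data.plot_idx]
            pred += eps[sl].astype(float)[:, data.indiv_idx]
        var_pred[sl] = pred.var(axis=1, ddof=0)
    denom = var_pred + extra + sigma ** 2
    if np.all(denom == 0):
        raise ValueError("zero total variance")
    return var_pred / denom


def species_deviation(fit: PosteriorFit, mass: float = 0.95) -> pd.DataFrame:
    """Species-minus-community coefficient contrasts and their HPDI flags.

    A species deviates on a parameter when the HPDI of (species
    coefficient - community coefficient) excludes zero.
    """
    B = fit.flat("species_coefs")                      # (d, S, 7)
    community = np.stack([fit.flat(n) for n in COEF_NAMES], axis=1)  # (d, 7)
    dev = B - community[:, None, :]
    rows = []
    for s, species in enumerate(fit.species_levels):
        for j, name in enumerate(COEF_NAMES):
            lo, hi = hpdi(dev[:, s, j], mass)
            rows.append({"species_id": species, "parameter": name,
                         "median": float(np.median(dev[:, s, j])),
                         "hpdi_lo": lo, "hpdi_hi": hi,
                         "deviates": bool(lo > 0 or hi < 0)})
    return pd.DataFrame(rows)


def _pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def diagnostic_correlations(index_sets: pd.DataFrame,
                            traits: pd.DataFrame | None = None,
                            fits: dict | None = None) -> dict:
    """The standard battery of Pearson cross-correlations.

    Returns a dict with (a) NCI against every NIh/NId column, (b) each NId
    against the conspecific share of NCI, and, when trait table and fitted
    models are supplied, (c) focal species trait values against
    species-level posterior-mean responses.  Correlations with fewer than
    three complete pairs are reported as NaN.
    """
    out: dict = {}
    nci = index_sets["nci"]
    rows = []
    for trait in TRAITS:
        rows.append({"trait": trait,
                     "r_nci_nih": _pearson(nci, index_sets[f"nih_{trait}"]),
                     "r_nci_nid": _pearson(nci, index_sets[f"nid_{trait}"])})
    out["nci_vs_indices"] = pd.DataFrame(rows)

    consp = index_sets["conspecific_fraction"]
    out["nid_vs_conspecific"] = pd.DataFrame(
        [{"trait": t, "r": _pearson(index_sets[f"nid_{t}"], consp)}
         for t in TRAITS])

    if traits is not None and fits:
        rows = []
        for key, fit in fits.items():
            B_mean = fit.flat("species_coefs").mean(axis=0)  # (S, 7)
            tvals = traits.reindex(fit.species_levels)
            for j, name in enumerate(COEF_NAMES):
                for trait in TRAITS:
                    rows.append({"fit": key, "parameter": name, "trait": trait,
                                 "r": _pearson(tvals[trait], B_mean[:, j])})
        out["trait_vs_response"] = pd.DataFrame(rows)
    return out


def posterior_mean_residuals(fit: PosteriorFit, data: ModelData) -> np.ndarray:
    """Observation-level residuals against the posterior-mean conditional fit."""
    B_mean = fit.flat("species_coefs").mean(axis=0)
    gamma_mean = fit.flat("gamma").mean(axis=0)
    mu = np.einsum("nk,nk->n", data.X, B_mean[data.species_idx]) \
        + gamma_mean[data.plot_idx]
    if "epsilon" in fit.draws:
        mu = mu + fit.flat("epsilon").astype(float).mean(axis=0)[data.indiv_idx]
    return data.y - mu


def _morans_i(z: np.ndarray, W: np.ndarray) -> float:
    z = z - z.mean()
    denom = np.sum(z ** 2)
    return float(len(z) / W.sum() * (z @ W @ z) / denom)


def residual_spatial_check(points: pd.DataFrame, *, max_dist: float = 30.0,
                           n_perm: int = 999, seed: int = 0,
                           min_obs: int = 10) -> pd.DataFrame:
    """Moran's I of residuals per plot with inverse-distance weights.

    ``points`` needs columns plot_id, x_m, y_m, resid (one row per
    location; aggregate repeated observations per tree beforehand).
    Weights are 1/d for pairs closer than ``max_dist``; the p-value is a
    two-sided permutation test with ``n_perm`` seeded shuffles.  Plots
    with fewer than ``min_obs`` locations are skipped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for plot_id, sub in points.groupby("plot_id"):
        n = len(sub)
        if n < min_obs:
            continue
        xy = sub[["x_m", "y_m"]].to_numpy(float)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore"):
            W = np.where((d > 0) & (d <= max_dist), 1.0 / np.maximum(d, 1e-9), 0.0)
        np.fill_diagonal(W, 0.0)
        if W.sum() == 0:
            continue
        z = sub["resid"].to_numpy(float)
        observed = _morans_i(z, W)
        perm = np.empty(n_perm)
        for p in range(n_perm):
            perm[p] = _morans_i(rng.permutation(z), W)
        p_two = (1 + np.sum(np.abs(perm - perm.mean())
                            >= abs(observed - perm.mean()))) / (n_perm + 1)
        rows.append({"plot_id": plot_id, "n": n, "moran_i": observed,
                     "expected_i": -1.0 / (n - 1), "p_value": float(p_two)})
    return pd.DataFrame(rows)
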