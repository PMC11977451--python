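"""End-to-end orchestration: data preparation and the model grid.

A full analysis crosses the two trait-index families with the three
climate-stress variables and the nine traits — 54 model configurations —
each fitted independently.  ``prepare_inputs`` turns raw census, trait and
climate tables into the joined model inputs; ``run_grid`` fits every
configuration and collates effect summaries and R-squared into one long
table, recording failed or non-converged fits instead of aborting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimatologyScaler, interval_anomalies
from .growth import GrowthFilterConfig, compute_agr, filter_growth, \
    standardize_size, transform_response
from .model import ModelConfig, build_design, fit_model
from .neighbourhood import TRAITS, NeighbourhoodConfig, compute_indices, \
    coverage_and_filter
from .summary import bayes_r2, summarize_community

log = logging.getLogger(__name__)

__all__ = ["GridSpec", "enumerate_grid", "prepare_inputs", "run_grid"]

CLIMATE_VARS = ("T_max", "VPD", "CWD")


@dataclass(frozen=True)
class GridSpec:
    """The model grid: families x climate variables x traits."""

    index_families: tuple = ("hierarchy", "dissimilarity")
    climate_vars: tuple = CLIMATE_VARS
    traits: tuple = TRAITS
    chains: int = 4
    iterations: int = 3000
    warmup: int = 1500
    base_seed: int = 0
    rhat_max: float = 1.05

    def __post_init__(self):
        if not (self.index_families and self.climate_vars and self.traits):
            raise ValueError("grid sets must be non-empty")

    @property
    def size(self) -> int:
        return len(self.index_families) * len(self.climate_vars) * len(self.traits)


def enumerate_grid(spec: GridSpec = GridSpec()) -> list[ModelConfig]:
    """Cartesian product in stable (family, climate, trait) order.

    Each configuration gets a deterministic seed ``base_seed + position``
    so the grid is reproducible without shared sampler state.
    """
    configs = []
    i = 0
    for family in spec.index_families:
        for climate_var in spec.climate_vars:
            for trait in spec.traits:
                configs.append(ModelConfig(
                    index_family=family, climate_var=climate_var, trait=trait,
                    chains=spec.chains, iterations=spec.iterations,
                    warmup=spec.warmup, seed=spec.base_seed + i,
                    rhat_max=spec.rhat_max))
                i += 1
    return configs


def prepare_inputs(records: pd.DataFrame, traits: pd.DataFrame,
                   climate: pd.DataFrame, *,
                   filter_config: GrowthFilterConfig = GrowthFilterConfig(),
                   neigh_config: NeighbourhoodConfig = NeighbourhoodConfig(),
                   baseline: tuple[int, int] = (1991, 2021),
                   plot_side: float | None = None) -> dict:
    """From raw tables to joined model inputs.

    Computes and filters growth observations (focal-eligible trees only;
    every tree still serves as a neighbour), transforms the response,
    standardises size, derives interval anomalies for all three climate
    variables, and computes coverage-filtered neighbourhood indices at
    every interval start.
    """
    obs = compute_agr(records)
    obs = obs[obs["focal_eligible"]].reset_index(drop=True) \
        if "focal_eligible" in obs.columns else obs
    obs, rejection_report = filter_growth(obs, filter_config)
    obs, response_scaler = transform_response(obs)
    obs = standardize_size(obs)

    scaler = ClimatologyScaler(baseline=baseline).fit(climate)
    anomalies = interval_anomalies(scaler.transform(climate),
                                   sorted(obs["t_end"].unique()))

    chunks = []
    for t_start in sorted(obs["t_start"].unique()):
        at_start = records[records["census_year"] == t_start]
        idx = compute_indices(at_start, traits, neigh_config,
                              t_start=int(t_start), plot_side=plot_side)
        chunks.append(coverage_and_filter(idx, traits, neigh_config))
    index_sets = pd.concat(chunks, ignore_index=True)

    return {
        "growth_obs": obs,
        "anomalies": anomalies,
        "index_sets": index_sets,
        "rejection_report": rejection_report,
        "response_scaler": response_scaler,
        "climatology": scaler.climatology_,
    }


def run_grid(spec: GridSpec, bundle: dict, **fit_kwargs) -> dict:
    """Fit every configuration of the grid and collate the summaries.

    Returns ``effects`` (one row per community parameter per accepted
    fit), ``fits_meta`` (per-configuration convergence and R-squared) and
    the list of failed configurations.  Non-converged fits are flagged and
    excluded from ``effects``; an exception is raised only if every
    configuration fails.
    """
    effects, meta, failures, fits = [], [], [], {}
    for config in enumerate_grid(spec):
        key = (config.index_family, config.climate_var, config.trait)
        try:
            data = build_design(bundle["growth_obs"], bundle["anomalies"],
                                bundle["index_sets"], config)
            fit = fit_model(data, config, **fit_kwargs)
            r2c = float(np.median(bayes_r2(fit, data, "conditional")))
            r2m = float(np.median(bayes_r2(fit, data, "marginal")))
            meta.append({"index_family": key[0], "climate_var": key[1],
                         "trait": key[2], "n_obs": data.n_obs,
                         "converged": fit.converged,
                         "max_rhat": fit.diagnostics["max_rhat"],
                         "r2_conditional": r2c, "r2_marginal": r2m})
            if not fit.converged:
                log.warning("non-converged fit %s (max Rhat %.3f) excluded",
                            key, fit.diagnostics["max_rhat"])
                continue
            fits[key] = fit
            table = summarize_community(fit)
            table.insert(0, "index_family", key[0])
            table.insert(1, "climate_var", key[1])
            table.insert(2, "trait", key[2])
            effects.append(table)
        except Exception as err:  # noqa: BLE001 - grid must survive one bad cell
            log.error("configuration %s failed: %s", key, err)
            failures.append({"config": key, "error": str(err)})
    if not effects:
        raise RuntimeError("every grid configuration failed")
    return {
        "effects": pd.concat(effects, ignore_index=True),
        "fits_meta": pd.DataFrame(meta),
        "failures": failures,
        "fits": fits,
    }
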