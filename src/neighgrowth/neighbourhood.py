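"""Neighbourhood crowding and trait-difference indices.

For a focal tree *i* at the start of a census interval, with neighbours *j*
of species *k* within a fixed radius in the same plot:

* crowding:       NCI_i  = sum_j DBH_j^2 / d_ij                (cm^2 m^-1)
* trait hierarchy NIh_i  = sum_j w_j (trait_s - trait_k) / sum_j w_j
* dissimilarity   NId_i  = sum_j w_j |trait_s - trait_k| / sum_j w_j

with w_j = DBH_j^2 / d_ij, the neighbour's contribution to NCI.  NIh and
NId are crowding-weighted *averages* of trait differences, so they do not
grow with neighbour density.  Unmeasured neighbour species are gap-filled
with a plot- and year-specific community-weighted mean trait, and focal
trees are retained only when measured species make up at least a configured
fraction of their NCI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import KDTree

log = logging.getLogger(__name__)

#: the nine functional trait columns, water-related then carbon-use
TRAITS = ("d13C", "pi_tlp", "LSWC", "g_min", "LA", "SLA", "L_thick", "L_tough", "WSG")

__all__ = [
    "TRAITS",
    "NeighbourhoodConfig",
    "find_neighbours",
    "compute_nci",
    "compute_trait_indices",
    "gapfill_traits",
    "compute_indices",
    "coverage_and_filter",
]


@dataclass(frozen=True)
class NeighbourhoodConfig:
    radius: float = 10.0             # m, closed ball
    min_distance: float = 0.5        # m, clamp before the 1/d weight
    edge_buffer: float = 10.0        # m, focal trees closer to a border are dropped
    coverage_threshold: float = 0.75  # min fraction of NCI from measured species
    cwm_weight: str = "basal_area"   # or "stem_count"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.coverage_threshold <= 1.0:
            raise ValueError("coverage_threshold must lie in [0, 1]")
        if self.cwm_weight not in ("basal_area", "stem_count"):
            raise ValueError("cwm_weight must be 'basal_area' or 'stem_count'")


def _alive(records_t: pd.DataFrame) -> pd.DataFrame:
    return records_t[records_t["status"] == "alive"]


def find_neighbours(records_t: pd.DataFrame, focal: object,
                    config: NeighbourhoodConfig = NeighbourhoodConfig()
                    ) -> list[tuple[object, float]]:
    """All alive same-plot trees within the radius of the focal tree.

    Distances are Euclidean, clamped below at ``config.min_distance`` (the
    census coordinate precision permits coincident stems).  The ball is
    closed: a neighbour at exactly the radius is included.
    """
    alive = _alive(records_t)
    me = alive[alive["tree_id"] == focal]
    if len(me) != 1:
        raise ValueError(f"focal tree {focal!r} not alive (or duplicated) at this census")
    me = me.iloc[0]
    plot = alive[(alive["plot_id"] == me["plot_id"]) & (alive["tree_id"] != focal)]
    dx = plot["x_m"].to_numpy(float) - float(me["x_m"])
    dy = plot["y_m"].to_numpy(float) - float(me["y_m"])
    dist = np.hypot(dx, dy)
    inside = dist <= config.radius
    dist = np.maximum(dist[inside], config.min_distance)
    return list(zip(plot["tree_id"].to_numpy()[inside], dist))


def compute_nci(neighbour_dbh, neighbour_dist) -> float:
    """Crowding index sum DBH_j^2 / d_ij; an empty neighbourhood gives 0."""
    dbh = np.asarray(neighbour_dbh, float)
    dist = np.asarray(neighbour_dist, float)
    return float(np.sum(dbh ** 2 / dist)) if dbh.size else 0.0


def compute_trait_indices(focal_trait: float, neighbour_traits,
                          neighbour_dbh, neighbour_dist) -> tuple[float, float]:
    """(NIh, NId) for one focal tree and one trait; NaN when NCI is zero."""
    w = np.asarray(neighbour_dbh, float) ** 2 / np.asarray(neighbour_dist, float)
    total = w.sum()
    if not total > 0:
        return float("nan"), float("nan")
    lam = focal_trait - np.asarray(neighbour_traits, float)
    return float(np.sum(w * lam) / total), float(np.sum(w * np.abs(lam)) / total)


def gapfill_traits(traits: pd.DataFrame, records_t: pd.DataFrame, plot_id,
                   weight: str = "basal_area") -> pd.DataFrame:
    """Plot-and-year trait table with unmeasured species set to the CWM.

    Weights are the summed squared DBH (basal-area proxy) or stem count of
    each measured species' stems alive in the plot at this census.  Filled
    rows carry ``measured = False``.
    """
    stems = _alive(records_t)
    stems = stems[stems["plot_id"] == plot_id]
    measured_ids = set(traits.index[traits["measured"]])
    meas = stems[stems["species_id"].isin(measured_ids)]
    if meas.empty:
        raise ValueError(f"plot {plot_id!r}: no stems of measured species to build a CWM")
    if weight == "basal_area":
        w = (meas["dbh_cm"].astype(float) ** 2).groupby(meas["species_id"]).sum()
    else:
        w = meas.groupby("species_id").size().astype(float)
    cols = list(TRAITS)
    cwm = traits.loc[w.index, cols].mul(w, axis=0).sum() / w.sum()

    present = stems["species_id"].unique()
    out = traits.reindex(traits.index.union(present, sort=False))
    fill = out.index[~out.index.isin(measured_ids)]
    out.loc[fill, cols] = cwm[cols].to_numpy()
    out["measured"] = out.index.isin(measured_ids)
    return out


def compute_indices(records_t: pd.DataFrame, traits: pd.DataFrame,
                    config: NeighbourhoodConfig = NeighbourhoodConfig(), *,
                    t_start: int | None = None,
                    plot_side: float | None = None) -> pd.DataFrame:
    """NCI, NIh and NId (all traits) for every alive tree at one census.

    Returns one row per tree with crowding, per-trait indices, the fraction
    of NCI contributed by measured-trait species (``coverage``) and by
    conspecifics, and, when ``plot_side`` is given, the distance to the
    nearest plot border for edge filtering.  Neighbour searches never cross
    plot boundaries.
    """
    if "measured" not in traits.columns:
        traits = traits.assign(measured=True)
    alive = _alive(records_t)
    frames = []
    n_no_neighbours = 0
    for plot_id, plot in alive.groupby("plot_id"):
        filled = gapfill_traits(traits, records_t, plot_id, weight=config.cwm_weight)
        species_index = pd.Index(filled.index)
        sp_code = species_index.get_indexer(plot["species_id"])
        if (sp_code < 0).any():
            missing = sorted(set(plot["species_id"][sp_code < 0]))
            raise ValueError(f"species absent from trait table after gap-fill: {missing}")
        xy = plot[["x_m", "y_m"]].to_numpy(float)
        dbh = plot["dbh_cm"].to_numpy(float)
        n, n_sp = len(plot), len(species_index)
        tree = KDTree(xy)
        neigh_idx, neigh_dist = tree.query_radius(xy, r=config.radius,
                                                  return_distance=True)
        # per-focal accumulation of NCI weight by neighbour species
        W = np.zeros((n, n_sp))
        n_neighbours = np.zeros(n, int)
        for i in range(n):
            idx, dist = neigh_idx[i], neigh_dist[i]
            keep = idx != i
            idx, dist = idx[keep], np.maximum(dist[keep], config.min_distance)
            n_neighbours[i] = idx.size
            if idx.size:
                np.add.at(W[i], sp_code[idx], dbh[idx] ** 2 / dist)
        nci = W.sum(axis=1)
        n_no_neighbours += int((nci == 0).sum())
        measured_mask = filled["measured"].to_numpy(bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            coverage = np.where(nci > 0, W[:, measured_mask].sum(axis=1) / nci, 1.0)
            conspecific = np.where(nci > 0, W[np.arange(n), sp_code] / nci, 0.0)
        out = pd.DataFrame({
            "tree_id": plot["tree_id"].to_numpy(),
            "plot_id": plot_id,
            "species_id": plot["species_id"].to_numpy(),
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
            "nci": nci,
            "coverage": coverage,
            "conspecific_fraction": conspecific,
            "n_neighbours": n_neighbours,
        })
        for trait in TRAITS:
            tv = filled[trait].to_numpy(float)
            focal_tv = tv[sp_code]
            with np.errstate(invalid="ignore", divide="ignore"):
                nih = focal_tv - (W @ tv) / nci
                nid = np.einsum("ns,ns->n", W, np.abs(focal_tv[:, None] - tv[None, :]))
                nid = nid / nci
            nih[nci == 0] = np.nan
            nid[nci == 0] = np.nan
            out[f"nih_{trait}"] = nih
            out[f"nid_{trait}"] = nid
        if plot_side is not None:
            out["edge_dist_m"] = np.minimum(
                np.minimum(xy[:, 0], plot_side - xy[:, 0]),
                np.minimum(xy[:, 1], plot_side - xy[:, 1]),
            )
        frames.append(out)
    result = pd.concat(frames, ignore_index=True)
    if t_start is not None:
        result.insert(1, "t_start", int(t_start))
    if n_no_neighbours:
        log.info("%d trees had no neighbours; their trait indices are missing",
                 n_no_neighbours)
    return result


def coverage_and_filter(index_sets: pd.DataFrame, traits: pd.DataFrame,
                        config: NeighbourhoodConfig = NeighbourhoodConfig()
                        ) -> pd.DataFrame:
    """Focal subset: sufficient trait coverage, measured species, off-edge.

    ``index_sets`` must come from :func:`compute_indices` (with
    ``plot_side`` supplied if edge filtering is wanted).
    """
    measured_ids = set(traits.index[traits.get("measured", pd.Series(True, traits.index))])
    keep = (index_sets["coverage"] >= config.coverage_threshold) \
        & index_sets["species_id"].isin(measured_ids)
    if "edge_dist_m" in index_sets.columns:
        keep &= index_sets["edge_dist_m"] >= config.edge_buffer
    result = index_sets[keep].reset_index(drop=True)
    if result.empty:
        log.warning("coverage/edge filtering removed every focal tree")
    return result
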