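"""Crowding and trait-difference indices against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import neighgrowth as ng
from neighgrowth.neighbourhood import (TRAITS, NeighbourhoodConfig,
                                       compute_indices, compute_nci,
                                       compute_trait_indices,
                                       coverage_and_filter, find_neighbours,
                                       gapfill_traits)


def _stand(n, side=60.0, n_species=5, seed=0, plot_id="p01"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "tree_id": [f"{plot_id}_t{i}" for i in range(n)],
        "plot_id": plot_id,
        "species_id": rng.choice([f"s{k}" for k in range(n_species)], size=n),
        "x_m": rng.uniform(0, side, n),
        "y_m": rng.uniform(0, side, n),
        "census_year": 2000,
        "dbh_cm": rng.uniform(10, 60, n),
        "status": "alive",
    })


def _traits(n_species, seed=0, measured=None):
    table = ng.generate_traits(n_species, seed=seed)
    table.index = [f"s{k}" for k in range(n_species)]
    if measured is not None:
        table["measured"] = measured
    return table


def brute_force_indices(records, traits, trait, config):
    """O(n^2) recomputation of NCI/NIh/NId for every tree, per plot."""
    out = {}
    for _, focal in records.iterrows():
        same = records[(records["plot_id"] == focal["plot_id"])
                       & (records["tree_id"] != focal["tree_id"])]
        d = np.hypot(same["x_m"] - focal["x_m"], same["y_m"] - focal["y_m"])
        sel = d <= config.radius
        dist = np.maximum(d[sel], config.min_distance)
        dbh = same.loc[sel, "dbh_cm"]
        w = dbh ** 2 / dist
        nci = w.sum()
        if nci > 0:
            lam = (traits.loc[focal["species_id"], trait]
                   - traits.loc[same.loc[sel, "species_id"], trait].to_numpy())
            nih = np.sum(w.to_numpy() * lam) / nci
            nid = np.sum(w.to_numpy() * np.abs(lam)) / nci
        else:
            nih = nid = np.nan
        out[focal["tree_id"]] = (nci, nih, nid)
    return out


def test_lone_tree_has_no_neighbours_and_zero_nci():
    records = _stand(1)
    assert find_neighbours(records, "p01_t0") == []
    assert compute_nci([], []) == 0.0


def test_neighbour_at_exactly_the_radius_is_included():
    records = pd.DataFrame({
        "tree_id": ["a", "b"], "plot_id": "p01", "species_id": ["s0", "s1"],
        "x_m": [0.0, 10.0], "y_m": [0.0, 0.0], "census_year": 2000,
        "dbh_cm": [20.0, 20.0], "status": "alive",
    })
    neigh = find_neighbours(records, "a", NeighbourhoodConfig(radius=10.0))
    assert [nid for nid, _ in neigh] == ["b"]


def test_single_neighbour_nci_arithmetic():
    assert compute_nci([20.0], [5.0]) == pytest.approx(80.0)  # 400 / 5


def test_trait_index_edge_cases():
    # conspecific neighbours contribute zero trait difference
    nih, nid = compute_trait_indices(1.5, [1.5, 1.5], [20, 30], [2, 4])
    assert nih == 0.0 and nid == 0.0
    # one neighbour: the weight cancels
    nih, nid = compute_trait_indices(2.0, [1.0], [37.0], [3.3])
    assert nih == pytest.approx(1.0) and nid == pytest.approx(1.0)
    # equal weights, opposite differences
    nih, nid = compute_trait_indices(0.0, [-1.0, 1.0], [20.0, 20.0], [5.0, 5.0])
    assert nih == pytest.approx(0.0) and nid == pytest.approx(1.0)


def test_kdtree_indices_match_brute_force():
    config = NeighbourhoodConfig()
    records = _stand(500, seed=11)
    traits = _traits(5, seed=12)
    fast = compute_indices(records, traits, config).set_index("tree_id")
    oracle = brute_force_indices(records, traits, "WSG", config)
    for tree_id, (nci, nih, nid) in oracle.items():
        assert fast.loc[tree_id, "nci"] == pytest.approx(nci, rel=1e-9, abs=1e-12)
        if np.isnan(nih):
            assert np.isnan(fast.loc[tree_id, "nih_WSG"])
        else:
            assert fast.loc[tree_id, "nih_WSG"] == pytest.approx(nih, rel=1e-9, abs=1e-12)
            assert fast.loc[tree_id, "nid_WSG"] == pytest.approx(nid, rel=1e-9, abs=1e-12)


def test_triangle_inequality_and_equivariance():
    config = NeighbourhoodConfig()
    records = _stand(300, seed=21)
    traits = _traits(5, seed=22)
    idx = compute_indices(records, traits, config)
    for trait in TRAITS:
        nih = idx[f"nih_{trait}"].to_numpy()
        nid = idx[f"nid_{trait}"].to_numpy()
        ok = ~np.isnan(nih)
        assert np.all(np.abs(nih[ok]) <= nid[ok] + 1e-12)
        spread = traits[trait].max() - traits[trait].min()
        assert np.all(nid[ok] <= spread + 1e-12)
    # adding a constant to a trait leaves both indices unchanged;
    # scaling by c scales nih by c and nid by |c|
    shifted = traits.copy()
    shifted["WSG"] = shifted["WSG"] + 5.0
    scaled = traits.copy()
    scaled["WSG"] = scaled["WSG"] * -2.0
    base = compute_indices(records, traits, config)
    sh = compute_indices(records, shifted, config)
    sc = compute_indices(records, scaled, config)
    assert np.allclose(sh["nih_WSG"], base["nih_WSG"], equal_nan=True)
    assert np.allclose(sh["nid_WSG"], base["nid_WSG"], equal_nan=True)
    assert np.allclose(sc["nih_WSG"], -2.0 * base["nih_WSG"], equal_nan=True)
    assert np.allclose(sc["nid_WSG"], 2.0 * base["nid_WSG"], equal_nan=True)


def test_trait_indices_invariant_to_neighbour_duplication():
    """NIh/NId are weighted means: duplicating every neighbour (so NCI
    doubles) leaves them unchanged — they do not scale with density."""
    rng = np.random.default_rng(31)
    n = 40
    neigh_traits = rng.normal(0.6, 0.1, n)
    dbh = rng.uniform(10, 50, n)
    dist = rng.uniform(0.5, 10.0, n)
    nih, nid = compute_trait_indices(0.7, neigh_traits, dbh, dist)
    nih2, nid2 = compute_trait_indices(0.7, np.tile(neigh_traits, 2),
                                       np.tile(dbh, 2), np.tile(dist, 2))
    assert nih2 == pytest.approx(nih, rel=1e-12)
    assert nid2 == pytest.approx(nid, rel=1e-12)
    assert compute_nci(np.tile(dbh, 2), np.tile(dist, 2)) == pytest.approx(
        2 * compute_nci(dbh, dist), rel=1e-12)


def test_gapfill_uses_basal_area_weighted_community_mean():
    records = pd.DataFrame({
        "tree_id": list("abcde"), "plot_id": "p01",
        "species_id": ["s0", "s0", "s1", "s1", "s2"],
        "x_m": np.arange(5.0), "y_m": 0.0, "census_year": 2000,
        "dbh_cm": [10.0, 20.0, 30.0, 40.0, 25.0], "status": "alive",
    })
    traits = _traits(3, measured=[True, True, False])
    filled = gapfill_traits(traits, records, "p01")
    # hand-computed CWM: weights sum(DBH^2) -> s0: 500, s1: 2500
    for trait in TRAITS:
        expected = (500 * traits.loc["s0", trait] + 2500 * traits.loc["s1", trait]) / 3000
        assert filled.loc["s2", trait] == pytest.approx(expected)
    assert not filled.loc["s2", "measured"]
    # equal basal area, traits 1 and 3 -> filled value 2
    records2 = records.copy()
    records2["dbh_cm"] = [10.0, 20.0, 10.0, 20.0, 5.0]
    traits2 = traits.copy()
    traits2.loc["s0", "WSG"] = 1.0
    traits2.loc["s1", "WSG"] = 3.0
    assert gapfill_traits(traits2, records2, "p01").loc["s2", "WSG"] == pytest.approx(2.0)
    # a plot with a single measured species copies that species' traits
    only = records[records["species_id"].isin(["s0", "s2"])]
    filled_one = gapfill_traits(traits, only, "p01")
    assert filled_one.loc["s2", "WSG"] == pytest.approx(traits.loc["s0", "WSG"])


def test_coverage_threshold_and_edge_filtering():
    traits = _traits(2, measured=[True, False])
    idx = pd.DataFrame({
        "tree_id": ["a", "b", "c", "d"],
        "species_id": ["s0"] * 4,
        "coverage": [1.0, 0.8, 0.74, 0.5],
        "edge_dist_m": [15.0, 15.0, 15.0, 15.0],
        "nci": 1.0,
    })
    kept = coverage_and_filter(idx, traits, NeighbourhoodConfig())
    assert list(kept["tree_id"]) == ["a", "b"]
    # unmeasured focal species always dropped
    idx2 = idx.assign(species_id="s1")
    assert coverage_and_filter(idx2, traits, NeighbourhoodConfig()).empty
    # edge buffer removes border trees even at full coverage
    idx3 = idx.assign(coverage=1.0, edge_dist_m=[3.0, 12.0, 9.99, 10.0])
    kept3 = coverage_and_filter(idx3, traits, NeighbourhoodConfig())
    assert list(kept3["tree_id"]) == ["b", "d"]


def test_indices_never_cross_plot_boundaries():
    a = _stand(50, seed=41, plot_id="p01")
    b = _stand(50, seed=42, plot_id="p02")
    traits = _traits(5, seed=43)
    together = compute_indices(pd.concat([a, b], ignore_index=True), traits)
    alone = pd.concat([compute_indices(a, traits), compute_indices(b, traits)],
                      ignore_index=True)
    merged = together.merge(alone, on="tree_id", suffixes=("_j", "_s"))
    assert np.allclose(merged["nci_j"], merged["nci_s"])
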