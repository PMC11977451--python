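"""HPDI, effect classification, R-squared, deviations and spatial checks."""

import numpy as np
import pandas as pd
import pytest

import neighgrowth as ng
from neighgrowth.model import COEF_NAMES, ModelConfig, ModelData, PosteriorFit
from neighgrowth.summary import (bayes_r2, classify_effect,
                                 diagnostic_correlations, hpdi,
                                 posterior_mean_residuals,
                                 residual_spatial_check, species_deviation,
                                 summarize_community)


def brute_force_hpdi(draws, mass):
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    m = int(np.ceil(mass * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if width < best[0]:
            best = (width, (x[i], x[i + m - 1]))
    return best[1]


def test_hpdi_edge_cases_and_exhaustive_oracle():
    assert hpdi([3.0, 3.0, 3.0], 0.95) == (3.0, 3.0)
    lo, hi = hpdi(np.arange(1, 101), 0.95)
    assert hi - lo == 94  # some 95-draw window of 1..100
    rng = np.random.default_rng(0)
    for n in (10, 137, 2000):
        draws = rng.gamma(2.0, size=n)  # skewed: interval placement matters
        for mass in (0.5, 0.9, 0.95):
            assert hpdi(draws, mass) == pytest.approx(
                brute_force_hpdi(draws, mass))
    with pytest.raises(ValueError):
        hpdi(draws, 1.0)
    with pytest.raises(ValueError):
        hpdi([1.0], 0.9)


def test_hpdi_shorter_than_equal_tailed_on_bimodal_sample():
    rng = np.random.default_rng(1)
    draws = np.concatenate([rng.normal(-3, 0.3, 2000), rng.normal(3, 0.3, 8000)])
    lo, hi = hpdi(draws, 0.8)
    eq = np.quantile(draws, [0.1, 0.9])
    assert hi - lo < eq[1] - eq[0]


def test_effect_classification_covers_all_labels():
    rng = np.random.default_rng(2)
    assert classify_effect(rng.uniform(0.5, 2.0, 6000)).classification == "clear_positive"
    assert classify_effect(rng.uniform(-2.0, -0.5, 6000)).classification == "clear_negative"
    assert classify_effect(rng.normal(0, 1, 6000)).classification == "unclear"
    # mean chosen so the 95% HPDI spans zero but the 90% HPDI does not
    trend = rng.normal(1.78, 1.0, 200000)
    assert classify_effect(trend).classification == "trend_positive"
    assert classify_effect(-trend).classification == "trend_negative"
    s = classify_effect(trend)
    assert s.hpdi95[0] < 0 < s.hpdi90[0]


def _toy_fit(community, species_offsets, sigma=0.5, n_draws=400, seed=3,
             n_plots=2):
    """Assemble a PosteriorFit from explicit draw arrays (no MCMC)."""
    rng = np.random.default_rng(seed)
    n_species = len(species_offsets)
    chains, keep = 2, n_draws // 2
    base = rng.normal(0, 0.01, size=(chains, keep, 7)) + np.asarray(community)
    draws = {name: base[:, :, j] for j, name in enumerate(COEF_NAMES)}
    sp = base[:, :, None, :] + np.asarray(species_offsets)[None, None, :, :]
    draws["species_coefs"] = sp
    draws["Sigma"] = np.tile(0.02 * np.eye(7), (chains, keep, 1, 1))
    draws["sigma"] = np.full((chains, keep), sigma)
    draws["sigma_plot"] = np.full((chains, keep), 0.1)
    draws["sigma_indiv"] = np.full((chains, keep), 0.2)
    draws["gamma"] = rng.normal(0, 0.01, size=(chains, keep, n_plots))
    draws["epsilon"] = np.zeros((chains, keep, 4), dtype=np.float32)
    return PosteriorFit(draws=draws,
                        species_levels=[f"s{i}" for i in range(n_species)],
                        plot_levels=[f"p{i}" for i in range(n_plots)],
                        indiv_levels=["t0", "t1", "t2", "t3"],
                        rhat={}, diagnostics={"converged": True},
                        config=ModelConfig())


def test_species_deviation_flags_only_the_offset_species():
    offsets = np.zeros((3, 7))
    offsets[1, 4] = 1.0  # species s1 deviates on beta4 only
    fit = _toy_fit([0.0] * 7, offsets)
    dev = species_deviation(fit)
    flagged = dev[dev["deviates"]]
    assert set(zip(flagged["species_id"], flagged["parameter"])) == {("s1", "beta4")}
    # identical species and community draws: nothing flagged
    none = species_deviation(_toy_fit([0.1] * 7, np.zeros((2, 7))))
    assert not none["deviates"].any()


def test_bayes_r2_hand_fixture_and_limits():
    frame = pd.DataFrame({
        "species_id": ["s0", "s0", "s1"], "plot_id": ["p0", "p0", "p1"],
        "tree_id": ["t0", "t1", "t2"],
        "x_dbh": [1.0, -1.0, 0.5], "x_ca": 0.0, "x_nci": 0.0, "x_ni": 0.0,
        "x_ca_nci": 0.0, "x_ca_ni": 0.0, "response": [0.5, -0.5, 0.2],
    })
    frame["x_ca"] += np.array([0.01, -0.01, 0.0])  # avoid degenerate columns
    frame["x_nci"] += np.array([0.01, 0.0, -0.01])
    frame["x_ni"] += np.array([0.0, 0.01, -0.01])
    frame["x_ca_nci"] = frame["x_ca"] * frame["x_nci"]
    frame["x_ca_ni"] = frame["x_ca"] * frame["x_ni"]
    data = ModelData.from_frame(frame)
    # one effective draw: beta1 = 1, all else 0 -> pred = x_dbh
    offsets = np.zeros((2, 7))
    fit = _toy_fit([0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0], offsets, sigma=0.5,
                   seed=4)
    for key in ("gamma",):
        fit.draws[key][:] = 0.0
    for name in COEF_NAMES:
        fit.draws[name][:] = [0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0][
            COEF_NAMES.index(name)]
    fit.draws["species_coefs"][:] = np.array([0.0, 1.0, 0, 0, 0, 0, 0])
    fit.draws["epsilon"] = np.zeros((2, 200, data.n_indiv), dtype=np.float32)
    r2 = bayes_r2(fit, data, "conditional")
    var_pred = np.var([1.0, -1.0, 0.5])  # population variance of predictions
    assert r2 == pytest.approx(var_pred / (var_pred + 0.25), abs=1e-9)
    # marginal mode adds the group variances to the denominator
    r2m = bayes_r2(fit, data, "marginal")
    assert r2m == pytest.approx(var_pred / (var_pred + 0.01 + 0.04 + 0.25),
                                abs=1e-9)
    # vanishing residual scale with no group terms drives R2 to 1
    fit.draws["sigma"][:] = 1e-12
    fit.draws["sigma_plot"][:] = 0.0
    fit.draws["sigma_indiv"][:] = 0.0
    assert bayes_r2(fit, data, "conditional") == pytest.approx(1.0)
    # constant predictions give R2 = 0
    fit.draws["species_coefs"][:] = 0.0
    for name in COEF_NAMES:
        fit.draws[name][:] = 0.0
    fit.draws["sigma"][:] = 0.5
    assert bayes_r2(fit, data, "conditional") == pytest.approx(0.0)


def test_pearson_correlation_oracle_and_guards(bundle):
    rng = np.random.default_rng(5)
    x = rng.normal(size=100)
    y = 0.4 * x + rng.normal(size=100)
    r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
        np.std(x) * np.std(y))
    from neighgrowth.summary import _pearson
    assert _pearson(x, y) == pytest.approx(r_oracle, abs=1e-12)
    assert _pearson(x, x) == pytest.approx(1.0)
    assert _pearson([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0)
    assert np.isnan(_pearson([1.0, 2.0], [3.0, 4.0]))  # too few pairs

    report = diagnostic_correlations(bundle["index_sets"])
    assert set(report) >= {"nci_vs_indices", "nid_vs_conspecific"}
    assert len(report["nci_vs_indices"]) == 9
    # weighted-mean indices should not track crowding strongly
    assert report["nci_vs_indices"][["r_nci_nih", "r_nci_nid"]].abs().max().max() < 0.6


def test_moran_statistic_detects_gradient_and_respects_symmetry():
    rng = np.random.default_rng(6)
    n = 80
    pts = pd.DataFrame({"plot_id": "p01",
                        "x_m": rng.uniform(0, 100, n),
                        "y_m": rng.uniform(0, 100, n)})
    # residuals equal to the x coordinate: strong positive autocorrelation
    grad = residual_spatial_check(pts.assign(resid=pts["x_m"]), n_perm=199,
                                  seed=1)
    assert grad.loc[0, "moran_i"] > 0.2
    assert grad.loc[0, "p_value"] < 0.05
    # random residuals: inside the permutation null band
    rand = residual_spatial_check(pts.assign(resid=rng.normal(size=n)),
                                  n_perm=199, seed=2)
    assert rand.loc[0, "p_value"] > 0.05
    # reordering observations leaves the statistic unchanged
    shuffled = pts.assign(resid=pts["x_m"]).sample(frac=1, random_state=3)
    again = residual_spatial_check(shuffled, n_perm=9, seed=1)
    assert again.loc[0, "moran_i"] == pytest.approx(grad.loc[0, "moran_i"])
    # undersized plots are skipped
    assert residual_spatial_check(pts.head(5).assign(resid=1.0)).empty


def test_summaries_on_a_real_fit(fitted, sim):
    fit, data = fitted["fit"], fitted["data"]
    table = summarize_community(fit)
    assert list(table["parameter"]) == list(COEF_NAMES)
    # nesting of the 90% inside the 95% interval holds up to the draw-level
    # jitter of independent shortest-window scans
    slack = 0.02 * (table["hpdi95_hi"] - table["hpdi95_lo"])
    assert (table["hpdi95_lo"] <= table["hpdi90_lo"] + slack).all()
    assert (table["hpdi90_hi"] <= table["hpdi95_hi"] + slack).all()
    # crowding clearly negative under the default truth
    beta3 = table.set_index("parameter").loc["beta3"]
    assert beta3["classification"] == "clear_negative"
    r2c = np.median(bayes_r2(fit, data, "conditional"))
    r2m = np.median(bayes_r2(fit, data, "marginal"))
    assert 0.0 < r2m < r2c < 1.0
    resid = posterior_mean_residuals(fit, data)
    assert resid.shape == (data.n_obs,)
    assert abs(resid.mean()) < 0.1
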