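"""Regression suite: OLS/ridge, collinearity, selection, published models."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import rooteit as rt
from rooteit.phantom import NoiseModel, synth_biomass_dataset
from rooteit.stats import (
    PUBLISHED_MODELS,
    RankDeficientError,
    RegressionModel,
    backward_eliminate,
    collinearity_diagnostics,
    correlate_spectrum,
    extract_layer_features,
    fit_ols,
    fit_ridge,
    predict_published,
    select_ridge_alpha,
    validation_report,
)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def _uniform_table(value=100.0):
    recs = []
    for layer in range(3):
        for a in range(1, 9):
            for b in range(1, 9):
                recs.append((a, b, layer, 5e3, value, "difference", "s1", 0))
    return rt.ImpedanceTable(
        pd.DataFrame.from_records(recs, columns=rt.acquisition.TABLE_COLUMNS)
    )


def test_equal_impedances_give_zero_sd_features():
    ft = extract_layer_features(_uniform_table())
    row = ft.data.iloc[0]
    for li in (1, 2, 3):
        assert row[f"Znl{li}SD"] == 0.0
        assert row[f"Znl{li}m"] == pytest.approx(1.0)  # max-normalized


def test_max_normalization_is_scale_invariant():
    t1, bio = synth_biomass_dataset(n_samples=3, seed=0)
    t2 = rt.ImpedanceTable(t1.data.assign(impedance_ohm=t1.data.impedance_ohm * 7.5))
    f1 = extract_layer_features(t1, biomass=bio)
    f2 = extract_layer_features(t2, biomass=bio)
    cols = [c for c in f1.data.columns if c.startswith("Znl")]
    assert np.allclose(f1.data[cols].to_numpy(), f2.data[cols].to_numpy())


def test_features_match_direct_recomputation():
    table, bio = synth_biomass_dataset(n_samples=3, seed=4)
    ft = extract_layer_features(table, biomass=bio)
    d = table.data
    for _, row in ft.data.iterrows():
        sdf = d[d.sample_id == row.sample_id]
        scale = sdf.impedance_ohm.max()
        sub = sdf[np.isclose(sdf.frequency_hz, row.frequency_hz) & (sdf.layer == 0)]
        vals = sub.impedance_ohm.to_numpy() / scale
        assert row["Znl1m"] == pytest.approx(vals.mean())
        assert row["Znl1SD"] == pytest.approx(vals.std(ddof=0))


def test_missing_layer_raises():
    t, _ = synth_biomass_dataset(n_samples=3, seed=0)
    broken = rt.ImpedanceTable(t.data[t.data.layer != 2].reset_index(drop=True))
    with pytest.raises(ValueError, match="layer"):
        extract_layer_features(broken)


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


def test_ols_exact_recovery_on_noiseless_data():
    rng = np.random.default_rng(0)
    X = rng.random((12, 2))
    y = 5.0 + X @ np.array([2.0, -3.0])
    m = fit_ols(X, y)
    assert m.intercept == pytest.approx(5.0, abs=1e-9)
    assert np.allclose(m.coefficients, [2.0, -3.0])
    assert m.r_squared == pytest.approx(1.0)
    assert m.rmse == pytest.approx(0.0, abs=1e-9)


def test_ols_constant_response():
    rng = np.random.default_rng(1)
    X = rng.random((10, 2))
    m = fit_ols(X, np.full(10, 7.0))
    assert np.allclose(m.coefficients, 0.0, atol=1e-10)
    assert m.intercept == pytest.approx(7.0)


def test_ols_rejects_rank_deficiency():
    rng = np.random.default_rng(2)
    x = rng.random(10)
    X = np.column_stack([x, 2 * x])
    with pytest.raises(RankDeficientError):
        fit_ols(X, rng.random(10))


def test_ols_adjusted_r2_below_r2_and_formula():
    rng = np.random.default_rng(3)
    X = rng.random((15, 3))
    y = X @ np.array([1.0, 0.5, -1.0]) + 0.3 * rng.standard_normal(15)
    m = fit_ols(X, y)
    n, k = 15, 3
    assert m.adj_r_squared <= m.r_squared
    assert m.adj_r_squared == pytest.approx(
        1 - (1 - m.r_squared) * (n - 1) / (n - k - 1)
    )


def test_ols_coefficient_recovery_on_synthetic_datasets():
    """ln(layer-mean impedance) regressed on weight recovers the generating
    slope within twice its sampling SE in ≥ 90 of 100 seeded replicates."""
    from rooteit.phantom import BiomassRelation, layer_mean_log_sd

    rel = BiomassRelation()
    f = 5e3
    hits = 0
    for seed in range(100):
        table, bio = synth_biomass_dataset(
            n_samples=9, noise=NoiseModel(0.02, seed), seed=seed, relation=rel
        )
        d = table.data
        sub = d[np.isclose(d.frequency_hz, f) & (d.layer == 1)]
        means = sub.groupby("sample_id", sort=True).impedance_ohm.mean()
        order = [f"sample{i + 1}" for i in range(9)]
        y = np.log(means.loc[order].to_numpy())
        W = bio.weight_g.to_numpy()
        m = fit_ols(W[:, None], y)
        # sampling SE of the slope from the generator's known noise SD
        se = layer_mean_log_sd(NoiseModel(0.02, seed)) / np.sqrt(np.sum((W - W.mean()) ** 2))
        if abs(m.coefficients[0] - (-rel.b(f))) <= 2 * se:
            hits += 1
    assert hits >= 90


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------


def test_ridge_alpha_zero_equals_ols():
    rng = np.random.default_rng(5)
    X = rng.random((20, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + 0.1 * rng.standard_normal(20)
    mo = fit_ols(X, y)
    mr = fit_ridge(X, y, 0.0)
    assert np.allclose(mr.coefficients, mo.coefficients, rtol=1e-10, atol=1e-12)
    assert mr.intercept == pytest.approx(mo.intercept, rel=1e-10)


def test_ridge_handles_collinear_design():
    rng = np.random.default_rng(6)
    x = rng.random(10)
    X = np.column_stack([x, 2 * x])
    m = fit_ridge(X, 3 * x + 1.0, 1e-3)
    assert np.all(np.isfinite(m.coefficients))


def test_ridge_shrinks_to_zero():
    rng = np.random.default_rng(7)
    X = rng.random((15, 2))
    y = X @ np.array([4.0, -4.0]) + rng.standard_normal(15)
    norms = [np.linalg.norm(fit_ridge(X, y, a).coefficients) for a in (0.0, 1.0, 1e3, 1e8)]
    assert all(a >= b for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-4
    # intercept tends to the response mean as slopes vanish
    assert fit_ridge(X, y, 1e10).intercept == pytest.approx(y.mean(), rel=1e-4)


def test_ridge_matches_brute_force_objective_minimizer():
    rng = np.random.default_rng(8)
    X = rng.random((9, 2))
    y = X @ np.array([2.0, -1.0]) + 0.2 * rng.standard_normal(9)
    alpha = 0.7
    m = fit_ridge(X, y, alpha)

    def objective(params):
        w0, w = params[0], params[1:]
        return np.sum((y - w0 - X @ w) ** 2) + alpha * np.sum(w**2)

    res = scipy.optimize.minimize(objective, np.zeros(3), method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
    assert m.intercept == pytest.approx(res.x[0], abs=1e-5)
    assert np.allclose(m.coefficients, res.x[1:], atol=1e-5)


def test_gcv_alpha_selection_returns_grid_member():
    rng = np.random.default_rng(9)
    X = rng.random((15, 3))
    y = X @ np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(15)
    a = select_ridge_alpha(X, y)
    assert a > 0


# ---------------------------------------------------------------------------
# collinearity and backward elimination
# ---------------------------------------------------------------------------


def test_vif_orthogonal_features():
    n = 32
    t = np.arange(n)
    X = np.column_stack([np.sin(2 * np.pi * t / n), np.cos(2 * np.pi * t / n)])
    diag = collinearity_diagnostics(X)
    assert np.allclose(diag.VIF, 1.0, atol=1e-9)
    assert not diag.flag.any()


def test_vif_duplicated_feature_is_infinite_and_flagged():
    rng = np.random.default_rng(10)
    x = rng.random(12)
    diag = collinearity_diagnostics(np.column_stack([x, x, rng.random(12)]))
    assert np.isinf(diag.VIF.iloc[0]) or diag.VIF.iloc[0] > 1e10
    assert diag.flag.iloc[0]
    assert "x2" in diag.high_corr_with.iloc[0]


def test_vif_matches_leave_one_out_recomputation():
    rng = np.random.default_rng(11)
    X = rng.random((25, 4))
    X[:, 3] = X[:, 0] + 0.05 * rng.standard_normal(25)
    diag = collinearity_diagnostics(X)
    for j in range(4):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(25), others]), X[:, j], rcond=None
        )
        pred = np.column_stack([np.ones(25), others]) @ beta
        ss_res = np.sum((X[:, j] - pred) ** 2)
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1 - ss_res / ss_tot
        assert diag.VIF.iloc[j] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)


def test_constant_feature_reported_infinite():
    rng = np.random.default_rng(12)
    X = np.column_stack([np.ones(10), rng.random(10)])
    diag = collinearity_diagnostics(X)
    assert np.isinf(diag.VIF.iloc[0])
    assert diag.flag.iloc[0]


def test_backward_elimination_drops_noise_feature():
    dropped = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = rng.random(30)
        noise_feat = rng.random(30)
        y = 2.0 + 5.0 * x + 0.1 * rng.standard_normal(30)
        names, model = backward_eliminate(
            np.column_stack([x, noise_feat]), y, ["signal", "noise"]
        )
        if names == ["signal"]:
            dropped += 1
    assert dropped >= 95


def test_backward_elimination_keeps_all_significant_and_is_deterministic():
    rng = np.random.default_rng(13)
    X = rng.random((40, 2))
    y = X @ np.array([3.0, -2.0]) + 0.05 * rng.standard_normal(40)
    names1, m1 = backward_eliminate(X, y, ["a", "b"])
    names2, m2 = backward_eliminate(X, y, ["a", "b"])
    assert names1 == ["a", "b"] == names2
    assert np.array_equal(m1.coefficients, m2.coefficients)


def test_backward_elimination_warns_on_failed_f_test():
    rng = np.random.default_rng(14)
    X = rng.standard_normal((8, 1))
    y = rng.standard_normal(8)  # pure noise: F-test should fail
    with pytest.warns(UserWarning, match="F-test"):
        names, model = backward_eliminate(X, y, ["junk"])
    assert model.warnings_


# ---------------------------------------------------------------------------
# published models, validation, correlation
# ---------------------------------------------------------------------------


def test_published_model_intercepts():
    assert predict_published("eq1_fresh_Z", np.zeros(2)) == pytest.approx(134.398)
    assert predict_published("eq9_100kHz", np.zeros(6)) == pytest.approx(110.897)
    assert predict_published("eq2_fresh_Zn", np.zeros(2)) == pytest.approx(243.513)


def test_published_eq1_worked_example():
    # 134.398 − 0.0446·1000 + 0.03822·1000
    assert predict_published("eq1_fresh_Z", [1000.0, 1000.0]) == pytest.approx(128.018)


def test_published_model_errors():
    with pytest.raises(KeyError):
        predict_published("eq99", [0.0])
    with pytest.raises(ValueError):
        predict_published("eq1_fresh_Z", [1.0, 2.0, 3.0])


def test_published_registry_serialization_round_trip():
    for mid, model in PUBLISHED_MODELS.items():
        back = RegressionModel.from_json(model.to_json())
        assert back.intercept == model.intercept
        assert np.array_equal(back.coefficients, model.coefficients)
        assert back.feature_names == model.feature_names


def test_validation_report_examples():
    rep = validation_report([99.0, 87.0, 62.0], [102.587, 84.9, 64.68])
    assert list(rep.abs_error_pct) == [3.62, 2.41, 4.32]
    assert rep.attrs["max_error"] == 4.32
    assert rep.attrs["min_accuracy"] == pytest.approx(100 - 4.32)


def test_validation_report_perfect_and_errors():
    rep = validation_report([50.0, 80.0], [50.0, 80.0])
    assert (rep.abs_error_pct == 0).all()
    with pytest.raises(ValueError):
        validation_report([0.0], [1.0])
    with pytest.raises(ValueError):
        validation_report([1.0, 2.0], [1.0])


def test_correlate_spectrum_perfect_log_linear():
    table, bio = synth_biomass_dataset(n_samples=5, noise=NoiseModel(0.0, 0), seed=0)
    d = table.data.copy()
    d["impedance_ohm"] = np.log(d["impedance_ohm"])  # analyze on generating scale
    out = correlate_spectrum(d, bio.weight_g.to_numpy())
    assert np.allclose(out.pearson_r, -1.0, atol=1e-9)


def test_correlate_spectrum_matches_covariance_formula():
    table, bio = synth_biomass_dataset(n_samples=6, noise=NoiseModel(0.01, 1), seed=1)
    out = correlate_spectrum(table.data, bio.weight_g.to_numpy())
    d = table.data
    f = 5e3
    means = d[np.isclose(d.frequency_hz, f)].groupby("sample_id", sort=True).impedance_ohm.mean().to_numpy()
    w = bio.weight_g.to_numpy()
    r = np.mean((means - means.mean()) * (w - w.mean())) / (means.std() * w.std())
    assert out.loc[np.isclose(out.frequency_hz, f), "pearson_r"].iloc[0] == pytest.approx(r)


def test_correlate_spectrum_permutation_null():
    table, bio = synth_biomass_dataset(n_samples=9, noise=NoiseModel(0.01, 2), seed=2)
    d = table.data[np.isclose(table.data.frequency_hz, 5e3)]
    means = d.groupby("sample_id", sort=True).impedance_ohm.mean().to_numpy()
    rng = np.random.default_rng(0)
    rs = []
    for _ in range(200):
        perm = rng.permutation(bio.weight_g.to_numpy())
        rs.append(abs(np.corrcoef(means, perm)[0, 1]))
    assert np.mean(rs) < 0.5


def test_correlate_spectrum_input_validation():
    table, bio = synth_biomass_dataset(n_samples=3, seed=0)
    with pytest.raises(ValueError):
        correlate_spectrum(table.data, bio.weight_g.to_numpy()[:2])
    with pytest.raises(ValueError):
        correlate_spectrum(table.data, np.full(3, 5.0))
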