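"""Attribution chain: screen, best-subsets AIC, relative weights, partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mehg_guild import (
    MehgAttribution,
    attribute_mehg,
    best_subset_aic,
    pearson_screen,
    relative_weights,
    variance_partition,
)
from mehg_guild.attribution import adjusted_r2, aic_gaussian, log10_with_offset
from mehg_guild import synthdata as sd


# ---------------------------------------------------------------------------
# Pearson screen
# ---------------------------------------------------------------------------


def test_screen_perfect_correlation_retained():
    data = pd.DataFrame({"x": np.arange(10.0)})
    data["y"] = 2 * data["x"]
    out = pearson_screen(data, "y", ["x"]).iloc[0]
    assert out["r"] == pytest.approx(1.0)
    assert out["p"] < 1e-10 and out["retained"]


def test_screen_zero_correlation_not_retained():
    # a permutation constructed to give r = 0 exactly on small n
    data = pd.DataFrame({"x": [-1.0, 0.0, 1.0, 2.0, -2.0],
                         "y": [1.0, -2.0, 1.0, 0.0, 0.0]})
    r, _ = stats.pearsonr(data["x"], data["y"])
    assert abs(r) < 1e-12
    out = pearson_screen(data, "y", ["x"])
    assert not out.iloc[0]["retained"]


def test_screen_skips_zero_variance_column(caplog):
    data = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "z": [1, 2, 3, 4.0],
                         "y": [0.1, 0.4, 0.2, 0.9]})
    with caplog.at_level("WARNING"):
        out = pearson_screen(data, "y", ["x", "z"])
    assert list(out["factor"]) == ["z"]
    assert "zero variance" in caplog.text


def test_screen_power_matches_closed_form():
    """Retention rate at planted r=0.8, n=20, over 1000 sims, vs the Fisher-z
    closed-form power of the two-sided t test (within +-3%)."""
    n, rho, nsim = 20, 0.8, 1000
    rng = np.random.default_rng(123)
    t_crit = stats.t.ppf(0.975, n - 2)
    r_crit = t_crit / np.sqrt(t_crit**2 + n - 2)
    power = stats.norm.sf(
        (np.arctanh(r_crit) - np.arctanh(rho)) * np.sqrt(n - 3)
    )
    x = rng.normal(size=(nsim, n))
    y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=(nsim, n))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    retention = float((np.abs(r) > r_crit).mean())
    assert retention == pytest.approx(power, abs=0.03)
    # spot-check the screen itself agrees with the vectorised statistic
    frame = pd.DataFrame({"x": x[0], "y": y[0]})
    out = pearson_screen(frame, "y", ["x"]).iloc[0]
    assert out["r"] == pytest.approx(r[0])
    assert out["retained"] == (abs(r[0]) > r_crit)


# ---------------------------------------------------------------------------
# best subsets
# ---------------------------------------------------------------------------


def test_aic_formula_worked_example():
    # n=10, RSS=10, k=2 -> 10 ln(1) + 2(2+1) = 6
    assert aic_gaussian(10, 10.0, 2) == pytest.approx(6.0)


def test_best_subset_exact_fit_selects_minimal_subset():
    rng = np.random.default_rng(1)
    data = pd.DataFrame({"x1": rng.normal(size=20), "x2": rng.normal(size=20)})
    data["y"] = 3.0 * data["x1"] - 1.0
    selected, table = best_subset_aic(data, "y", ["x1", "x2"])
    assert selected == ["x1"]
    assert len(table) == 3


def test_best_subset_invariances():
    rng = np.random.default_rng(2)
    data = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
    data["y"] = data["a"] + 0.5 * data["b"] + 0.1 * rng.normal(size=30)
    sel1, _ = best_subset_aic(data, "y", ["a", "b", "c"])
    sel2, _ = best_subset_aic(data, "y", ["c", "b", "a"])
    assert set(sel1) == set(sel2)
    rescaled = data.copy()
    rescaled["a"] = 100.0 * rescaled["a"] + 7.0
    sel3, _ = best_subset_aic(rescaled, "y", ["a", "b", "c"])
    assert set(sel3) == set(sel1)


def test_best_subset_skips_collinear_subsets():
    rng = np.random.default_rng(3)
    data = pd.DataFrame({"a": rng.normal(size=25)})
    data["b"] = 2.0 * data["a"]  # exactly collinear
    data["y"] = data["a"] + 0.1 * rng.normal(size=25)
    selected, table = best_subset_aic(data, "y", ["a", "b"])
    pair_row = table[table["subset"].apply(lambda s: set(s) == {"a", "b"})]
    assert pair_row["note"].iloc[0] == "rank-deficient"
    assert selected in (["a"], ["b"])


def test_best_subset_validation():
    data = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
    with pytest.raises(ValueError):
        best_subset_aic(data, "y", [])
    with pytest.raises(ValueError):
        best_subset_aic(data, "y", ["x"], criterion="bic")
    with pytest.raises(ValueError, match="too few"):
        best_subset_aic(data, "y", ["x"])  # n=3 <= k+2


def test_best_subset_noiseless_recovery_with_redundant_candidate():
    """Generating model uses 5 of 6 screened candidates; noiseless fits tie
    across all supersets of the truth, and the fewer-predictor tie-break
    recovers exactly the true five in >=95% of 200 sims."""
    rng = np.random.default_rng(42)
    hits = 0
    nsim = 200
    beta = np.array([0.5, 0.3, -0.4, 0.4, 0.3])
    for _ in range(nsim):
        X = rng.normal(size=(20, 5))
        redundant = X @ rng.normal(size=5) + 0.5 * rng.normal(size=20)
        data = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
        data["x5"] = redundant
        data["y"] = X @ beta  # sigma = 0
        selected, _ = best_subset_aic(data, "y", list(data.columns[:-1]))
        hits += set(selected) == {f"x{i}" for i in range(5)}
    assert hits / nsim >= 0.95


# ---------------------------------------------------------------------------
# relative weights
# ---------------------------------------------------------------------------


def test_relative_weights_single_predictor_equals_r2():
    rng = np.random.default_rng(4)
    data = pd.DataFrame({"x": rng.normal(size=50)})
    data["y"] = data["x"] + rng.normal(size=50)
    w = relative_weights(data, "y", ["x"])
    assert w["weight"].iloc[0] == pytest.approx(w.attrs["rsquared"], abs=1e-12)


def test_relative_weights_orthogonal_closed_form():
    """With exactly orthogonal (centred) predictors, each weight equals the
    squared simple correlation with the response."""
    rng = np.random.default_rng(5)
    raw = rng.normal(size=(40, 3))
    q, _ = np.linalg.qr(raw - raw.mean(0))  # orthonormal, centred columns
    data = pd.DataFrame(q, columns=["a", "b", "c"])
    data["y"] = rng.normal(size=40)
    w = relative_weights(data, "y", ["a", "b", "c"]).set_index("factor")
    for col in ("a", "b", "c"):
        r, _ = stats.pearsonr(data[col], data["y"])
        assert w.loc[col, "weight"] == pytest.approx(r**2, abs=1e-9)


def test_relative_weights_sum_to_r2_and_scale_invariant():
    rng = np.random.default_rng(6)
    for _ in range(20):
        n, p = 30, 4
        data = pd.DataFrame(rng.normal(size=(n, p)), columns=list("abcd"))
        data["y"] = data[list("abcd")] @ rng.normal(size=p) + 0.5 * rng.normal(size=n)
        w = relative_weights(data, "y", list("abcd"))
        assert w["weight"].sum() == pytest.approx(w.attrs["rsquared"], abs=1e-9)
        assert w["share_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        scaled = data.copy()
        scaled["a"] = scaled["a"] * 1e3 + 5
        w2 = relative_weights(scaled, "y", list("abcd"))
        np.testing.assert_allclose(w2["weight"], w["weight"], atol=1e-9)


def test_relative_weights_rejects_rank_deficiency():
    data = pd.DataFrame({"a": [1.0, 2, 3, 4], "y": [1.0, 2, 1, 2]})
    data["b"] = 2 * data["a"]
    with pytest.raises(ValueError, match="rank-deficient"):
        relative_weights(data, "y", ["a", "b"])


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------


def test_partition_identity_and_duplicate_sets():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    data["y"] = data["a"] + data["c"] + 0.3 * rng.normal(size=30)
    part = variance_partition(data, "y", ["a", "b"], ["c", "d"])
    assert part["unique1"] + part["unique2"] + part["shared"] == pytest.approx(
        part["adj_r2_union"], abs=1e-12
    )
    dup = variance_partition(data, "y", ["a", "b"], ["a", "b"])
    assert dup["unique1"] == pytest.approx(0.0, abs=1e-12)
    assert dup["unique2"] == pytest.approx(0.0, abs=1e-12)
    assert dup["shared"] == pytest.approx(dup["adj_r2_set1"], abs=1e-12)


def test_partition_orthogonal_sets_share_nothing():
    """y depends on set1 only; with independent sets at n=500 the shared and
    unique2 fractions vanish (|.| < 0.02 on average over 100 reps)."""
    rng = np.random.default_rng(8)
    shared_vals, unique2_vals = [], []
    for _ in range(100):
        data = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        data["y"] = data["a"] + 0.5 * data["b"] + 0.5 * rng.normal(size=500)
        part = variance_partition(data, "y", ["a", "b"], ["c", "d"])
        shared_vals.append(part["shared"])
        unique2_vals.append(part["unique2"])
    assert abs(np.mean(shared_vals)) < 0.02
    assert abs(np.mean(unique2_vals)) < 0.02


def test_partition_validation():
    data = pd.DataFrame({"a": [1.0, 2, 3], "y": [1.0, 2, 3]})
    with pytest.raises(ValueError):
        variance_partition(data, "y", [], ["a"])
    with pytest.raises(ValueError):
        adjusted_r2(data, "y", ["a", "a", "a"])  # n <= p + 1


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


def test_model_end_to_end_on_generated_sites():
    table, beta = sd.generate_sites(sd.SiteModelSpec(seed=0))
    fit = MehgAttribution(
        table,
        microbial=list(sd.SITE_FACTORS[:3]),
        environmental=["TC", "Fe2_Fe3"],
    ).fit()
    screened = fit.screened.set_index("factor")
    for factor in sd.SITE_FACTORS:
        assert np.sign(screened.loc[factor, "r"]) == np.sign(beta[factor])
    assert fit.selected, "some subset must be selected"
    assert fit.rsquared is not None and 0 < fit.rsquared <= 1
    if fit.relative_weights is not None:
        assert fit.relative_weights["weight"].sum() == pytest.approx(
            fit.rsquared, abs=1e-9
        )
    text = fit.summary()
    assert "Pearson screen" in text and "selected subset" in text


def test_null_factor_excluded_at_alpha_rate():
    """A beta=0 factor passes the screen at about the nominal alpha."""
    rng = np.random.default_rng(9)
    n, nsim, alpha = 20, 400, 0.05
    false_pos = 0
    for _ in range(nsim):
        data = pd.DataFrame({"null": rng.normal(size=n),
                             "y": rng.normal(size=n)})
        out = pearson_screen(data, "y", ["null"], alpha=alpha)
        false_pos += int(out.iloc[0]["retained"])
    assert false_pos / nsim == pytest.approx(alpha, abs=0.025)


def test_empty_microbial_set_errors_but_earlier_stages_returned():
    rng = np.random.default_rng(10)
    data = pd.DataFrame({"env1": rng.normal(size=20)})
    data["log10_MeHg"] = 2 * data["env1"] + 0.1 * rng.normal(size=20)
    data["mic1"] = rng.normal(size=20)  # unrelated: fails the screen
    fit = attribute_mehg(
        data, {"microbial": ["mic1"], "environmental": ["env1"]}
    )
    assert fit.selected == ["env1"]
    assert fit.partition is None
    assert "variance_partition" in fit.errors
    assert fit.rsquared is not None


def test_model_validation_and_from_raw():
    with pytest.raises(ValueError, match="3 sites"):
        MehgAttribution(
            pd.DataFrame({"log10_MeHg": [1.0, 2.0], "a": [1.0, 2.0]}),
            microbial=["a"], environmental=[],
        )
    raw = pd.DataFrame(
        {"MeHg": [10.0, 100.0, 50.0, 20.0], "abund": [0.0, 0.1, 0.2, 0.3],
         "TC": [1.0, 2.0, 3.0, 4.0]}
    )
    model = MehgAttribution.from_raw(raw, microbial=["abund"],
                                     environmental=["TC"])
    assert model.transform_flags["abund"] is True  # zero was offset
    assert model.transform_flags["TC"] is False
    # the zero became half the smallest positive value
    assert model.data["abund"].iloc[0] == pytest.approx(np.log10(0.05))
    with pytest.raises(ValueError):
        log10_with_offset(pd.Series([-1.0, 2.0], name="bad"))
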