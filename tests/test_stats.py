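"""Group tests, correlations, adjustment, OLS, and the model ledger."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wmhtremor.stats import (
    bonferroni,
    chi_square,
    mann_whitney_u,
    ols_fit,
    pearson,
    residualize,
    run_model_ledger,
    spearman,
    two_sample_t,
    two_sample_t_from_data,
    vascular_burden_score,
)
from wmhtremor.synthetic import generate_cohort

# --- t-tests ----------------------------------------------------------------


def pooled_t_oracle(x, y):
    """Textbook pooled two-sample t-test, written independently."""
    n1, n2 = len(x), len(y)
    v1 = sum((xi - sum(x) / n1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - sum(y) / n2) ** 2 for yi in y) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    t = (sum(x) / n1 - sum(y) / n2) / (sp * math.sqrt(1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def test_raw_data_matches_textbook_formula():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = two_sample_t_from_data(x, y)
    t, p = pooled_t_oracle(x, y)
    assert res.statistic == pytest.approx(t, abs=1e-12)
    assert res.p == pytest.approx(p, abs=1e-12)


def test_summary_and_raw_paths_agree(rng):
    x = rng.normal(0, 1, 20)
    y = rng.normal(0.5, 1.2, 25)
    for variant in ("pooled", "welch"):
        raw = two_sample_t_from_data(x, y, variant)
        summ = two_sample_t(
            x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size, variant
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)


def test_identical_groups_give_p_one():
    res = two_sample_t(5.0, 0.0, 10, 5.0, 0.0, 10)
    assert (res.statistic, res.p) == (0.0, 1.0)


def test_zero_variance_unequal_means_flagged_degenerate():
    res = two_sample_t(5.0, 0.0, 10, 6.0, 0.0, 10)
    assert res.p == 0.0 and res.degenerate


# --- Mann-Whitney -----------------------------------------------------------


def mw_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled data."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    obs = u_stat(x, y)
    center = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - center) >= abs(obs - center) - 1e-12:
            count += 1
    return count / total


def test_mw_complete_separation():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0  # U counts x-wins


def test_mw_null_center(rng):
    us = [
        mann_whitney_u(s[:15], s[15:]).statistic
        for s in (rng.normal(size=30) for _ in range(200))
    ]
    assert np.mean(us) == pytest.approx(15 * 15 / 2, rel=0.1)


def test_mw_exact_p_matches_enumeration(rng):
    for _ in range(10):
        x = rng.permutation(np.arange(0, 20.0))[:5]  # distinct values, no ties
        y = rng.permutation(np.arange(20.0, 40.0))[:5] - rng.uniform(0, 25)
        res = mann_whitney_u(x, y)
        assert "exact" in res.method
        assert res.p == pytest.approx(mw_enumeration_oracle(list(x), list(y)), abs=1e-9)


# --- chi-square -------------------------------------------------------------


def test_chi_square_proportional_table_is_null():
    res = chi_square([[10, 20], [20, 40]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_chi_square_diagonal_table_hand_computed():
    res = chi_square([[10, 0], [0, 10]])
    assert res.statistic == pytest.approx(20.0)
    assert res.df == 1


def test_chi_square_df_2x3():
    assert chi_square([[5, 5, 5], [5, 5, 6]]).df == 2


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(ValueError, match="marginal"):
        chi_square([[0, 0], [5, 5]])


# --- correlations -----------------------------------------------------------


def test_pearson_perfect_linear():
    x = np.arange(10.0)
    assert pearson(x, 2 * x + 1).coefficient == pytest.approx(1.0)


def test_spearman_monotone_invariance(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    base = spearman(x, y).coefficient
    assert spearman(np.exp(x), y).coefficient == pytest.approx(base, abs=1e-12)
    assert spearman(x, y**3).coefficient == pytest.approx(base, abs=1e-12)


def test_spearman_matches_rank_then_pearson(rng):
    """rho equals Pearson on midranks (brute-force oracle, n=6)."""
    for _ in range(20):
        x = rng.integers(0, 5, 6).astype(float)
        y = rng.integers(0, 5, 6).astype(float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        if np.std(rx) == 0 or np.std(ry) == 0:
            continue
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).coefficient == pytest.approx(expected, abs=1e-12)


def test_zero_variance_correlation_rejected():
    with pytest.raises(ValueError, match="variance"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# --- residualization --------------------------------------------------------


def test_exactly_linear_outcome_residualizes_to_zero():
    c = np.arange(10.0)
    assert np.allclose(residualize(3 * c - 2, c), 0.0, atol=1e-10)


def test_residuals_orthogonal_to_covariate(rng):
    y = rng.normal(size=50)
    c = rng.normal(size=50)
    resid = residualize(y, c)
    assert abs(np.corrcoef(resid, c)[0, 1]) < 1e-10
    assert abs(resid.mean()) < 1e-10


def test_constant_covariate_mean_centers_with_warning():
    y = np.array([1.0, 2.0, 3.0, 6.0])
    with pytest.warns(UserWarning, match="constant covariate"):
        out = residualize(y, np.ones(4))
    assert np.allclose(out, y - y.mean())


def test_frisch_waugh_lovell(rng):
    """Residualize-then-fit reproduces the two-predictor partial coefficient."""
    n = 60
    c = rng.normal(size=n)
    x = 0.5 * c + rng.normal(size=n)
    y = 1.5 * x - 0.7 * c + rng.normal(size=n)
    joint = ols_fit(pd.DataFrame({"x": x, "c": c}), y)
    adj_x = residualize(x, c)
    via_adj = ols_fit(pd.DataFrame({"adj_x": adj_x, "c": c}), y)
    assert via_adj.coefficients["adj_x"] == pytest.approx(joint.coefficients["x"], abs=1e-8)


# --- OLS --------------------------------------------------------------------


def normal_equations_oracle(X, y):
    """Independent least-squares solve via the normal equations."""
    Xc = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


def test_exact_linear_outcome():
    x = np.arange(10.0)
    res = ols_fit(pd.DataFrame({"x": x}), 2 * x)
    assert res.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
    assert res.r_squared == pytest.approx(1.0)


def test_ols_matches_normal_equations(rng):
    for _ in range(25):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        res = ols_fit(pd.DataFrame(X, columns=list("abc")), y)
        expected = normal_equations_oracle(X, y)
        got = np.array([res.coefficients["const"]] + [res.coefficients[c] for c in "abc"])
        assert np.allclose(got, expected, rtol=1e-8)


def test_adjusted_r2_bounded_by_r2(rng):
    for _ in range(10):
        X = rng.normal(size=(15, 2))
        res = ols_fit(pd.DataFrame(X, columns=["a", "b"]), rng.normal(size=15))
        assert res.adjusted_r_squared <= res.r_squared
        assert 0.0 <= res.model_p <= 1.0


def test_singular_design_names_collinear_columns(rng):
    x = rng.normal(size=20)
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        ols_fit(pd.DataFrame({"a": x, "b": 2 * x}), rng.normal(size=20))


def test_standardized_beta_definition(rng):
    x = rng.normal(size=40)
    y = 0.8 * x + rng.normal(size=40)
    res = ols_fit(pd.DataFrame({"x": x}), y)
    expected = res.coefficients["x"] * np.std(x, ddof=1) / np.std(y, ddof=1)
    assert res.standardized_beta["x"] == pytest.approx(expected, abs=1e-12)
    # simple regression: standardized beta equals Pearson r
    assert res.standardized_beta["x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


# --- Bonferroni and vascular burden ----------------------------------------


@pytest.mark.parametrize("alpha, m, expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
def test_bonferroni_values(alpha, m, expected):
    assert bonferroni(alpha, m) == pytest.approx(expected)


def test_bonferroni_27_rois_rounds_to_0019():
    assert round(bonferroni(0.05, 27), 4) == 0.0019


def test_vascular_burden_is_component_sum():
    assert vascular_burden_score(1, 1, 1, 1, 1) == 5
    assert vascular_burden_score(0, 0, 0, 0, 0) == 0
    assert vascular_burden_score(1, 0, 1, 0, 0) == 2
    with pytest.raises(ValueError):
        vascular_burden_score(2, 0, 0, 0, 0)


# --- model ledger -----------------------------------------------------------


def test_ledger_row_count_and_bonferroni(table_only_config):
    _, table = generate_cohort(table_only_config)
    ledger = run_model_ledger(table)
    m = ledger.n_rois
    assert m == 4
    for outcome in ("tetras_part2", "mean_frequency"):
        assert (ledger.table.outcome == outcome).sum() == 2 + m
    assert ledger.bonferroni_level == pytest.approx(0.05 / m)
    assert set(ledger.table.model) == {"1", "2"} | {f"3.{i}" for i in range(1, m + 1)}


def test_ledger_null_wmh_effect_adds_no_r2(table_only_config):
    """With no planted WMH effect, Model 2 gains ~2% R² over Model 1 (chance)."""
    cfg = dataclasses.replace(
        table_only_config, wmh_tetras_corr=0.0, wmh_freq_corr=0.0, wmh_age_corr=0.0
    )
    gains = []
    for seed in range(60):
        _, t = generate_cohort(dataclasses.replace(cfg, seed=seed))
        led = run_model_ledger(t).table
        rows = led[led.outcome == "tetras_part2"].set_index("model")
        gains.append(rows.loc["2", "r_squared"] - rows.loc["1", "r_squared"])
    # E[R² gain from one noise predictor] = 1/(n-1) ~ 0.022 at n=47
    assert np.mean(gains) == pytest.approx(1 / 46, abs=0.02)


def test_ledger_missing_columns_rejected(table_only_config):
    _, table = generate_cohort(table_only_config)
    with pytest.raises(KeyError, match="missing"):
        run_model_ledger(table.drop(columns=["total_wmh_mm3"]))


def test_all_ledger_pvalues_valid(table_only_config):
    _, table = generate_cohort(table_only_config)
    led = run_model_ledger(table).table
    assert led.model_p.between(0, 1).all()
    assert (led.adjusted_r_squared <= led.r_squared + 1e-12).all()
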