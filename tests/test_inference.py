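"""GLM contrasts, BH-FDR adjustment, chi-squared mortality tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from matefit.errors import DegenerateGroupError, DesignError
from matefit.inference import (
    bh_adjust,
    chisq_mortality,
    fit_interaction_glm,
    fit_treatment_glm,
)


# ------------------------------------------------------------------------- BH


def test_bh_single_p():
    assert bh_adjust([0.04]) == pytest.approx([0.04])


def test_bh_hand_example():
    assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])


def test_bh_ties_stay_equal():
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


def test_bh_preserves_input_order():
    out = bh_adjust([0.04, 0.01, 0.02])
    assert out == pytest.approx([0.04, 0.03, 0.03])


def test_bh_domain_error():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@given(
    pvals=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=30)
)
@settings(max_examples=80)
def test_bh_properties(pvals):
    p = np.asarray(pvals)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    # rank monotone: smaller raw p never gets a larger adjusted p
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_matches_statsmodels():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=25)
    from statsmodels.stats.multitest import multipletests

    expected = multipletests(p, method="fdr_bh")[1]
    assert bh_adjust(p) == pytest.approx(expected)


# ------------------------------------------------------------------ chi-squared


def test_chisq_homogeneous_table():
    res = chisq_mortality([[10, 10], [10, 10]], yates=True)
    assert res.chi2 == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)
    assert res.df == 1
    assert res.df_residual == 39


def test_chisq_yates_shrinks_statistic():
    rng = np.random.default_rng(5)
    for _ in range(30):
        table = rng.integers(1, 40, size=(2, 2))
        corrected = chisq_mortality(table, yates=True)
        uncorrected = chisq_mortality(table, yates=False)
        assert corrected.chi2 <= uncorrected.chi2 + 1e-12


def test_chisq_brute_force_oracle():
    table = np.array([[20, 5], [10, 15]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    plain = ((table - expected) ** 2 / expected).sum()
    yates = ((np.abs(table - expected) - 0.5).clip(min=0) ** 2 / expected).sum()
    assert chisq_mortality(table, yates=False).chi2 == pytest.approx(plain)
    assert chisq_mortality(table, yates=True).chi2 == pytest.approx(yates)


def test_chisq_2xk_no_correction_applied():
    res = chisq_mortality([[5, 10, 20], [30, 25, 15]], yates=True)
    assert res.df == 2
    assert not res.yates  # Yates applies to 2x2 only


def test_chisq_p_decreases_with_imbalance():
    balanced = chisq_mortality([[12, 12], [12, 12]], yates=False)
    skewed = chisq_mortality([[20, 4], [4, 20]], yates=False)  # same margins
    assert skewed.p < balanced.p


def test_chisq_degenerate_and_invalid():
    with pytest.raises(DegenerateGroupError):
        chisq_mortality([[0, 0], [5, 5]])
    with pytest.raises(ValueError):
        chisq_mortality([[1.5, 2], [3, 4]])
    with pytest.raises(ValueError):
        chisq_mortality([[1, 2]])


# ------------------------------------------------------------------------ GLMs


def _frame(groups: dict[str, np.ndarray], response: str = "y") -> pd.DataFrame:
    rows = [
        {"yeast": level, response: value}
        for level, values in groups.items()
        for value in values
    ]
    return pd.DataFrame(rows)


def test_gaussian_contrasts_equal_mean_differences():
    df = _frame(
        {
            "control_5pct": np.array([4.0, 6.0, 5.0]),
            "low_1pct": np.array([7.0, 9.0]),
            "none": np.array([1.0, 2.0, 3.0]),
        }
    )
    fit = fit_treatment_glm(
        df, "y", "gaussian", level_order=["control_5pct", "low_1pct", "none"]
    )
    table = fit.table.set_index("contrast")
    assert table.loc["control_5pct - low_1pct", "estimate"] == pytest.approx(8.0 - 5.0)
    assert table.loc["control_5pct - none", "estimate"] == pytest.approx(2.0 - 5.0)
    assert table.loc["low_1pct - none", "estimate"] == pytest.approx(2.0 - 8.0)
    assert fit.df_resid == 8 - 3


def test_quasipoisson_recovers_log_fold_effect():
    rng = np.random.default_rng(17)
    effect = -2.6
    mu_c = 20.0
    control = rng.poisson(mu_c, 50) * rng.integers(1, 3, 50)  # overdispersed
    stressed = rng.poisson(mu_c * np.exp(effect), 50) * rng.integers(1, 3, 50)
    df = _frame({"control_5pct": control, "none": stressed})
    fit = fit_treatment_glm(df, "y", "quasipoisson")
    row = fit.table.iloc[0]
    assert row["contrast"] == "control_5pct - none"
    assert row["estimate"] == pytest.approx(effect, abs=3 * row["se"])
    assert fit.dispersion > 1.0


def test_quasipoisson_se_equals_poisson_se_times_sqrt_dispersion():
    rng = np.random.default_rng(3)
    counts_a = rng.poisson(8, 40) * 2  # dispersion ~4
    counts_b = rng.poisson(15, 40) * 2
    df = _frame({"control_5pct": counts_a, "none": counts_b})
    fit = fit_treatment_glm(df, "y", "quasipoisson")
    x = np.column_stack([np.ones(80), df["yeast"].eq("none").to_numpy(float)])
    res = sm.GLM(df["y"], x, family=sm.families.Poisson()).fit()
    expected_se = res.bse.iloc[1] * np.sqrt(fit.dispersion)
    # two separate IRLS runs: allow convergence-level noise
    assert fit.table["se"].iloc[0] == pytest.approx(expected_se, rel=1e-6)


def test_glm_null_simulation_type_one_error():
    rng = np.random.default_rng(29)
    rejected = 0
    n_rep = 300
    for _ in range(n_rep):
        df = _frame(
            {"control_5pct": rng.normal(5, 1, 25), "none": rng.normal(5, 1, 25)}
        )
        fit = fit_treatment_glm(df, "y", "gaussian")
        rejected += fit.table["p_raw"].iloc[0] < 0.05
    assert 0.02 <= rejected / n_rep <= 0.09


def test_glm_omnibus_f_detects_effect():
    rng = np.random.default_rng(10)
    df = _frame(
        {"control_5pct": rng.normal(10, 1, 30), "none": rng.normal(5, 1, 30)}
    )
    fit = fit_treatment_glm(df, "y", "gaussian")
    assert fit.f_p < 1e-6
    assert fit.f_df == (1, 58)


def test_glm_design_and_degenerate_errors():
    with pytest.raises(DesignError):
        fit_treatment_glm(_frame({"none": np.arange(5.0)}), "y", "gaussian")
    zero = _frame({"control_5pct": np.zeros(5), "none": np.zeros(5)})
    with pytest.raises(DegenerateGroupError):
        fit_treatment_glm(zero, "y", "quasipoisson")
    with pytest.raises(ValueError):
        fit_treatment_glm(zero, "y", "negbin")


def test_glm_p_adj_bh_within_table():
    rng = np.random.default_rng(6)
    df = _frame(
        {
            "control_5pct": rng.normal(10, 1, 20),
            "low_1pct": rng.normal(10.5, 1, 20),
            "none": rng.normal(6, 1, 20),
        }
    )
    fit = fit_treatment_glm(df, "y", "gaussian")
    assert fit.table["p_adj"].to_numpy() == pytest.approx(
        bh_adjust(fit.table["p_raw"].to_numpy())
    )
    assert np.all(fit.table["p_adj"] >= fit.table["p_raw"] - 1e-15)


def test_interaction_estimate_matches_cell_means():
    # gaussian two-factor model: interaction coefficient equals the
    # difference-in-differences of cell means, exactly
    cells = {
        ("female", "control_5pct"): [10.0, 12.0],
        ("female", "none"): [6.0, 8.0],
        ("male", "control_5pct"): [9.0, 11.0],
        ("male", "none"): [8.5, 9.5],
    }
    rows = [
        {"sex": sex, "yeast": yeast, "y": v}
        for (sex, yeast), vals in cells.items()
        for v in vals
    ]
    tab = fit_interaction_glm(pd.DataFrame(rows), "y", "sex", "yeast", "gaussian")
    inter = tab[tab["term"] == "male:none"]["estimate"].iloc[0]
    did = (9.0 - 10.0) - (7.0 - 11.0)  # (male none - male ctrl) - (female none - female ctrl)
    assert inter == pytest.approx(did)


def test_interaction_requires_two_levels_each():
    rows = [{"sex": "male", "yeast": y, "y": 1.0} for y in ("control_5pct", "none")]
    with pytest.raises(DesignError):
        fit_interaction_glm(pd.DataFrame(rows), "y", "sex", "yeast")
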