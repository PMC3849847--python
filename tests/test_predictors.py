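"""Charlson index, outcome labelling, univariable screen and logistic models."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comorbval import (charlson_index, fit_multivariable, label_outcomes,
                       predictor_analysis, univariable_screen)
from comorbval.predictors import _principal_group, derive_covariates


# --- Charlson comorbidity index --------------------------------------------

def test_unmapped_codes_score_zero():
    assert charlson_index(["I10", "J189", "Z999"], 10) == 0
    assert charlson_index([], 9) == 0


@pytest.mark.parametrize("codes,version,expected", [
    (["I500", "C349"], 10, 3),          # CHF (1) + lung malignancy (2)
    (["4280", "1629"], 9, 3),
    (["I500", "I500", "I501"], 10, 1),  # one condition counts once
    (["C349", "C780"], 10, 6),          # metastasis supersedes malignancy
    (["K700", "K704"], 10, 3),          # severe liver supersedes mild
    (["B20"], 10, 6),
])
def test_charlson_weights_hand_summed(codes, version, expected):
    assert charlson_index(codes, version) == expected


def test_diabetes_categories_excluded_when_requested():
    assert charlson_index(["E119", "25001"], 10, exclude_diabetes=True) == 0
    assert charlson_index(["E119"], 10, exclude_diabetes=False) == 1
    assert charlson_index(["E1122"], 10, exclude_diabetes=False) == 2
    assert charlson_index(["2504"], 9, exclude_diabetes=False) == 2


def test_charlson_monotone_under_code_inclusion():
    rng = np.random.default_rng(12)
    pool = ["I500", "C349", "J449", "K700", "N189", "G30", "I10", "M05",
            "E119", "B20", "C780", "I21"]
    for _ in range(30):
        codes = list(rng.choice(pool, size=rng.integers(0, 8)))
        extra = list(rng.choice(pool, size=rng.integers(0, 4)))
        a = charlson_index(codes, 10, exclude_diabetes=False)
        b = charlson_index(codes + extra, 10, exclude_diabetes=False)
        assert b >= a


def test_unknown_icd_version_is_an_error():
    with pytest.raises(ValueError):
        charlson_index(["I500"], 11)


# --- outcome labelling -----------------------------------------------------

def test_label_outcomes_fn_fp_definitions():
    cohort = pd.DataFrame({
        "person_id": ["a", "b", "c", "d"], "era": ["ICD10"] * 4,
        "reference_diabetes": [True, False, True, False]})
    asc = pd.DataFrame({
        "person_id": ["a", "b", "c", "d"], "era": ["ICD10"] * 4,
        "window": ["index"] * 4,
        "administrative_diabetes": [False, True, True, False]})
    out = label_outcomes(cohort, asc)
    assert list(out["outcome_fn"]) == [True, pd.NA, False, pd.NA]
    assert list(out["outcome_fp"]) == [pd.NA, True, pd.NA, False]


@pytest.mark.parametrize("code,version,expected", [
    ("41091", 9, "MI"), ("4111", 9, "UA"), ("4139", 9, "other"),
    ("I214", 10, "MI"), ("I200", 10, "UA"), ("I251", 10, "other"),
])
def test_principal_diagnosis_grouping(code, version, expected):
    assert _principal_group(code, version) == expected


# --- univariable screen ----------------------------------------------------

def _rows_from_table(var_levels, outcome_counts):
    """Expand a contingency spec into row-level data."""
    recs = []
    for level, (n_pos, n_neg) in zip(var_levels, outcome_counts):
        recs += [{"v": level, "y": True}] * n_pos
        recs += [{"v": level, "y": False}] * n_neg
    return pd.DataFrame(recs)


def test_screen_detects_admission_type_pattern():
    # false-negative pattern among reference-positives: 12/47 booked vs
    # 22/332 emergency — strongly associated.  The smallest expected count is
    # 47*34/379 = 4.2 < 5, so the conventional rule routes this to Fisher.
    df = _rows_from_table(["booked", "emergency"], [(12, 35), (22, 310)])
    res = univariable_screen(df.rename(columns={"v": "admission_type"}),
                             "y", variables=("admission_type",))
    row = res.iloc[0]
    assert row["method"] == "fisher"
    assert row["p_value"] < 0.05 and row["significant"]
    # textbook Pearson chi-square on the same table agrees on significance
    obs = np.array([[12, 35], [22, 310]])
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    stat = ((obs - exp) ** 2 / exp).sum()
    assert stats.chi2.sf(stat, 1) < 0.05


def test_screen_chi_square_matches_textbook_statistic():
    df = _rows_from_table(["booked", "emergency"], [(30, 90), (40, 340)])
    res = univariable_screen(df.rename(columns={"v": "admission_type"}),
                             "y", variables=("admission_type",))
    row = res.iloc[0]
    assert row["method"] == "chi_square"
    obs = np.array([[30, 90], [40, 340]])
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    stat = ((obs - exp) ** 2 / exp).sum()
    assert row["statistic"] == pytest.approx(stat)
    assert row["p_value"] == pytest.approx(stats.chi2.sf(stat, 1))


def test_screen_balanced_table_is_null():
    df = _rows_from_table(["a", "b"], [(30, 30), (30, 30)])
    res = univariable_screen(df.rename(columns={"v": "x"}), "y",
                             variables=("x",))
    assert res.iloc[0]["p_value"] == pytest.approx(1.0)


def hypergeom_fisher_p(obs):
    """Brute-force two-sided Fisher p: enumerate tables with fixed margins."""
    r = obs.sum(axis=1)
    c = obs.sum(axis=0)
    n = obs.sum()

    def prob(a):
        b, cc, d = r[0] - a, c[0] - a, n - r[0] - c[0] + a
        if min(b, cc, d) < 0:
            return 0.0
        return (math.comb(r[0], a) * math.comb(r[1], cc)) / math.comb(n, c[0])

    p_obs = prob(obs[0, 0])
    return sum(prob(a) for a in range(0, min(r[0], c[0]) + 1)
               if prob(a) <= p_obs + 1e-12)


def test_screen_takes_fisher_branch_for_small_expected_counts():
    df = _rows_from_table(["a", "b"], [(4, 2), (1, 13)])  # expected cell < 5
    res = univariable_screen(df.rename(columns={"v": "x"}), "y",
                             variables=("x",))
    row = res.iloc[0]
    assert row["method"] == "fisher"
    obs = np.array([[4, 2], [1, 13]])
    assert row["p_value"] == pytest.approx(hypergeom_fisher_p(obs), abs=1e-10)


def test_screen_skips_degenerate_variable(caplog):
    df = pd.DataFrame({"x": ["only"] * 20, "y": [True] * 5 + [False] * 15})
    with caplog.at_level("INFO", logger="comorbval"):
        res = univariable_screen(df, "y", variables=("x",))
    assert res.empty


# --- logistic regression ---------------------------------------------------

def test_single_covariate_or_equals_cross_product_ratio():
    rng = np.random.default_rng(7)
    x = rng.random(400) < 0.4
    y = rng.random(400) < np.where(x, 0.35, 0.15)
    df = pd.DataFrame({"admission_type": np.where(x, "elective", "emergency"),
                       "y": y})
    res = fit_multivariable(df, "y", ["admission_type"])
    a = np.sum(x & y); b = np.sum(x & ~y)
    c = np.sum(~x & y); d = np.sum(~x & ~y)
    assert res.converged
    assert res.table.iloc[0]["odds_ratio"] == pytest.approx(
        (a * d) / (b * c), abs=1e-8)


def test_null_model_cis_cover_one():
    rng = np.random.default_rng(42)
    n = 3000
    df = pd.DataFrame({
        "admission_type": np.where(rng.random(n) < 0.3, "elective",
                                   "emergency"),
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "y": rng.random(n) < 0.2})
    res = fit_multivariable(df, "y", ["admission_type", "sex"])
    for _, row in res.table.iterrows():
        assert row["ci_low"] < 1.0 < row["ci_high"]


def test_separation_is_flagged_not_silent():
    df = pd.DataFrame({"x": ["a"] * 10 + ["b"] * 10,
                       "y": [True] * 10 + [False] * 10})
    res = fit_multivariable(df, "y", ["x"])
    assert not res.converged


def test_multilevel_variable_contrasts_against_reference():
    rng = np.random.default_rng(3)
    n = 2000
    band = rng.choice(["1-2", "3-5", ">=6"], size=n)
    p = np.select([band == "1-2", band == "3-5"], [0.3, 0.2], default=0.1)
    df = pd.DataFrame({"los_band": band, "y": rng.random(n) < p})
    res = fit_multivariable(df, "y", ["los_band"])
    got = dict(zip(res.table["level"], res.table["odds_ratio"]))
    assert set(got) == {"1-2", "3-5"}          # >=6 is the reference
    assert got["1-2"] > got["3-5"] > 1.0


def test_fp_model_not_fitted_when_screen_is_null():
    rng = np.random.default_rng(8)
    n = 800
    df = pd.DataFrame({
        "era": ["ICD10"] * n,
        "sex": rng.choice(["M", "F"], n),
        "admission_type": rng.choice(["elective", "emergency"], n),
        "outcome_fp": pd.array(rng.random(n) < 0.02, dtype="boolean")})
    screen, model = predictor_analysis(
        df, "outcome_fp", "ICD10", variables=("sex", "admission_type"))
    assert not screen["significant"].any()
    assert model is None


def test_or_recovery_small_simulation():
    """Quick coverage sanity check at 60 replicates; the full 500-replicate
    nominal-coverage check runs in the acceptance suite."""
    rng = np.random.default_rng(99)
    true_or = 3.0
    hits = 0
    for _ in range(60):
        n = 700
        x = rng.random(n) < 0.3
        logit = -1.8 + math.log(true_or) * x
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({"admission_type": np.where(x, "elective",
                                                      "emergency"), "y": y})
        res = fit_multivariable(df, "y", ["admission_type"])
        row = res.table.iloc[0]
        hits += row["ci_low"] <= true_or <= row["ci_high"]
    assert hits >= 48  # ~95% nominal; allow wide slack at 60 replicates


# --- covariate derivation ---------------------------------------------------

def test_derive_covariates_bands(small_cohort, small_dataset):
    adm, _, _ = small_dataset
    from comorbval import derive_history_covariates

    hc = derive_history_covariates(small_cohort, adm)
    cov = derive_covariates(small_cohort, hc)
    assert set(cov["los_band"]) <= {"1-2", "3-5", ">=6"}
    assert set(cov["age_band"]) <= {"25-50", "51-65", "66-79"}
    assert set(cov["charlson_band"]) <= {"0", "1-4", ">=5"}
    assert set(cov["comorbidity_band"]) <= {"0-3", "4-7", ">=8"}
    assert set(cov["principal_dx_group"]) <= {"MI", "UA", "other"}
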