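"""Predictors of administrative false negatives and false positives.

On the index admission, a false negative is a reference-standard diabetic
with no administrative diabetes code, a false positive a non-diabetic with
one.  Candidate predictors are administrative covariates of the index
admission; screening is univariable (Pearson chi-square, or Fisher's exact
when expected cell counts are small), and variables passing the screen enter
a multivariable logistic regression with Wald 95% CIs, fitted separately per
ICD era.

The Charlson Comorbidity Index uses the Quan et al. ICD-9-CM/ICD-10 coding
algorithm shipped as package data (data/charlson_quan.csv) with the original
Charlson weights; the diabetes categories can be excluded, as is usual when
diabetes itself is the condition under validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ascertainment import INDEX_ONLY, _split_secondaries

logger = logging.getLogger("comorbval")

#: Charlson category hierarchy: when both are present only the more severe counts
_CHARLSON_HIERARCHY = {
    "diabetes_uncomplicated": "diabetes_complicated",
    "mild_liver": "severe_liver",
    "cancer": "mets",
}
_DIABETES_CONDITIONS = ("diabetes_uncomplicated", "diabetes_complicated")

#: Table-style reference levels for indicator contrasts
REFERENCE_LEVELS = {
    "admission_type": "emergency",
    "died_in_hospital": False,
    "los_band": ">=6",
    "principal_dx_group": "other",
    "comorbidity_band": ">=8",
    "charlson_band": "0",
    "age_band": "66-79",
    "sex": "M",
    "indigenous_derived": False,
    "prior_90day": False,
    "hospital_location": "metropolitan",
    "hospital_type": "public",
    "transfer_in_or_out": False,
    "first_ever_chd": False,
}

#: the standard candidate-variable list for the false-negative/positive screen
DEFAULT_VARIABLES = ("los_band", "age_band", "sex", "admission_type",
                     "indigenous_derived", "charlson_band", "comorbidity_band",
                     "prior_90day", "hospital_location", "hospital_type",
                     "transfer_in_or_out", "died_in_hospital",
                     "principal_dx_group", "first_ever_chd")


@lru_cache(maxsize=1)
def _charlson_table() -> pd.DataFrame:
    with resources.files("comorbval.data").joinpath(
            "charlson_quan.csv").open() as fh:
        return pd.read_csv(fh, dtype={"prefix": str})


def charlson_index(codes: Iterable[str], version: int,
                   exclude_diabetes: bool = True) -> int:
    """Charlson Comorbidity Index from a set of ICD diagnosis codes.

    Each mapped condition counts once at its weight; within the hierarchical
    pairs (diabetes with/without complication, mild/severe liver disease,
    malignancy/metastasis) only the more severe member counts.  With
    ``exclude_diabetes`` both diabetes categories contribute zero.
    """
    if version not in (9, 10):
        raise ValueError(f"unknown ICD version {version!r}")
    table = _charlson_table()
    table = table[table["icd_version"] == version]
    norm = [str(c).replace(".", "").replace(" ", "").upper()
            for c in codes if c is not None and str(c).strip()]
    hit = {}
    for cond, weight, prefix in zip(table["condition"], table["weight"],
                                    table["prefix"]):
        if cond in hit:
            continue
        if any(c.startswith(prefix) for c in norm):
            hit[cond] = int(weight)
    for mild, severe in _CHARLSON_HIERARCHY.items():
        if mild in hit and severe in hit:
            del hit[mild]
    if exclude_diabetes:
        for cond in _DIABETES_CONDITIONS:
            hit.pop(cond, None)
    return sum(hit.values())


def _band(value: float, edges: Sequence[float], labels: Sequence[str]) -> str:
    for hi, lab in zip(edges, labels):
        if value <= hi:
            return lab
    return labels[-1]


def _principal_group(code: str, version: int) -> str:
    c = str(code).replace(".", "").upper()
    if version == 9:
        if c.startswith("410"):
            return "MI"
        if c.startswith("4111"):
            return "UA"
    else:
        if c[:3] in ("I21", "I22"):
            return "MI"
        if c.startswith("I200"):
            return "UA"
    return "other"


def derive_covariates(cohort: pd.DataFrame,
                      history_covariates: pd.DataFrame) -> pd.DataFrame:
    """Attach banded index-admission covariates to the cohort.

    Bands follow the validation-study conventions: length of stay 1-2 / 3-5 /
    >=6 days, age 25-50 / 51-65 / 66-79, Charlson (diabetes excluded) 0 /
    1-4 / >=5, comorbidity count (diabetes excluded) 0-3 / 4-7 / >=8.
    """
    df = cohort.merge(history_covariates, on=["person_id", "era"], how="left")
    los = (pd.to_datetime(df["separation_date"])
           - pd.to_datetime(df["index_date"])).dt.days.clip(lower=1)
    df["los_band"] = [_band(v, (2, 5), ("1-2", "3-5", ">=6")) for v in los]
    if "age" in df:
        df["age_band"] = [_band(v, (50, 65), ("25-50", "51-65", "66-79"))
                          for v in df["age"]]

    charlson, n_comorb, pgroup = [], [], []
    from .ascertainment import is_diabetes_code
    for row in df[["icd_version", "principal_diagnosis",
                   "secondary_diagnoses"]].to_dict("records"):
        v = int(row["icd_version"])
        sec = _split_secondaries(row["secondary_diagnoses"])
        charlson.append(charlson_index(sec + [row["principal_diagnosis"]], v,
                                       exclude_diabetes=True))
        n_comorb.append(sum(not is_diabetes_code(c, v) for c in sec))
        pgroup.append(_principal_group(row["principal_diagnosis"], v))
    df["charlson_band"] = [_band(v, (0, 4), ("0", "1-4", ">=5"))
                           for v in charlson]
    df["comorbidity_band"] = [_band(v, (3, 7), ("0-3", "4-7", ">=8"))
                              for v in n_comorb]
    df["principal_dx_group"] = pgroup
    df["transfer_in_or_out"] = (df["transfer_in"].astype(bool)
                                | df["transfer_out"].astype(bool))
    df["died_in_hospital"] = df["died_in_hospital"].astype(bool)
    df["indigenous_derived"] = df["indigenous_derived"].astype(bool)
    return df


def label_outcomes(cohort: pd.DataFrame,
                   ascertainment: pd.DataFrame) -> pd.DataFrame:
    """Attach index-admission FN/FP outcome labels.

    ``outcome_fn`` is defined among reference-positives (NA elsewhere),
    ``outcome_fp`` among reference-negatives.
    """
    idx = ascertainment[ascertainment["window"] == INDEX_ONLY]
    df = cohort.merge(
        idx[["person_id", "era", "administrative_diabetes"]],
        on=["person_id", "era"], how="left", validate="one_to_one")
    ref = df["reference_diabetes"].astype(bool)
    adm = df["administrative_diabetes"].astype(bool)
    df["outcome_fn"] = pd.array(np.where(ref, ~adm, None), dtype="boolean")
    df["outcome_fp"] = pd.array(np.where(~ref, adm, None), dtype="boolean")
    return df


def univariable_screen(rows: pd.DataFrame, outcome: str,
                       variables: Sequence[str] = DEFAULT_VARIABLES,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable association screen against a binary outcome.

    Pearson chi-square on the variable x outcome contingency table; Fisher's
    exact replaces it for 2x2 tables with any expected count below 5.
    Degenerate variables (a single observed level) are skipped and logged.

    Returns a DataFrame (variable, method, statistic, p_value, significant).
    """
    data = rows.dropna(subset=[outcome])
    y = data[outcome].astype(bool)
    out = []
    for var in variables:
        if var not in data.columns:
            logger.info("screen: variable %s absent, skipped", var)
            continue
        tab = pd.crosstab(data[var], y)
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            logger.info("screen: variable %s degenerate, skipped", var)
            continue
        obs = tab.to_numpy()
        expected = stats.contingency.expected_freq(obs)
        if obs.shape == (2, 2) and (expected < 5).any():
            stat, p = stats.fisher_exact(obs)
            method = "fisher"
        else:
            stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
            method = "chi_square"
        out.append((var, method, float(stat), float(p), p < alpha))
    return pd.DataFrame(out, columns=["variable", "method", "statistic",
                                      "p_value", "significant"])


@dataclass
class ModelResult:
    """Multivariable logistic-regression summary for one era."""

    era: str
    n: int
    converged: bool
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: variable, level, odds_ratio, ci_low, ci_high, p_value


def fit_multivariable(rows: pd.DataFrame, outcome: str,
                      selected_variables: Sequence[str],
                      era: str = "") -> ModelResult:
    """Maximum-likelihood logistic regression with Wald 95% CIs on the ORs.

    Multi-level variables enter as indicator contrasts against the
    conventional reference levels (emergency admission, no in-hospital death,
    >=6-day stay, other-CHD principal diagnosis, >=8 comorbidities, ...).
    Non-convergence or separation is flagged, never silently reported.
    """
    data = rows.dropna(subset=[outcome]).copy()
    y = data[outcome].astype(bool).astype(float).to_numpy()
    cols, names = [], []
    for var in selected_variables:
        ref = REFERENCE_LEVELS.get(var)
        levels = [l for l in pd.unique(data[var]) if l != ref]
        try:
            levels = sorted(levels)
        except TypeError:
            pass
        for level in levels:
            cols.append((data[var] == level).astype(float).to_numpy())
            names.append((var, level))
    X = sm.add_constant(np.column_stack(cols)) if cols else None
    if X is None:
        raise ValueError("no covariates to fit")

    import warnings

    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if any("erfect separation" in str(w.message) for w in caught):
            converged = False
        converged = converged and bool(fit.mle_retvals.get("converged", False))
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    except Exception as exc:  # separation raises PerfectSeparationError
        logger.warning("logistic fit failed (%s); flagged as non-converged", exc)
        return ModelResult(era=era, n=len(y), converged=False)
    if not (np.all(np.isfinite(bse)) and np.all(np.abs(params) < 30)):
        converged = False
        logger.warning("logistic fit unstable (separation suspected); "
                       "flagged as non-converged")

    z = stats.norm.ppf(0.975)
    recs = []
    with np.errstate(over="ignore"):
        for i, (var, level) in enumerate(names, start=1):
            recs.append((var, str(level), float(np.exp(params[i])),
                         float(np.exp(params[i] - z * bse[i])),
                         float(np.exp(params[i] + z * bse[i])),
                         float(pvals[i])))
    table = pd.DataFrame(recs, columns=["variable", "level", "odds_ratio",
                                        "ci_low", "ci_high", "p_value"])
    return ModelResult(era=era, n=len(y), converged=converged, table=table)


def predictor_analysis(rows: pd.DataFrame, outcome: str, era: str,
                       variables: Sequence[str] = DEFAULT_VARIABLES,
                       entry_p: float = 0.05):
    """Screen-then-model workflow for one era and one outcome.

    Univariably significant variables (at ``entry_p``; 0.1 available as the
    sensitivity-entry rule) enter the multivariable model.  When nothing
    passes the screen no model is fitted and None is returned in its place —
    the expected behaviour for the rare-false-positive outcome.
    """
    data = rows[rows["era"] == era]
    screen = univariable_screen(data, outcome, variables, alpha=entry_p)
    selected = list(screen.loc[screen["significant"], "variable"])
    if not selected:
        logger.info("%s/%s: no univariably significant variables; "
                    "no multivariable model fitted", era, outcome)
        return screen, None
    model = fit_multivariable(data, outcome, selected, era=era)
    return screen, model
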