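"""Administrative diabetes ascertainment at configurable lookback windows.

For each cohort row the administrative diabetes status is the union, over the
index admission plus every prior admission inside the lookback window, of a
per-admission code check: ICD-9/ICD-9-CM category 250 or ICD-10-AM E10-E14 in
any of the 21 diagnosis fields, matched under the ICD version in force at
that record's own date.  Windows are half-open calendar intervals
``[index_date - w years, index_date)``; the index admission itself is always
included, so status is non-decreasing in window length by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, Union

import pandas as pd

from .cohort import _normalise, is_chd_code

logger = logging.getLogger("comorbval")

#: label for the no-lookback window
INDEX_ONLY = "index"
#: the study's lookback grid, in years
STANDARD_WINDOWS: tuple = (INDEX_ONLY, 1, 2, 5, 10, 15)

Window = Union[str, int]


@dataclass
class LookbackSpec:
    """Ordered lookback windows: 'index' and/or year counts, strictly increasing."""

    windows: Sequence[Window] = field(default_factory=lambda: STANDARD_WINDOWS)

    def __post_init__(self):
        years = [w for w in self.windows if w != INDEX_ONLY]
        if any(not isinstance(w, int) or w <= 0 for w in years):
            raise ValueError(f"invalid lookback windows {self.windows!r}")
        if years != sorted(set(years)):
            raise ValueError("year windows must be strictly increasing")


def is_diabetes_code(code, version: int) -> bool:
    """True iff the code's category is diabetes mellitus (250 or E10-E14).

    Sub-codes (fourth/fifth digits, ICD-10 decimals) match by prefix;
    malformed codes match nothing.
    """
    c = _normalise(code)
    if version == 9:
        return c[:3] == "250"
    if version == 10:
        return c[:1] == "E" and c[1:3].isdigit() and 10 <= int(c[1:3]) <= 14
    logger.warning("unknown ICD version %r for code %r", version, code)
    return False


def _split_secondaries(raw) -> list:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return []
    return [c for c in str(raw).split(";") if c]


def admission_has_diabetes(record) -> bool:
    """True iff any of the record's 21 diagnosis fields carries a diabetes code.

    The record's own ``icd_version`` governs matching, so mixed-era histories
    are handled per record (a 1997 admission is matched against 250-codes even
    when the index admission is ICD-10).
    """
    v = int(record["icd_version"])
    if is_diabetes_code(record["principal_diagnosis"], v):
        return True
    return any(is_diabetes_code(c, v)
               for c in _split_secondaries(record["secondary_diagnoses"]))


def years_before(date: pd.Timestamp, years: int) -> pd.Timestamp:
    """Same month/day ``years`` earlier; Feb-29 maps to Feb-28."""
    return pd.Timestamp(date) - pd.DateOffset(years=years)


def ascertain(index_row, history: pd.DataFrame,
              spec: LookbackSpec) -> dict:
    """Administrative diabetes status for one cohort row at each window.

    Parameters
    ----------
    index_row : mapping with ``index_admission_id`` and ``index_date``.
    history : the person's admission records (must include the index).
    spec : lookback windows to evaluate.

    Returns
    -------
    dict mapping window label -> bool; includes the windows requested plus
    always the index-only component used to anchor them.
    """
    h = history.copy()
    h["admission_date"] = pd.to_datetime(h["admission_date"])
    index_date = pd.Timestamp(index_row["index_date"])
    is_index = h["admission_id"] == index_row["index_admission_id"]
    if not is_index.any():
        raise ValueError("history does not contain the index admission")
    after = ~is_index & (h["admission_date"] >= index_date)
    if after.any():
        logger.debug("excluding %d admissions dated on/after the index",
                     int(after.sum()))
    has_dm = h.apply(admission_has_diabetes, axis=1)
    index_status = bool(has_dm[is_index].any())

    out = {}
    for w in spec.windows:
        if w == INDEX_ONLY:
            out[w] = index_status
            continue
        lo = years_before(index_date, int(w))
        in_win = (~is_index & ~after
                  & (h["admission_date"] >= lo)
                  & (h["admission_date"] < index_date))
        out[w] = index_status or bool(has_dm[in_win].any())
    return out


def ascertain_cohort(cohort: pd.DataFrame, admissions: pd.DataFrame,
                     spec: LookbackSpec = None) -> pd.DataFrame:
    """Vectorised ascertainment for every cohort row.

    Returns a long-format table (person_id, era, window, administrative_diabetes)
    with one row per cohort row per window.
    """
    spec = spec or LookbackSpec()
    adm = admissions.copy()
    adm["admission_date"] = pd.to_datetime(adm["admission_date"])
    adm["has_dm"] = [
        admission_has_diabetes(r) for r in
        adm[["icd_version", "principal_diagnosis",
             "secondary_diagnoses"]].to_dict("records")]

    merged = adm[["person_id", "admission_id", "admission_date", "has_dm"]].merge(
        cohort[["person_id", "era", "index_admission_id", "index_date"]],
        on="person_id", how="inner")
    merged["index_date"] = pd.to_datetime(merged["index_date"])
    is_index = merged["admission_id"] == merged["index_admission_id"]
    prior = merged["admission_date"] < merged["index_date"]

    key = ["person_id", "era"]
    base = cohort[key].copy()
    index_status = (merged.loc[is_index].groupby(key)["has_dm"].any()
                    .rename("status"))

    rows = []
    for w in spec.windows:
        if w == INDEX_ONLY:
            status = base.merge(index_status.reset_index(), on=key, how="left")
        else:
            lo = merged["index_date"] - pd.DateOffset(years=int(w))
            in_win = prior & merged["has_dm"] & (merged["admission_date"] >= lo)
            prior_hit = (merged.assign(hit=in_win).groupby(key)["hit"].any()
                         .rename("prior"))
            status = (base.merge(index_status.reset_index(), on=key, how="left")
                      .merge(prior_hit.reset_index(), on=key, how="left"))
            status["status"] = (status["status"].fillna(False)
                                | status["prior"].fillna(False))
        status["status"] = status["status"].fillna(False).astype(bool)
        rows.append(status.assign(window=str(w))[
            ["person_id", "era", "window", "status"]])
    out = pd.concat(rows, ignore_index=True).rename(
        columns={"status": "administrative_diabetes"})
    return out


def derive_history_covariates(cohort: pd.DataFrame,
                              admissions: pd.DataFrame) -> pd.DataFrame:
    """Per cohort row: recent-hospitalization and first-ever-CHD indicators.

    ``prior_90day`` — any admission (any diagnosis) in the 90 days before the
    index; ``first_ever_chd`` — no CHD *principal* admission in the 15 years
    before the index (consistent with index selection, which also uses the
    principal field only).
    """
    adm = admissions.copy()
    adm["admission_date"] = pd.to_datetime(adm["admission_date"])
    adm["chd_principal"] = [is_chd_code(c, v) for c, v in
                            zip(adm["principal_diagnosis"], adm["icd_version"])]
    merged = adm[["person_id", "admission_id", "admission_date",
                  "chd_principal"]].merge(
        cohort[["person_id", "era", "index_admission_id", "index_date"]],
        on="person_id", how="inner")
    merged["index_date"] = pd.to_datetime(merged["index_date"])
    prior = merged["admission_date"] < merged["index_date"]
    key = ["person_id", "era"]

    in_90 = prior & (merged["admission_date"]
                     >= merged["index_date"] - pd.Timedelta(days=90))
    lo15 = merged["index_date"] - pd.DateOffset(years=15)
    chd_prior = (prior & merged["chd_principal"]
                 & (merged["admission_date"] >= lo15))

    g = merged.assign(p90=in_90, chd15=chd_prior).groupby(key)[["p90", "chd15"]].any()
    out = cohort[key].merge(g.reset_index(), on=key, how="left").fillna(
        {"p90": False, "chd15": False})
    out["prior_90day"] = out.pop("p90").astype(bool)
    out["first_ever_chd"] = ~out.pop("chd15").astype(bool)
    return out
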