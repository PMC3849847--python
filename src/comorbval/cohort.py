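"""Analysis-cohort construction from linked admission and medical-record tables.

Selects one index CHD admission per person per sampling era, derives
Indigenous status from the person's whole record history (the >=25% rule used
to counter record-level under-identification), and classifies reference
diabetes status from the medical-record review entry.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("comorbval")

#: category ranges for coronary heart disease principal diagnoses
_CHD_RANGE_9 = (410, 414)   # ICD-9-CM 410-414
_CHD_RANGE_10 = (20, 25)    # ICD-10-AM I20-I25


def _normalise(code) -> str:
    return str(code).replace(".", "").replace(" ", "").upper()


def is_chd_code(code, version: int) -> bool:
    """True iff the code's leading category is CHD (410-414 or I20-I25).

    Matching is on the category prefix, ignoring punctuation and sub-code
    digits; malformed codes match nothing (logged, never raised).
    """
    c = _normalise(code)
    try:
        if version == 9:
            return c[:3].isdigit() and _CHD_RANGE_9[0] <= int(c[:3]) <= _CHD_RANGE_9[1]
        if version == 10:
            return (c[:1] == "I" and c[1:3].isdigit()
                    and _CHD_RANGE_10[0] <= int(c[1:3]) <= _CHD_RANGE_10[1])
    except (ValueError, IndexError):  # pragma: no cover - isdigit guards
        pass
    if version not in (9, 10):
        logger.warning("unknown ICD version %r for code %r", version, code)
    elif not c:
        logger.debug("empty diagnosis code treated as non-CHD")
    return False


def select_index_admissions(admissions: pd.DataFrame, era: str,
                            era_window: tuple) -> pd.DataFrame:
    """One row per person: the earliest CHD-principal admission in the window.

    Persons with no in-window admission whose *principal* diagnosis is CHD are
    excluded (secondary-field CHD does not qualify).  Same-day ties break on
    the lowest admission_id, so the result is invariant to input row order.
    """
    adm = admissions.copy()
    adm["admission_date"] = pd.to_datetime(adm["admission_date"])
    lo, hi = pd.Timestamp(era_window[0]), pd.Timestamp(era_window[1])
    in_window = (adm["admission_date"] >= lo) & (adm["admission_date"] <= hi)
    chd = np.fromiter(
        (is_chd_code(c, v) for c, v in
         zip(adm["principal_diagnosis"], adm["icd_version"])),
        dtype=bool, count=len(adm))
    eligible = adm.loc[in_window.to_numpy() & chd]
    if eligible.empty:
        return pd.DataFrame(columns=["person_id", "era", "index_admission_id",
                                     "index_date"])
    idx = (eligible.sort_values(["person_id", "admission_date", "admission_id"])
           .groupby("person_id", sort=True).head(1))
    out = idx[["person_id", "admission_id", "admission_date"]].rename(
        columns={"admission_id": "index_admission_id",
                 "admission_date": "index_date"})
    out.insert(1, "era", era)
    return out.reset_index(drop=True)


def derive_indigenous(history: pd.DataFrame) -> bool:
    """Indigenous if >=25% of the person's records carry the Indigenous flag.

    Uses integer arithmetic so the 25% boundary is exact (1 of 4 -> True).
    """
    n = len(history)
    if n == 0:
        raise ValueError("derive_indigenous requires a non-empty history")
    flagged = int(pd.Series(history["indigenous_flag"]).astype(int).sum())
    return 4 * flagged >= n


def classify_reference_diabetes(documented: str, drug_treatment: bool):
    """Reference-standard diabetes classification for one index admission.

    Diabetes is present if documented 'present' in the notes OR diabetes drug
    treatment was identified; 'not recorded' with no drugs counts as no
    diabetes but sets the flag used by the drop-not-recorded sensitivity
    analysis.

    Returns
    -------
    (reference_diabetes, not_recorded_flag) : tuple of bool
    """
    if documented not in ("present", "absent", "not_recorded"):
        raise ValueError(f"invalid documentation status {documented!r}")
    if documented == "present" or drug_treatment:
        return True, False
    return False, documented == "not_recorded"


def build_cohort(admissions: pd.DataFrame, medical_records: pd.DataFrame,
                 era_windows: dict,
                 age_bounds: Optional[dict] = None,
                 truth: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Assemble the analysis cohort: one row per (person, era).

    For each era window, selects index admissions, attaches the per-person
    derived Indigenous status (whole supplied history), joins the
    medical-record reference entry (rows without one are excluded and
    counted), and carries the index admission's administrative covariates.

    Parameters
    ----------
    era_windows : mapping era label -> (start, end) date-likes.
    age_bounds : optional mapping era label -> (min_age, max_age); applied
        only when a truth table with an ``age`` column is supplied (the two
        sampling frames used different age ranges).
    truth : optional person-level table with age/sex to carry along.
    """
    adm = admissions.copy()
    adm["admission_date"] = pd.to_datetime(adm["admission_date"])

    # person-level Indigenous derivation over the full record history
    per_person = adm.groupby("person_id")["indigenous_flag"].agg(["sum", "count"])
    indig = (4 * per_person["sum"] >= per_person["count"]).rename(
        "indigenous_derived")

    pieces = []
    for era, window in era_windows.items():
        idx = select_index_admissions(adm, era, window)
        pieces.append(idx)
    cohort = pd.concat(pieces, ignore_index=True)
    cohort = cohort.merge(indig.reset_index(), on="person_id", how="left")

    n_selected = len(cohort)
    mr = medical_records[["index_admission_id", "diabetes_documented",
                          "diabetes_drug_treatment"]]
    cohort = cohort.merge(mr, on="index_admission_id", how="left")
    missing = cohort["diabetes_documented"].isna()
    if missing.any():
        logger.info("excluding %d index admissions without a reviewable "
                    "medical record", int(missing.sum()))
    cohort = cohort.loc[~missing].copy()

    ref = [classify_reference_diabetes(d, bool(t)) for d, t in
           zip(cohort["diabetes_documented"],
               cohort["diabetes_drug_treatment"].astype(int))]
    cohort["reference_diabetes"] = [r[0] for r in ref]
    cohort["not_recorded_flag"] = [r[1] for r in ref]

    # carry the index admission's administrative covariates
    carry = ["admission_id", "icd_version", "principal_diagnosis",
             "secondary_diagnoses", "admission_type", "hospital_type",
             "hospital_location", "transfer_in", "transfer_out",
             "died_in_hospital", "separation_date"]
    cohort = cohort.merge(
        adm[carry].rename(columns={"admission_id": "index_admission_id"}),
        on="index_admission_id", how="left")

    if truth is not None:
        cohort = cohort.merge(
            truth[["person_id", "era", "age", "sex"]],
            on=["person_id", "era"], how="left")
        if age_bounds:
            keep = pd.Series(True, index=cohort.index)
            for era, (lo, hi) in age_bounds.items():
                in_era = cohort["era"] == era
                keep &= ~in_era | cohort["age"].between(lo, hi)
            dropped = int((~keep).sum())
            if dropped:
                logger.info("excluding %d rows outside era age bounds", dropped)
            cohort = cohort.loc[keep].copy()

    cohort.attrs["n_index_selected"] = n_selected
    cohort.attrs["n_missing_medical_record"] = int(missing.sum())
    return cohort.sort_values(["era", "person_id"]).reset_index(drop=True)


def drop_not_recorded(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity analysis: remove rows whose reference entry was 'not recorded'."""
    return cohort.loc[~cohort["not_recorded_flag"]].reset_index(drop=True)
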