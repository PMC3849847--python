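"""Synthetic linked hospital-admission histories with a medical-record reference standard.

Generates the three tables the validation pipeline consumes — admissions,
medical-record entries and person-level truth — with the statistical structure
of a linked administrative dataset: each person has one index coronary heart
disease (CHD) admission per sampling era, a multi-year Poisson admission
history before it, per-admission diabetes coding with era-dependent
sensitivity, and fallible per-record Indigenous-status flags.

Tables are plain pandas DataFrames with ISO-8601 date strings, suitable for
round-tripping through delimited text files.

Column schemas
--------------
admissions:
    person_id, admission_id, admission_date, separation_date, icd_version,
    principal_diagnosis, secondary_diagnoses (``;``-joined, empty string when
    none), admission_type (elective|emergency), hospital_type (public|private),
    hospital_location (metropolitan|rural), transfer_in, transfer_out,
    died_in_hospital, indigenous_flag (0/1 integers for booleans)
medical_records:
    person_id, index_admission_id, era, diabetes_documented
    (present|absent|not_recorded), diabetes_drug_treatment (0/1)
truth:
    person_id, era, true_diabetes, true_indigenous, age, sex
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("comorbval")

#: date on which hospital coding switched from ICD-9-CM to ICD-10-AM
ICD10_CUTOVER = dt.date(1999, 7, 1)

# Small pools of syntactically valid codes per version.  The principal pool
# deliberately contains no CHD (410-414 / I20-I25) and no diabetes category.
_CHD_PRINCIPAL = {
    # (group, version) -> codes; groups weighted to the roughly 49/45/6
    # MI / unstable angina / other-CHD case mix of acute CHD admissions
    ("MI", 9): ["41001", "41041", "41071", "41091"],
    ("UA", 9): ["4111", "41181"],
    ("other", 9): ["4139", "41400", "41401"],
    ("MI", 10): ["I210", "I211", "I214", "I219"],
    ("UA", 10): ["I200"],
    ("other", 10): ["I208", "I209", "I251", "I259"],
}
_CHD_GROUP_P = {"MI": 0.49, "UA": 0.45, "other": 0.06}
_NONCHD_PRINCIPAL = {
    9: ["486", "5990", "78650", "4280", "5849", "56211", "49390", "82120"],
    10: ["J189", "N390", "R074", "I500", "N179", "K573", "J459", "S7200"],
}
_COMORBIDITY_POOL = {
    9: ["4011", "2720", "4280", "42731", "496", "5859", "2859", "3051",
        "71590", "53081", "2449", "27800"],
    10: ["I10", "E780", "I500", "I480", "J449", "N189", "D649", "F171",
         "M199", "K219", "E039", "E669"],
}
_DIABETES_CODES = {
    9: ["25000", "25001", "25040", "25060", "2509"],
    10: ["E119", "E1165", "E1122", "E109", "E149"],
}


def _as_date(x) -> dt.date:
    if isinstance(x, dt.date):
        return x
    return dt.date.fromisoformat(str(x))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic linked-data generator.

    Defaults emulate the study conditions of a two-era CHD validation sample:
    an ICD-9 era (1998) and an ICD-10 era (2002-04) with era sizes 1685 and
    2258, era- and Indigenous-status-specific true diabetes prevalence,
    era-dependent per-admission diabetes coding sensitivity, and at least
    15 years of admission history before each index admission.
    """

    n_patients_per_era: Mapping[str, int] = field(
        default_factory=lambda: {"ICD9": 1685, "ICD10": 2258})
    era_windows: Mapping[str, tuple] = field(
        default_factory=lambda: {"ICD9": ("1998-01-01", "1998-12-31"),
                                 "ICD10": ("2002-01-01", "2004-12-31")})
    #: years of pre-index admission history to simulate (>= max lookback)
    history_years: int = 16
    #: true diabetes prevalence per era, split by true Indigenous status
    prev_diabetes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "ICD9": {"non_indigenous": 0.22, "indigenous": 0.45},
            "ICD10": {"non_indigenous": 0.29, "indigenous": 0.56}})
    #: per-admission probability a true diabetic's record carries a diabetes
    #: code, keyed by the ICD version in force at that record's date
    p_code_diabetes: Mapping[int, float] = field(
        default_factory=lambda: {9: 0.91, 10: 0.815})
    #: per-admission probability a non-diabetic's record carries a diabetes code
    q_miscode: float = 0.015
    #: expected non-index admissions per person-year (non-diabetics)
    admission_rate: float = 0.4
    #: multiplier on admission_rate for true diabetics
    admission_rate_ratio_diabetic: float = 1.5
    prop_indigenous: Mapping[str, float] = field(
        default_factory=lambda: {"ICD9": 0.015, "ICD10": 0.23})
    #: per-record probability a truly Indigenous person's admission is flagged
    p_record_indigenous: float = 0.7
    #: medical-record documentation probabilities (defaults treat the record
    #: as an error-free reference standard for diabetics)
    p_doc_present: float = 1.0
    p_drug_given_diabetic: float = 0.5
    #: probability a non-diabetic's reference entry is 'not recorded'
    p_not_recorded: float = 0.025
    covariate_params: Mapping[str, float] = field(
        default_factory=lambda: {
            "los_poisson_mean": 3.0,       # length of stay = 1 + Poisson
            "p_elective": 0.11,
            "p_private": 0.21,
            "p_rural": 0.19,
            "p_transfer": 0.10,
            "p_death_index": 0.06,
            "comorbidity_poisson_mean": 4.0,
            "p_prior_chd": 0.25,           # prior admission may be CHD when
                                           # dated outside every era window
            "age_mean": 62.0, "age_sd": 12.0,
            "age_min": 25.0, "age_max": 79.0,
            "p_male": 0.68,
        })
    seed: int = 0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        probs = [self.q_miscode, self.p_record_indigenous, self.p_doc_present,
                 self.p_drug_given_diabetic, self.p_not_recorded]
        probs += list(self.p_code_diabetes.values())
        probs += list(self.prop_indigenous.values())
        for m in self.prev_diabetes.values():
            probs += list(m.values())
        for p in probs:
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p!r}")
        if self.admission_rate < 0:
            raise ValueError("admission_rate must be non-negative")
        windows = sorted(
            (( _as_date(a), _as_date(b)) for a, b in self.era_windows.values()))
        for (a, b) in windows:
            if b < a:
                raise ValueError("era window end precedes start")
        for (_, b), (a2, _) in zip(windows, windows[1:]):
            if a2 <= b:
                raise ValueError("era windows must be disjoint")
        if self.history_years < 15:
            logger.warning(
                "history_years=%d is shorter than the 15-year lookback; "
                "15-year windows will be truncated", self.history_years)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from a YAML (or JSON; YAML is a superset) file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "p_code_diabetes" in raw:
            raw["p_code_diabetes"] = {int(k): v
                                      for k, v in raw["p_code_diabetes"].items()}
        return cls(**raw)


def icd_version_for(date: dt.date) -> int:
    """ICD version in force on a given admission date (cutover 1999-07-01)."""
    return 9 if date < ICD10_CUTOVER else 10


def expected_lookback_sensitivity(p_code: float,
                                  pmf: Sequence[float]) -> float:
    """Closed-form ascertainment sensitivity under per-admission coding.

    A true case whose index admission is preceded by ``k`` admissions in the
    lookback window, each independently carrying the comorbidity code with
    probability ``p_code``, is detected with probability ``1-(1-p_code)**(k+1)``
    (index plus k priors).  Given the pmf of the prior-admission count K this
    returns ``sum_k pmf[k] * (1-(1-p_code)**(k+1))``.

    Parameters
    ----------
    p_code : per-admission coding probability, in [0, 1].
    pmf : pmf of the prior-admission count over k = 0, 1, ...; must sum to 1
        within 1e-9.
    """
    if not 0.0 <= p_code <= 1.0:
        raise ValueError("p_code must be in [0, 1]")
    pmf = np.asarray(pmf, dtype=float)
    if abs(pmf.sum() - 1.0) > 1e-9:
        raise ValueError("pmf must sum to 1 within 1e-9")
    k = np.arange(pmf.size)
    return float(np.sum(pmf * (1.0 - (1.0 - p_code) ** (k + 1))))


def _in_any_era_window(dates: np.ndarray, windows) -> np.ndarray:
    """Boolean mask of dates (as ordinals) falling inside any era window."""
    out = np.zeros(dates.shape, dtype=bool)
    for a, b in windows:
        out |= (dates >= a.toordinal()) & (dates <= b.toordinal())
    return out


def generate_linked_data(config: SimulationConfig):
    """Simulate linked admissions, medical-record entries and truth.

    Returns
    -------
    (admissions, medical_records, truth) : tuple of pandas.DataFrame
        See the module docstring for column schemas.  Deterministic for a
        fixed config (single numpy Generator stream seeded by ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov = config.covariate_params
    windows = [(_as_date(a), _as_date(b)) for a, b in config.era_windows.values()]

    adm_rows: list[tuple] = []
    mr_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for era in config.n_patients_per_era:
        n = int(config.n_patients_per_era[era])
        w0, w1 = (_as_date(x) for x in config.era_windows[era])
        span = (w1 - w0).days + 1

        indig = rng.random(n) < config.prop_indigenous[era]
        prev = np.where(indig,
                        config.prev_diabetes[era]["indigenous"],
                        config.prev_diabetes[era]["non_indigenous"])
        diabetic = rng.random(n) < prev
        age = np.clip(rng.normal(cov["age_mean"], cov["age_sd"], n),
                      cov["age_min"], cov["age_max"]).round(0)
        male = rng.random(n) < cov["p_male"]
        index_ord = w0.toordinal() + rng.integers(0, span, n)

        rate = config.admission_rate * np.where(
            diabetic, config.admission_rate_ratio_diabetic, 1.0)
        n_prior = rng.poisson(rate * config.history_years, n)

        for i in range(n):
            pid = f"{era}-{i:06d}"
            truth_rows.append((pid, era, int(diabetic[i]), int(indig[i]),
                               age[i], "M" if male[i] else "F"))

            # admission dates: index last, priors uniform over the history
            offs = rng.integers(1, max(config.history_years * 365, 2),
                                size=n_prior[i])
            dates = np.concatenate([[index_ord[i]], index_ord[i] - offs])
            k = dates.size
            versions = np.where(
                dates < ICD10_CUTOVER.toordinal(), 9, 10)
            p_dm = np.where(versions == 9,
                            config.p_code_diabetes[9], config.p_code_diabetes[10])
            if not diabetic[i]:
                p_dm = np.full(k, config.q_miscode)
            carries_dm = rng.random(k) < p_dm

            # principal diagnoses: index is CHD; priors are CHD only when the
            # date lies outside every era window (keeps exactly one
            # index-eligible CHD admission per sampled era window)
            chd_ok = ~_in_any_era_window(dates, windows)
            chd_ok[0] = True
            group = rng.choice(list(_CHD_GROUP_P), p=list(_CHD_GROUP_P.values()))
            prior_is_chd = (rng.random(k) < cov["p_prior_chd"]) & chd_ok
            prior_is_chd[0] = True

            n_comorb = np.minimum(
                rng.poisson(cov["comorbidity_poisson_mean"], k), 19)
            los = 1 + rng.poisson(cov["los_poisson_mean"], k)
            elective = rng.random(k) < cov["p_elective"]
            private = rng.random(k) < cov["p_private"]
            rural = rng.random(k) < cov["p_rural"]
            tin = rng.random(k) < cov["p_transfer"]
            tout = rng.random(k) < cov["p_transfer"]
            flag = (rng.random(k) < config.p_record_indigenous) & indig[i]
            died = np.zeros(k, dtype=bool)
            died[0] = rng.random() < cov["p_death_index"]

            for j in range(k):
                v = int(versions[j])
                if j == 0:
                    principal = rng.choice(_CHD_PRINCIPAL[(group, v)])
                elif prior_is_chd[j]:
                    g = rng.choice(list(_CHD_GROUP_P),
                                   p=list(_CHD_GROUP_P.values()))
                    principal = rng.choice(_CHD_PRINCIPAL[(g, v)])
                else:
                    principal = rng.choice(_NONCHD_PRINCIPAL[v])
                secondaries = list(rng.choice(_COMORBIDITY_POOL[v],
                                              size=n_comorb[j]))
                if carries_dm[j]:
                    # comorbidity coding: diabetes goes in a uniformly chosen
                    # secondary slot, never the principal field
                    pos = int(rng.integers(0, len(secondaries) + 1))
                    secondaries.insert(pos, rng.choice(_DIABETES_CODES[v]))
                d = dt.date.fromordinal(int(dates[j]))
                adm_rows.append((
                    pid, f"{pid}-A{j:03d}", d.isoformat(),
                    (d + dt.timedelta(days=int(los[j]))).isoformat(), v,
                    principal, ";".join(secondaries),
                    "elective" if elective[j] else "emergency",
                    "private" if private[j] else "public",
                    "rural" if rural[j] else "metropolitan",
                    int(tin[j]), int(tout[j]), int(died[j]), int(flag[j])))

            # medical-record reference entry for the index admission
            if diabetic[i]:
                present = rng.random() < config.p_doc_present
                drugs = rng.random() < config.p_drug_given_diabetic
                documented = "present" if present else "absent"
            else:
                drugs = False
                documented = ("not_recorded"
                              if rng.random() < config.p_not_recorded
                              else "absent")
            mr_rows.append((pid, f"{pid}-A000", era, documented, int(drugs)))

    admissions = pd.DataFrame(adm_rows, columns=[
        "person_id", "admission_id", "admission_date", "separation_date",
        "icd_version", "principal_diagnosis", "secondary_diagnoses",
        "admission_type", "hospital_type", "hospital_location",
        "transfer_in", "transfer_out", "died_in_hospital", "indigenous_flag"])
    medical_records = pd.DataFrame(mr_rows, columns=[
        "person_id", "index_admission_id", "era", "diabetes_documented",
        "diabetes_drug_treatment"])
    truth = pd.DataFrame(truth_rows, columns=[
        "person_id", "era", "true_diabetes", "true_indigenous", "age", "sex"])
    return admissions, medical_records, truth


def write_tables(admissions: pd.DataFrame, medical_records: pd.DataFrame,
                 truth: pd.DataFrame, out_dir) -> None:
    """Write the three tables as CSV (missing values as empty strings)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    admissions.to_csv(out / "admissions.csv", index=False)
    medical_records.to_csv(out / "medical_records.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
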