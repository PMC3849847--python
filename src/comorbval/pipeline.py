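"""End-to-end orchestration: simulate -> cohort -> ascertain -> concordance -> predictors.

Produces tidy delimited result tables per stratum and lookback window, a
predictors report, and a run manifest with row-count bookkeeping at each
stage (input = retained + excluded, per logged reason).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .ascertainment import (LookbackSpec, ascertain_cohort,
                            derive_history_covariates)
from .cohort import build_cohort, drop_not_recorded
from .concordance import (build_two_by_two, compare_measures,
                          concordance_measures, mcnemar_test)
from .predictors import derive_covariates, label_outcomes, predictor_analysis
from .synthetic import SimulationConfig, generate_linked_data, write_tables

logger = logging.getLogger("comorbval")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "results"
    #: simulate when no input tables are given
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    admissions_path: Optional[str] = None
    medical_records_path: Optional[str] = None
    truth_path: Optional[str] = None
    windows: Sequence = field(default_factory=lambda: LookbackSpec().windows)
    #: strata beyond the always-present era split; each must name a boolean
    #: cohort column (e.g. indigenous_derived)
    strata: Sequence[str] = field(default_factory=lambda: ["indigenous_derived"])
    drop_not_recorded: bool = False
    entry_p: float = 0.05
    seed: int = 0
    log_level: str = "INFO"
    age_bounds: Optional[Mapping[str, Sequence[float]]] = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if "p_code_diabetes" in sim:
                sim["p_code_diabetes"] = {int(k): v
                                          for k, v in sim["p_code_diabetes"].items()}
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _load_or_simulate(config: PipelineConfig, manifest: dict):
    if config.admissions_path:
        admissions = pd.read_csv(config.admissions_path,
                                 keep_default_na=False, na_values=[])
        medical_records = pd.read_csv(config.medical_records_path,
                                      keep_default_na=False, na_values=[])
        truth = (pd.read_csv(config.truth_path)
                 if config.truth_path else None)
        manifest["source"] = "files"
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        admissions, medical_records, truth = generate_linked_data(sim)
        manifest["source"] = "simulated"
    manifest["n_admissions"] = len(admissions)
    manifest["n_medical_records"] = len(medical_records)
    return admissions, medical_records, truth


def _concordance_tables(cohort, ascertainment, strata):
    """Tidy concordance results per stratum x window, plus era comparisons."""
    merged = cohort.merge(ascertainment, on=["person_id", "era"])
    strata_defs = {"era:" + era: merged["era"] == era
                   for era in sorted(merged["era"].unique())}
    for col in strata:
        if col not in merged.columns:
            logger.warning("stratum column %s missing; skipped", col)
            continue
        for era in sorted(merged["era"].unique()):
            for val in (True, False):
                label = f"era:{era}|{col}:{val}"
                strata_defs[label] = ((merged["era"] == era)
                                      & (merged[col].astype(bool) == val))

    rows, tables = [], {}
    for label, mask in strata_defs.items():
        for window in merged.loc[mask, "window"].unique():
            cell = merged.loc[mask & (merged["window"] == window)]
            if cell.empty:
                continue
            t = build_two_by_two(cell["reference_diabetes"],
                                 cell["administrative_diabetes"])
            tables[(label, window)] = t
            rep = concordance_measures(t, stratum=label, window=window)
            mc = mcnemar_test(t)
            rows.append({
                "stratum": label, "window": window, "n": t.n,
                "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
                "observed_agreement": rep.observed_agreement,
                "kappa": rep.kappa, "sensitivity": rep.sensitivity,
                "specificity": rep.specificity, "ppv": rep.ppv,
                "npv": rep.npv, "under_over": rep.under_over,
                "mcnemar_statistic": mc.statistic, "mcnemar_p": mc.p_value,
            })
    results = pd.DataFrame(rows)

    # between-era comparisons per window (the two samples are independent)
    eras = sorted(merged["era"].unique())
    comp_rows = []
    if len(eras) == 2:
        for window in merged["window"].unique():
            ka, kb = ("era:" + eras[0], window), ("era:" + eras[1], window)
            if ka in tables and kb in tables:
                for m, res in compare_measures(tables[ka], tables[kb]).items():
                    comp_rows.append({"window": window, "measure": m,
                                      "method": res.method,
                                      "statistic": res.statistic,
                                      "p_value": res.p_value})
    comparisons = pd.DataFrame(comp_rows)
    return results, comparisons


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the in-memory bundle: cohort, ascertainment, concordance,
    comparisons, predictors screen/model tables and the manifest dict.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "comorbval_version": __version__}

    admissions, medical_records, truth = _load_or_simulate(config, manifest)
    era_windows = config.simulation.era_windows
    cohort = build_cohort(admissions, medical_records, era_windows,
                          age_bounds=config.age_bounds, truth=truth)
    manifest["n_index_selected"] = cohort.attrs["n_index_selected"]
    manifest["n_missing_medical_record"] = cohort.attrs["n_missing_medical_record"]
    manifest["n_cohort"] = len(cohort)
    if config.drop_not_recorded:
        before = len(cohort)
        cohort = drop_not_recorded(cohort)
        manifest["n_dropped_not_recorded"] = before - len(cohort)
        manifest["n_cohort_analysed"] = len(cohort)

    spec = LookbackSpec(tuple(config.windows))
    asc = ascertain_cohort(cohort, admissions, spec)
    hist_cov = derive_history_covariates(cohort, admissions)

    results, comparisons = _concordance_tables(cohort, asc, config.strata)

    cov = derive_covariates(cohort, hist_cov)
    labelled = label_outcomes(cov, asc)
    screens, model_tables = [], []
    for era in sorted(labelled["era"].unique()):
        for outcome in ("outcome_fn", "outcome_fp"):
            screen, model = predictor_analysis(
                labelled, outcome, era, entry_p=config.entry_p)
            screen.insert(0, "era", era)
            screen.insert(1, "outcome", outcome)
            screens.append(screen)
            manifest[f"model_fitted_{era}_{outcome}"] = model is not None
            if model is not None:
                t = model.table.copy()
                t.insert(0, "era", era)
                t.insert(1, "outcome", outcome)
                t["converged"] = model.converged
                t["n"] = model.n
                model_tables.append(t)
    non_empty = [s for s in screens if not s.empty]
    screen_df = (pd.concat(non_empty, ignore_index=True)
                 if non_empty else screens[0])
    model_df = (pd.concat(model_tables, ignore_index=True)
                if model_tables else pd.DataFrame())

    cohort.to_csv(out / "cohort.csv", index=False)
    asc.to_csv(out / "ascertainment.csv", index=False)
    results.to_csv(out / "concordance.csv", index=False)
    comparisons.to_csv(out / "era_comparisons.csv", index=False)
    screen_df.to_csv(out / "predictor_screen.csv", index=False)
    model_df.to_csv(out / "predictor_models.csv", index=False)
    if manifest["source"] == "simulated":
        write_tables(admissions, medical_records, truth, out / "simulated")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"cohort": cohort, "ascertainment": asc, "concordance": results,
            "comparisons": comparisons, "predictor_screen": screen_df,
            "predictor_models": model_df, "manifest": manifest}
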