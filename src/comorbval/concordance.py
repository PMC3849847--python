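"""Concordance statistics for administrative vs medical-record diabetes status.

The administrative determination is the test, the medical record the
reference standard.  All rate measures are reported as percentages to one
decimal (round half away from zero, matching epidemiological table
conventions), with kappa likewise on the percentage scale.  The
under/over-estimation statistic ``(Sensitivity/PPV - 1) x 100`` summarises net
prevalence bias: negative values mean the administrative source undercounts
true cases relative to the cases it flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("comorbval")

_MEASURES = ("observed_agreement", "sensitivity", "specificity",
             "ppv", "npv", "kappa")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (4.45 -> 4.5, -4.45 -> -4.5)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass(frozen=True)
class TwoByTwoTable:
    """Paired 2x2 counts: test = administrative status, reference = medical record."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 or int(c) != c for c in cells):
            raise ValueError(f"cell counts must be non-negative integers: {cells}")
        if sum(cells) < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_two_by_two(reference: Sequence[bool],
                     test: Sequence[bool]) -> TwoByTwoTable:
    """Cross-classify paired reference/test booleans into a TwoByTwoTable."""
    ref = np.asarray(reference, dtype=bool)
    tst = np.asarray(test, dtype=bool)
    if ref.shape != tst.shape:
        raise ValueError("reference and test vectors must have equal length")
    return TwoByTwoTable(
        tp=int(np.sum(ref & tst)), fp=int(np.sum(~ref & tst)),
        fn=int(np.sum(ref & ~tst)), tn=int(np.sum(~ref & ~tst)))


@dataclass
class ConcordanceReport:
    """All concordance measures for one stratum x lookback-window cell.

    Percentage fields are rounded to one decimal; ``raw`` holds the unrounded
    proportions (0-1 scale, kappa on its natural scale) for downstream
    arithmetic.  Measures with a zero denominator are NaN and listed in
    ``undefined`` rather than silently reported as 0.
    """

    observed_agreement: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float
    under_over: float
    stratum: str = ""
    window: str = ""
    raw: dict = field(default_factory=dict)
    undefined: tuple = ()


def concordance_measures(t: TwoByTwoTable, stratum: str = "",
                         window: str = "") -> ConcordanceReport:
    """Observed agreement, Se, Sp, PPV, NPV, Cohen's kappa and under/over.

    Kappa uses the standard chance-corrected form
    ``(p_o - p_e) / (1 - p_e)`` with
    ``p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)] / n**2``.
    """
    n = t.n
    raw, undefined = {}, []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    raw["observed_agreement"] = (t.tp + t.tn) / n
    raw["sensitivity"] = ratio(t.tp, t.tp + t.fn, "sensitivity")
    raw["specificity"] = ratio(t.tn, t.tn + t.fp, "specificity")
    raw["ppv"] = ratio(t.tp, t.tp + t.fp, "ppv")
    raw["npv"] = ratio(t.tn, t.tn + t.fn, "npv")

    p_o = raw["observed_agreement"]
    p_e = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / n**2
    if p_e == 1.0:
        undefined.append("kappa")
        raw["kappa"] = float("nan")
    else:
        raw["kappa"] = (p_o - p_e) / (1.0 - p_e)

    if math.isnan(raw["ppv"]) or raw["ppv"] == 0 or math.isnan(raw["sensitivity"]):
        undefined.append("under_over")
        raw["under_over"] = float("nan")
    else:
        raw["under_over"] = (raw["sensitivity"] / raw["ppv"] - 1.0) * 100.0

    return ConcordanceReport(
        **{m: round_half_away(raw[m] * 100.0) for m in _MEASURES},
        under_over=round_half_away(raw["under_over"]),
        stratum=stratum, window=window, raw=raw, undefined=tuple(undefined))


def under_over_estimation(sensitivity: float, ppv: float) -> float:
    """Net under(-)/over(+)-estimation: ``(Sensitivity/PPV - 1) x 100``.

    Inputs are percentages as printed in a concordance table; the result is a
    signed percentage rounded to one decimal.
    """
    if ppv is None or ppv == 0 or math.isnan(ppv):
        return float("nan")
    return round_half_away((sensitivity / ppv - 1.0) * 100.0)


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    p_value: float
    df: Optional[int] = None


#: below this many discordant pairs McNemar falls back to the exact binomial
MCNEMAR_EXACT_THRESHOLD = 25


def mcnemar_test(t: TwoByTwoTable) -> ComparisonResult:
    """McNemar's test of marginal homogeneity (paired prevalence difference).

    Large-sample form ``(fn-fp)**2 / (fn+fp)`` against chi-square(1), no
    continuity correction; with fewer than 25 discordant pairs the p-value
    comes from the exact two-sided binomial on the discordant split.
    """
    d = t.fn + t.fp
    if d == 0:
        return ComparisonResult("mcnemar", 0.0, 1.0, df=1)
    statistic = (t.fn - t.fp) ** 2 / d
    if d < MCNEMAR_EXACT_THRESHOLD:
        k = min(t.fn, t.fp)
        p = min(1.0, 2.0 * stats.binom.cdf(k, d, 0.5))
        return ComparisonResult("mcnemar_exact", float(statistic), float(p), df=None)
    p = stats.chi2.sf(statistic, df=1)
    return ComparisonResult("mcnemar", float(statistic), float(p), df=1)


def _measure_two_by_two(t: TwoByTwoTable, measure: str):
    """The 2x2 success/failure split underlying each rate measure."""
    return {
        "sensitivity": (t.tp, t.fn),
        "specificity": (t.tn, t.fp),
        "ppv": (t.tp, t.fp),
        "npv": (t.tn, t.fn),
        "observed_agreement": (t.tp + t.tn, t.fp + t.fn),
    }[measure]


def _log_ratio_var(t: TwoByTwoTable) -> float:
    """Delta-method variance of log(Sens/PPV) = log(test+) - log(ref+).

    Treats (tp, fp, fn, tn) as one multinomial draw of size n, so the two
    margins are correlated through the shared tp cell.
    """
    n = t.n
    a = (t.tp + t.fp) / n   # test-positive margin
    b = (t.tp + t.fn) / n   # reference-positive margin
    c = t.tp / n - a * b    # Cov(test+, ref+)/n on the proportion scale
    if a == 0 or b == 0:
        return float("nan")
    return (a * (1 - a) / a**2 + b * (1 - b) / b**2 - 2 * c / (a * b)) / n


def compare_measures(table_a: TwoByTwoTable, table_b: TwoByTwoTable,
                     measures: Sequence[str] = None) -> dict:
    """Between-sample comparison of concordance measures (independent samples).

    Rate measures are compared by a Pearson chi-square on each measure's own
    success/failure 2x2; the under/over-estimation statistic by a two-sample
    z on log(Sens/PPV) with delta-method multinomial variance.  Measures with
    an empty denominator in either sample are skipped with a log entry.
    """
    measures = measures or ("observed_agreement", "sensitivity", "specificity",
                            "ppv", "npv", "under_over")
    out = {}
    for m in measures:
        if m == "under_over":
            va, vb = _log_ratio_var(table_a), _log_ratio_var(table_b)
            if math.isnan(va) or math.isnan(vb):
                logger.info("skipping under_over comparison: empty margin")
                continue
            ra = math.log((table_a.tp + table_a.fp) / (table_a.tp + table_a.fn))
            rb = math.log((table_b.tp + table_b.fp) / (table_b.tp + table_b.fn))
            se = math.sqrt(va + vb)
            z = 0.0 if se == 0 else (ra - rb) / se
            out[m] = ComparisonResult("z_ratio", float(z),
                                      float(2 * stats.norm.sf(abs(z))))
            continue
        sa, fa = _measure_two_by_two(table_a, m)
        sb, fb = _measure_two_by_two(table_b, m)
        if sa + fa == 0 or sb + fb == 0:
            logger.info("skipping %s comparison: zero denominator", m)
            continue
        obs = np.array([[sa, fa], [sb, fb]])
        if obs.sum(axis=0).min() == 0:
            # degenerate margin (e.g. both samples at 100%): no heterogeneity
            out[m] = ComparisonResult("chi_square", 0.0, 1.0, df=1)
            continue
        stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
        out[m] = ComparisonResult("chi_square", float(stat), float(p), df=int(dof))
    return out


def bootstrap_under_over_comparison(table_a: TwoByTwoTable,
                                    table_b: TwoByTwoTable,
                                    n_boot: int = 2000,
                                    seed: int = 0) -> ComparisonResult:
    """Percentile-bootstrap cross-check of the under/over z comparison.

    Resamples each table as a multinomial, computes the difference of
    log(Sens/PPV) per replicate, and inverts the percentile interval into an
    approximate two-sided p-value.  Provided as a labelled cross-check of the
    delta-method z construction, not as the primary test.
    """
    rng = np.random.default_rng(seed)

    def log_ratio(cells):
        tp, fp, fn, _ = cells
        if tp + fp == 0 or tp + fn == 0:
            return np.nan
        return math.log((tp + fp) / (tp + fn))

    diffs = np.empty(n_boot)
    pa = np.array([table_a.tp, table_a.fp, table_a.fn, table_a.tn]) / table_a.n
    pb = np.array([table_b.tp, table_b.fp, table_b.fn, table_b.tn]) / table_b.n
    for i in range(n_boot):
        ca = rng.multinomial(table_a.n, pa)
        cb = rng.multinomial(table_b.n, pb)
        diffs[i] = log_ratio(ca) - log_ratio(cb)
    diffs = diffs[~np.isnan(diffs)]
    point = log_ratio([table_a.tp, table_a.fp, table_a.fn, table_a.tn]) - \
        log_ratio([table_b.tp, table_b.fp, table_b.fn, table_b.tn])
    # p from the bootstrap distribution centred at the point estimate
    shifted = diffs - point
    p = 2 * min(np.mean(shifted <= -abs(point)) + 0.5 / len(shifted),
                np.mean(shifted >= abs(point)) + 0.5 / len(shifted))
    return ComparisonResult("bootstrap_z_ratio", float(point), float(min(1.0, p)))
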