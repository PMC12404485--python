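"""Subgroup (sex, age) stratified screens and two-drug comparative
disproportionality via the difference of log reporting odds ratios.

For two drugs whose report sets are disjoint (each is the other's
comparator background after primary-suspect assignment), the
log-scale standard error of each ROR is recovered from its 95% CI as
ln(hi/lo)/(2 * 1.96), and

    delta   = ln ROR_A - ln ROR_B,   SE = sqrt(SE_A^2 + SE_B^2),
    95% CI  = delta +/- 1.96 SE,     z = delta / SE   (two-tailed normal p),

the usual independent log-normal approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from . import contingency, signals
from .ingest import CaseReport, flag_target

logger = logging.getLogger(__name__)

Z95 = signals.Z95

#: Age strata: <65 is [0, 65); 65-85 is [65, 85]; >85 is (85, inf).
AGE_BINS = {"<65": (0.0, 65.0), "65-85": (65.0, 85.0001), ">85": (85.0001, float("inf"))}
SEX_LEVELS = ("male", "female")


@dataclass(frozen=True)
class DeltaComparison:
    term: str
    ror_a: float
    ror_b: float
    delta_lnror: float
    ci_lo: float
    ci_hi: float
    z: float
    p: float


def in_stratum(report: CaseReport, variable: str, level: str) -> bool:
    """Whether a report belongs to a sex or age stratum.

    Reports with the variable missing belong to no stratum of it.
    """
    if variable == "sex":
        if level not in SEX_LEVELS:
            raise ValueError(f"unknown sex level {level!r}")
        return report.sex == level
    if variable == "age":
        if level not in AGE_BINS:
            raise ValueError(f"unknown age level {level!r}")
        lo, hi = AGE_BINS[level]
        return report.age_years is not None and lo <= report.age_years < hi
    raise ValueError(f"unknown stratification variable {variable!r}")


def stratified_screen(
    reports: list[CaseReport],
    variable: str,
    level: str,
    alpha: float = 0.05,
    min_a: int = 3,
) -> pd.DataFrame:
    """PT signal screen within one stratum.

    Both target and comparator reports are restricted to the stratum, the
    2x2 tables are rebuilt and the full four-algorithm screen re-run.
    """
    subset = [r for r in reports if in_stratum(r, variable, level)]
    if not any(r.is_target for r in subset):
        logger.warning("stratified_screen: no target reports in %s=%s", variable, level)
        return signals.screen_pt([], alpha=alpha, min_a=min_a)
    tables = contingency.build_tables(subset, level="pt", min_a=min_a)
    return signals.screen_pt(tables, alpha=alpha, min_a=min_a)


def se_from_ci(lo: float, hi: float, z: float = Z95) -> float:
    """Log-scale standard error implied by a ratio's confidence interval."""
    if lo <= 0 or hi <= 0:
        raise ValueError("confidence bounds must be positive")
    if hi < lo:
        raise ValueError("upper bound below lower bound")
    return math.log(hi / lo) / (2.0 * z)


def delta_lnror(
    term: str,
    ror_a: float,
    ci_a: tuple[float, float],
    ror_b: float,
    ci_b: tuple[float, float],
) -> DeltaComparison:
    """Head-to-head comparison of one shared PT between two drugs."""
    if ror_a <= 0 or ror_b <= 0:
        raise ValueError("RORs must be positive")
    se = math.hypot(se_from_ci(*ci_a), se_from_ci(*ci_b))
    delta = math.log(ror_a) - math.log(ror_b)
    if se == 0:
        raise ValueError("degenerate (zero) combined standard error")
    z = delta / se
    return DeltaComparison(
        term=term,
        ror_a=ror_a,
        ror_b=ror_b,
        delta_lnror=delta,
        ci_lo=delta - Z95 * se,
        ci_hi=delta + Z95 * se,
        z=z,
        p=float(2.0 * sps.norm.sf(abs(z))),
    )


def partition_terms(
    signals_a: pd.DataFrame, signals_b: pd.DataFrame
) -> tuple[list[str], list[str], list[str]]:
    """Partition the two screens' significant PTs into (shared, only_a,
    only_b), each sorted alphabetically."""
    terms_a = set(signals_a.loc[signals_a["significant"], "term"])
    terms_b = set(signals_b.loc[signals_b["significant"], "term"])
    return (sorted(terms_a & terms_b),
            sorted(terms_a - terms_b),
            sorted(terms_b - terms_a))


def comparative_analysis(
    reports: list[CaseReport],
    patterns_a: list[str],
    patterns_b: list[str],
    alpha: float = 0.05,
    min_a: int = 3,
) -> dict:
    """Run both drugs' screens against the all-other-drugs background,
    partition their significant PTs, and compute delta ln ROR for every
    shared PT.

    Returns a dict with keys ``screen_a``, ``screen_b``, ``shared``,
    ``only_a``, ``only_b`` and ``deltas`` (a DataFrame, one row per shared
    PT: both RORs with CIs, delta, CI, z, p).
    """
    screens = {}
    for key, patterns in (("a", patterns_a), ("b", patterns_b)):
        flagged = flag_target(reports, patterns)
        tables = contingency.build_tables(flagged, level="pt", min_a=min_a)
        screens[key] = signals.screen_pt(tables, alpha=alpha, min_a=min_a)
    shared, only_a, only_b = partition_terms(screens["a"], screens["b"])

    rows = []
    for term in shared:
        ra = screens["a"].set_index("term").loc[term]
        rb = screens["b"].set_index("term").loc[term]
        d = delta_lnror(term, ra["ror"], (ra["ror_lo"], ra["ror_hi"]),
                        rb["ror"], (rb["ror_lo"], rb["ror_hi"]))
        rows.append({
            "term": term,
            "ror_a": d.ror_a, "ror_a_lo": ra["ror_lo"], "ror_a_hi": ra["ror_hi"],
            "ror_b": d.ror_b, "ror_b_lo": rb["ror_lo"], "ror_b_hi": rb["ror_hi"],
            "delta_lnror": d.delta_lnror, "ci_lo": d.ci_lo, "ci_hi": d.ci_hi,
            "z": d.z, "p": d.p,
        })
    return {
        "screen_a": screens["a"], "screen_b": screens["b"],
        "shared": shared, "only_a": only_a, "only_b": only_b,
        "deltas": pd.DataFrame(rows, columns=[
            "term", "ror_a", "ror_a_lo", "ror_a_hi", "ror_b", "ror_b_lo",
            "ror_b_hi", "delta_lnror", "ci_lo", "ci_hi", "z", "p"]),
    }
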