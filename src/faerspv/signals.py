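"""The four disproportionality algorithms and the joint decision rule.

For a 2x2 table (a, b, c, d) with N = a + b + c + d:

    ROR   = ad / bc, with 95% CI exp(ln ROR +/- 1.96 s),
            s = sqrt(1/a + 1/b + 1/c + 1/d)
    PRR   = a(c + d) / (c(a + b)), with the Pearson chi-square
            chi2 = (ad - bc)^2 N / ((a+b)(c+d)(a+c)(b+d))   (no Yates correction)
    BCPNN IC    = log2( aN / ((a+c)(a+b)) ),
          IC025 = IC - 2 sqrt(1/(a+1)) / ln 2
    MGPS  EBGM  = aN / ((a+c)(a+b))   (the point-estimate observed/expected
          form, so IC = log2(EBGM) identically),
          EBGM05 = EBGM * exp(-1.645 s)   (one-sided 5th percentile)

A term is a joint-rule signal when all four criteria hold simultaneously
(ROR lower bound > 1, ROR >= 2, a >= 3; PRR >= 2 with chi2 >= 4 and a >= 3;
IC025 > 0; EBGM05 > 2); the candidates' chi-square p-values are then
adjusted by Benjamini-Hochberg and signals require q < alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .contingency import ContingencyTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile
EBGM05_MULT = 1.645  # one-sided 5th-percentile multiplier


@dataclass(frozen=True)
class SignalMetrics:
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    chi2_p: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    corrected: bool = False  # Haldane-Anscombe 0.5 correction applied


@dataclass(frozen=True)
class SignalDecision:
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_mgps: bool
    pass_all: bool
    fdr_q: float | None = None
    significant: bool = False


def ic025_lower(ic: float, a: float) -> float:
    """Lower 95% credibility bound of the information component."""
    return ic - 2.0 * math.sqrt(1.0 / (a + 1.0)) / math.log(2.0)


def compute_metrics(
    t: ContingencyTable, ebgm05_mult: float = EBGM05_MULT
) -> SignalMetrics:
    """All four algorithms' point estimates and interval bounds for one table.

    If b, c or d is zero, 0.5 is added to all four cells for estimation
    (Haldane-Anscombe) and the result is flagged ``corrected``.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) < 0:
        raise ValueError("negative contingency cell")
    corrected = t.needs_correction
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d

    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror = a * d / (b * c)
    ror_lo, ror_hi = ror * math.exp(-Z95 * s), ror * math.exp(Z95 * s)

    prr = a * (c + d) / (c * (a + b))
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    chi2_p = float(sps.chi2.sf(chi2, df=1))

    ebgm = a * n / ((a + c) * (a + b))
    ebgm05 = ebgm * math.exp(-ebgm05_mult * s)
    ic = math.log2(ebgm)
    ic025 = ic025_lower(ic, a)

    return SignalMetrics(ror, ror_lo, ror_hi, prr, chi2, chi2_p,
                         ic, ic025, ebgm, ebgm05, corrected)


def classify(
    m: SignalMetrics,
    a: float,
    min_a: int = 3,
    require_ror_ci: bool = True,
) -> SignalDecision:
    """Per-algorithm threshold verdicts and their conjunction.

    ``require_ror_ci`` additionally demands the ROR CI lower bound exceed 1
    (the conventional ROR signal rule) on top of ROR >= 2.
    """
    pass_ror = m.ror >= 2.0 and a >= min_a
    if require_ror_ci:
        pass_ror = pass_ror and m.ror_lo > 1.0
    pass_prr = m.prr >= 2.0 and m.chi2 >= 4.0 and a >= min_a
    pass_bcpnn = m.ic025 > 0.0
    pass_mgps = m.ebgm05 > 2.0
    return SignalDecision(
        pass_ror=pass_ror,
        pass_prr=pass_prr,
        pass_bcpnn=pass_bcpnn,
        pass_mgps=pass_mgps,
        pass_all=pass_ror and pass_prr and pass_bcpnn and pass_mgps,
    )


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_METRIC_COLS = ["ror", "ror_lo", "ror_hi", "prr", "chi2", "chi2_p",
                "ic", "ic025", "ebgm", "ebgm05"]


def metrics_frame(
    tables: list[ContingencyTable], ebgm05_mult: float = EBGM05_MULT
) -> pd.DataFrame:
    """One row per table: cells plus all metric columns."""
    rows = []
    for t in tables:
        m = compute_metrics(t, ebgm05_mult=ebgm05_mult)
        row = {"term": t.term, "level": t.level,
               "a": t.a, "b": t.b, "c": t.c, "d": t.d,
               "eligible": t.eligible, "corrected": m.corrected}
        row.update({k: getattr(m, k) for k in _METRIC_COLS})
        rows.append(row)
    return pd.DataFrame(rows)


def screen_pt(
    tables: list[ContingencyTable],
    alpha: float = 0.05,
    min_a: int = 3,
    require_ror_ci: bool = True,
    fdr_scope: str = "candidates",
) -> pd.DataFrame:
    """Full PT-level signal screen.

    Computes metrics for every table, applies the joint four-algorithm rule
    to eligible tables, BH-adjusts the chi-square p-values (by default over
    the joint-positive candidate set only), and marks as significant the
    candidates with q < alpha.  Returns the full table — metrics, per-
    algorithm flags, q-values and the final verdict — sorted by ROR
    descending.
    """
    if fdr_scope not in ("candidates", "all"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    df = metrics_frame(tables)
    if df.empty:
        for col in ["pass_ror", "pass_prr", "pass_bcpnn", "pass_mgps",
                    "pass_all", "fdr_q", "significant"]:
            df[col] = []
        return df
    decisions = [
        classify(
            SignalMetrics(**{k: row[k] for k in _METRIC_COLS},
                          corrected=row["corrected"]),
            a=row["a"],
            min_a=min_a,
            require_ror_ci=require_ror_ci,
        )
        for row in df.to_dict("records")
    ]
    for flag in ("pass_ror", "pass_prr", "pass_bcpnn", "pass_mgps", "pass_all"):
        df[flag] = [getattr(d, flag) for d in decisions]
    df["pass_all"] &= df["eligible"]

    df["fdr_q"] = np.nan
    scope = df.index if fdr_scope == "all" else df.index[df["pass_all"]]
    if len(scope):
        df.loc[scope, "fdr_q"] = adjust_fdr(df.loc[scope, "chi2_p"].to_numpy())
    df["significant"] = df["pass_all"] & (df["fdr_q"] < alpha)
    return df.sort_values("ror", ascending=False, ignore_index=True)


def screen_soc(tables: list[ContingencyTable]) -> pd.DataFrame:
    """SOC-level screen: SOCs with ROR >= 2 are significant.

    Returns all SOC tables with metrics attached and a ``significant``
    flag, sorted by ROR descending.
    """
    df = metrics_frame(tables)
    if df.empty:
        df["significant"] = []
        return df
    df["significant"] = df["ror"] >= 2.0
    return df.sort_values("ror", ascending=False, ignore_index=True)
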