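"""2x2 disproportionality tables at PT or SOC level.

For a target drug and one adverse-event term the cells are

    a  reports with the target drug AND the term
    b  target-drug reports without the term
    c  comparator ("all other drugs") reports with the term
    d  comparator reports without the term

Counting is report-level: a report contributes at most once per distinct
term, however many times the term repeats within it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .ingest import CaseReport

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    term: str
    level: str  # "pt" or "soc"
    a: float
    b: float
    c: float
    d: float
    eligible: bool = True  # a >= min_a at construction time

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def needs_correction(self) -> bool:
        """True when a zero cell would make the odds ratio degenerate."""
        return 0 in (self.b, self.c, self.d)


def _term_sets(report: CaseReport, level: str) -> frozenset[str]:
    if level == "pt":
        return report.events
    if level == "soc":
        return report.socs
    raise ValueError(f"unknown level {level!r} (expected 'pt' or 'soc')")


def build_tables(
    reports: list[CaseReport],
    level: str = "pt",
    min_a: int = 3,
) -> list[ContingencyTable]:
    """Build one table per term observed in at least one target report.

    Tables with ``a < min_a`` are still emitted but flagged ineligible for
    signal classification (the conventional minimum co-occurrence count is
    3).  Reports must already be deduplicated and target-flagged.
    """
    n_target = sum(r.is_target for r in reports)
    n_comp = len(reports) - n_target
    if n_target == 0:
        logger.warning("build_tables: no target reports; returning empty list")
        return []

    target_counts: dict[str, int] = {}
    comp_counts: dict[str, int] = {}
    for r in reports:
        counts = target_counts if r.is_target else comp_counts
        for term in _term_sets(r, level):
            counts[term] = counts.get(term, 0) + 1

    tables = []
    for term in sorted(target_counts):
        a = target_counts[term]
        c = comp_counts.get(term, 0)
        tables.append(
            ContingencyTable(
                term=term,
                level=level,
                a=a,
                b=n_target - a,
                c=c,
                d=n_comp - c,
                eligible=a >= min_a,
            )
        )
    return tables


def to_frame(tables: list[ContingencyTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": t.term, "level": t.level, "a": t.a, "b": t.b,
             "c": t.c, "d": t.d, "eligible": t.eligible}
            for t in tables
        ]
    )
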