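"""Ingestion of FAERS-style quarterly ASCII extracts.

FAERS ships one ``$``-delimited text file per table (``DEMO``, ``DRUG``,
``REAC``, optionally ``THER``), first line a header, dates as ``YYYYMMDD``
integers that may be truncated to ``YYYYMM`` or ``YYYY`` when the reporter
only knew the month or year.  This module reads that dialect into
:class:`CaseReport` records, normalizes demographics, applies the cleaning
and deduplication rules, flags target-drug reports and attaches
system-organ-class (SOC) labels from a user-supplied PT->SOC table.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: FAERS role codes: primary suspect, secondary suspect, concomitant, interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

_AGE_UNIT_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
    "": 1.0,  # blank unit: assume years (FAERS convention)
}

_SEX = {"M": "male", "F": "female"}
_SEX_BACK = {"male": "M", "female": "F", "unknown": ""}

_REPORTER = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "HP": "health-professional",
    "OT": "other",
    "LW": "other",
}
_REPORTER_BACK = {
    "consumer": "CN",
    "physician": "MD",
    "pharmacist": "PH",
    "health-professional": "HP",
    "other": "OT",
    "missing": "",
}


def parse_faers_date(raw: str | None) -> dt.date | None:
    """Parse an 8-digit ``YYYYMMDD`` string into a date.

    Truncated (``YYYYMM`` / ``YYYY``) or malformed values return ``None`` —
    partial dates are kept only as raw strings and are excluded from any
    interval arithmetic downstream.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if len(raw) != 8 or not raw.isdigit():
        return None
    try:
        return dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
    except ValueError:
        return None


def normalize_age(value: str | None, unit: str | None) -> float | None:
    """Convert a FAERS (AGE, AGE_COD) pair to years; unparseable -> None."""
    if value is None:
        return None
    value = str(value).strip()
    if not value:
        return None
    try:
        num = float(value)
    except ValueError:
        return None
    factor = _AGE_UNIT_YEARS.get((unit or "").strip().upper())
    if factor is None:
        return None
    years = num * factor
    return years if years >= 0 else None


@dataclass
class DrugEntry:
    """One drug row of a report: name, FAERS role code, optional start date."""

    name: str
    role: str = "PS"
    start_date_raw: str = ""
    dose: str = ""
    indication: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown FAERS role code {self.role!r}")

    @property
    def start_date(self) -> dt.date | None:
        return parse_faers_date(self.start_date_raw)


@dataclass
class CaseReport:
    """One (eventually deduplicated) safety report."""

    primary_id: str
    case_id: str
    sex: str = "unknown"  # male / female / unknown
    age_years: float | None = None
    country: str | None = None
    reporter_type: str = "missing"
    fda_date_raw: str = ""
    event_date_raw: str = ""
    drugs: list[DrugEntry] = field(default_factory=list)
    events: frozenset[str] = field(default_factory=frozenset)
    socs: frozenset[str] = field(default_factory=frozenset)
    is_target: bool = False

    @property
    def fda_date(self) -> dt.date | None:
        return parse_faers_date(self.fda_date_raw)

    @property
    def event_date(self) -> dt.date | None:
        return parse_faers_date(self.event_date_raw)

    @property
    def report_year(self) -> int | None:
        raw = self.fda_date_raw.strip()
        return int(raw[:4]) if len(raw) >= 4 and raw[:4].isdigit() else None

    def primary_suspect(self) -> DrugEntry | None:
        for d in self.drugs:
            if d.role == "PS":
                return d
        return None


class IngestionError(RuntimeError):
    """A mandatory file is missing or a header does not match the dialect."""


_DEMO_COLS = [
    "primaryid", "caseid", "fda_dt", "event_dt",
    "age", "age_cod", "sex", "occp_cod", "occr_country",
]
_DRUG_COLS = ["primaryid", "drug_seq", "role_cod", "drugname"]
_REAC_COLS = ["primaryid", "pt"]
_THER_COLS = ["primaryid", "dsg_drug_seq", "start_dt"]


def _read_table(path: Path, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise IngestionError(f"{path.name}: header lacks columns {missing}")
    return df


def _find_file(directory: Path, stem: str) -> Path | None:
    for p in sorted(directory.iterdir()):
        if p.is_file() and p.name.upper().startswith(stem):
            return p
    return None


def clean_reports(reports: list[CaseReport]) -> list[CaseReport]:
    """Drop reports with no adverse-event terms, no drug entries, or an
    implausible age (> 150 years).  Missing sex/age/country are retained as
    their own category, as spontaneous-reporting analyses tabulate them."""
    kept = []
    dropped = {"no_event": 0, "no_drug": 0, "implausible_age": 0}
    for r in reports:
        if not r.events:
            dropped["no_event"] += 1
        elif not r.drugs:
            dropped["no_drug"] += 1
        elif r.age_years is not None and r.age_years > 150:
            dropped["implausible_age"] += 1
        else:
            kept.append(r)
    if any(dropped.values()):
        logger.info("clean_reports dropped %s", dropped)
    return kept


def read_quarter(directory: str | Path, clean: bool = True) -> list[CaseReport]:
    """Read one FAERS-style quarter (DEMO/DRUG/REAC, optional THER).

    One CaseReport per DEMO row, joined on primary id.  Orphan DRUG/REAC
    rows (no matching DEMO row) are dropped with a warning; unparseable ages
    and dates become missing values, never errors.
    """
    directory = Path(directory)
    paths = {}
    for stem in ("DEMO", "DRUG", "REAC"):
        p = _find_file(directory, stem)
        if p is None:
            raise IngestionError(f"mandatory file {stem}* not found in {directory}")
        paths[stem] = p
    ther_path = _find_file(directory, "THER")

    demo = _read_table(paths["DEMO"], _DEMO_COLS)
    drug = _read_table(paths["DRUG"], _DRUG_COLS).drop_duplicates()
    reac = _read_table(paths["REAC"], _REAC_COLS).drop_duplicates()
    ther = (
        _read_table(ther_path, _THER_COLS).drop_duplicates()
        if ther_path is not None
        else pd.DataFrame(columns=_THER_COLS)
    )

    known_ids = set(demo["primaryid"])
    for name, df in (("DRUG", drug), ("REAC", reac)):
        orphans = ~df["primaryid"].isin(known_ids)
        if orphans.any():
            logger.warning("%s: dropped %d orphan rows with no DEMO match",
                           name, int(orphans.sum()))
    drug = drug[drug["primaryid"].isin(known_ids)]
    reac = reac[reac["primaryid"].isin(known_ids)]

    start_by_key: dict[tuple[str, str], str] = {
        (r.primaryid, r.dsg_drug_seq): r.start_dt for r in ther.itertuples()
    }
    drugs_by_id: dict[str, list[DrugEntry]] = {}
    for row in drug.itertuples():
        role = row.role_cod.strip().upper()
        if role not in ROLE_CODES:
            role = "C"
        drugs_by_id.setdefault(row.primaryid, []).append(
            DrugEntry(
                name=row.drugname.strip(),
                role=role,
                start_date_raw=start_by_key.get((row.primaryid, row.drug_seq), ""),
            )
        )
    events_by_id: dict[str, set[str]] = {}
    for row in reac.itertuples():
        pt = row.pt.strip()
        if pt:
            events_by_id.setdefault(row.primaryid, set()).add(pt)

    reports = []
    for row in demo.itertuples():
        pid = row.primaryid
        reports.append(
            CaseReport(
                primary_id=pid,
                case_id=row.caseid,
                sex=_SEX.get(row.sex.strip().upper(), "unknown"),
                age_years=normalize_age(row.age, row.age_cod),
                country=row.occr_country.strip() or None,
                reporter_type=_REPORTER.get(row.occp_cod.strip().upper(), "missing"),
                fda_date_raw=row.fda_dt.strip(),
                event_date_raw=row.event_dt.strip(),
                drugs=drugs_by_id.get(pid, []),
                events=frozenset(events_by_id.get(pid, set())),
            )
        )
    logger.info("read_quarter: %d DEMO rows from %s", len(reports), directory)
    return clean_reports(reports) if clean else reports


def deduplicate(reports: list[CaseReport]) -> list[CaseReport]:
    """Two-step duplicate removal.

    1. Per case id keep only the latest version (max FDA receipt date,
       ties broken by largest primary id) — the FAERS case-version rule.
    2. Among survivors, reports identical on (sex, age, country, event date,
       sorted event-term set) are considered duplicate submissions of the
       same case; one representative (smallest primary id) is kept.

    The result is sorted by primary id, so the operation is idempotent and
    deterministic.
    """
    by_case: dict[str, CaseReport] = {}
    for r in reports:
        key = (r.fda_date or dt.date.min, r.primary_id)
        prev = by_case.get(r.case_id)
        if prev is None or key > (prev.fda_date or dt.date.min, prev.primary_id):
            by_case[r.case_id] = r

    seen: dict[tuple, CaseReport] = {}
    for r in sorted(by_case.values(), key=lambda r: r.primary_id):
        ident = (r.sex, r.age_years, r.country, r.event_date_raw,
                 tuple(sorted(r.events)))
        if ident not in seen:
            seen[ident] = r
    out = sorted(seen.values(), key=lambda r: r.primary_id)
    logger.info("deduplicate: %d -> %d reports", len(reports), len(out))
    return out


def flag_target(
    reports: list[CaseReport],
    patterns: list[str],
    mode: str = "substring",
) -> list[CaseReport]:
    """Mark reports whose *primary-suspect* drug matches any pattern.

    Matching is case-insensitive; ``mode`` is ``"substring"`` (default —
    FAERS drug names carry dose/formulation suffixes) or ``"exact"``.
    All other reports form the all-other-drugs comparator background.
    """
    if not patterns:
        raise ValueError("flag_target requires at least one drug-name pattern")
    if mode not in ("substring", "exact"):
        raise ValueError(f"unknown match mode {mode!r}")
    pats = [p.lower() for p in patterns]

    def matches(name: str) -> bool:
        name = name.lower()
        if mode == "exact":
            return any(name == p for p in pats)
        return any(p in name for p in pats)

    out = []
    for r in reports:
        hit = any(d.role == "PS" and matches(d.name) for d in r.drugs)
        out.append(replace(r, is_target=hit))
    return out


def read_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Read a two-column delimited PT -> SOC table (tab or ``$`` separated)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    cols = list(df.columns[:2])
    return {str(pt).strip(): str(soc).strip()
            for pt, soc in zip(df[cols[0]], df[cols[1]])}


def attach_soc(
    reports: list[CaseReport], mapping: dict[str, str]
) -> tuple[list[CaseReport], list[str]]:
    """Attach to each report the set of distinct SOCs induced by its PTs.

    Set semantics: several PTs in one SOC contribute that SOC once.
    Unmapped PTs are collected and returned (they are excluded from
    SOC-level analysis only); the report list is returned annotated.
    """
    unmapped: set[str] = set()
    out = []
    for r in reports:
        socs = set()
        for pt in r.events:
            soc = mapping.get(pt)
            if soc is None:
                unmapped.add(pt)
            else:
                socs.add(soc)
        out.append(replace(r, socs=frozenset(socs)))
    if unmapped:
        logger.warning("attach_soc: %d PTs without SOC mapping: %s",
                       len(unmapped), sorted(unmapped)[:10])
    return out, sorted(unmapped)


def reports_to_frame(reports: list[CaseReport]) -> pd.DataFrame:
    """Flat export of cleaned reports (drugs and events ';'-joined)."""
    rows = []
    for r in reports:
        rows.append({
            "primary_id": r.primary_id,
            "case_id": r.case_id,
            "sex": r.sex,
            "age_years": r.age_years,
            "country": r.country or "",
            "reporter_type": r.reporter_type,
            "fda_dt": r.fda_date_raw,
            "event_dt": r.event_date_raw,
            "is_target": r.is_target,
            "drugs": ";".join(f"{d.name}[{d.role}]" for d in r.drugs),
            "events": ";".join(sorted(r.events)),
            "socs": ";".join(sorted(r.socs)),
        })
    return pd.DataFrame(rows)
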