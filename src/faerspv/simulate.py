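"""Synthetic FAERS-like report generator with known ground truth.

The generator emulates the statistical structure of a spontaneous-reporting
database: per-report demographics with realistic missingness, multiple drug
entries with FAERS role codes, multiple event preferred terms (PTs),
partial ``YYYYMM``/``YYYY`` dates, verbatim duplicate submissions, and
drug-event associations of configurable strength.

Signal injection uses a two-component event-probability model: for a report
whose primary-suspect drug D carries an injected signal on event E with
target odds ratio theta against background rate q,

    P(E | D) = q * theta / (1 - q + q * theta),

which makes the population odds ratio of (D, E) exactly theta.  Reports
are independent; with theta = 1 everywhere the expected ROR of every pair
is 1.  Ground truth records the realized 2x2 counts over the unique
event-bearing reports (reports that draw no event are emitted but vanish
at ingestion, like real no-PT cases).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import CaseReport, DrugEntry, _REPORTER_BACK, _SEX_BACK

#: Drug universe: (name, marginal usage probability).  The first entry is
#: the target potassium binder; reports that draw no drug at all receive
#: the filler comparator so every report has a primary suspect.
DEFAULT_DRUGS: list[tuple[str, float]] = [
    ("SODIUM ZIRCONIUM CYCLOSILICATE", 0.02),
    ("PATIROMER", 0.03),
    ("LISINOPRIL", 0.08),
    ("METFORMIN", 0.10),
    ("ATORVASTATIN", 0.10),
    ("FUROSEMIDE", 0.08),
    ("OMEPRAZOLE", 0.08),
    ("WARFARIN", 0.06),
    ("AMLODIPINE", 0.08),
]
FILLER_DRUG = "OTHER MEDICATION"

#: Event universe: (PT, SOC, background report probability).
DEFAULT_PTS: list[tuple[str, str, float]] = [
    ("Hypokalaemia", "Metabolism and nutrition disorders", 0.004),
    ("Hypernatraemia", "Metabolism and nutrition disorders", 0.001),
    ("Blood sodium increased", "Investigations", 0.001),
    ("Blood pressure increased", "Investigations", 0.006),
    ("Constipation", "Gastrointestinal disorders", 0.010),
    ("Abdominal discomfort", "Gastrointestinal disorders", 0.008),
    ("Faeces hard", "Gastrointestinal disorders", 0.002),
    ("Ileus", "Gastrointestinal disorders", 0.001),
    ("Diarrhoea", "Gastrointestinal disorders", 0.060),
    ("Nausea", "Gastrointestinal disorders", 0.080),
    ("Dysphagia", "Gastrointestinal disorders", 0.003),
    ("Cardiac failure congestive", "Cardiac disorders", 0.004),
    ("Ventricular fibrillation", "Cardiac disorders", 0.0005),
    ("Oedema peripheral", "General disorders and administration site conditions", 0.008),
    ("Fluid retention", "General disorders and administration site conditions", 0.003),
    ("Fatigue", "General disorders and administration site conditions", 0.100),
    ("Drug ineffective", "General disorders and administration site conditions", 0.150),
    ("Malaise", "General disorders and administration site conditions", 0.060),
    ("Headache", "Nervous system disorders", 0.080),
    ("Dizziness", "Nervous system disorders", 0.060),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.050),
    ("Off label use", "Injury, poisoning and procedural complications", 0.100),
]

_COUNTRIES = (["US"] * 74 + ["JP"] * 17 + ["GB"] * 3 + ["CN"] * 2
              + ["CO"] * 2 + ["DE"] * 2)
_REPORTERS = (["consumer"] * 36 + ["physician"] * 33 + ["pharmacist"] * 14
              + ["health-professional"] * 16 + ["other"] * 1)


class ConfigurationError(ValueError):
    """An injected signal references an unknown drug or PT, or a rate is
    outside [0, 1]."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic report set.

    Missingness and duplication defaults mirror a typical spontaneous-
    reporting extract: ~21% missing sex, ~66% missing age, half of event
    dates absent or partial, 5% verbatim duplicate submissions; onset days
    are lognormal with median 92 days unless overridden per PT.
    """

    n_reports: int = 20_000
    drugs: list[tuple[str, float]] = field(default_factory=lambda: list(DEFAULT_DRUGS))
    pts: list[tuple[str, str, float]] = field(default_factory=lambda: list(DEFAULT_PTS))
    injected_signals: list[tuple[str, str, float]] = field(default_factory=list)
    missing_sex_rate: float = 0.214
    missing_age_rate: float = 0.659
    missing_date_rate: float = 0.5
    duplicate_rate: float = 0.05
    sex_male_frac: float = 0.62  # among reports with known sex
    onset_median_days: float = 92.0
    onset_sigma: float = 1.2
    onset_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    target_drug: str | None = None  # defaults to the first drug
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        rates = {
            "missing_sex_rate": self.missing_sex_rate,
            "missing_age_rate": self.missing_age_rate,
            "missing_date_rate": self.missing_date_rate,
            "duplicate_rate": self.duplicate_rate,
            "sex_male_frac": self.sex_male_frac,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        drug_names = {d for d, _ in self.drugs}
        pt_names = {p for p, _, _ in self.pts}
        for drug, pt, theta in self.injected_signals:
            if drug not in drug_names:
                raise ConfigurationError(f"injected signal references unknown drug {drug!r}")
            if pt not in pt_names:
                raise ConfigurationError(f"injected signal references unknown PT {pt!r}")
            if theta <= 0:
                raise ConfigurationError("target odds ratio must be > 0")

    @property
    def pt_soc_map(self) -> dict[str, str]:
        return {pt: soc for pt, soc, _ in self.pts}


@dataclass
class GroundTruth:
    """Realized 2x2 counts per (drug, PT) over unique event-bearing reports."""

    counts: pd.DataFrame  # columns: drug, pt, a, b, c, d, target_or

    def cells(self, drug: str, pt: str) -> tuple[int, int, int, int]:
        row = self.counts[(self.counts["drug"] == drug) & (self.counts["pt"] == pt)]
        if row.empty:
            raise KeyError((drug, pt))
        r = row.iloc[0]
        return int(r.a), int(r.b), int(r.c), int(r.d)

    def realized_or(self, drug: str, pt: str) -> float:
        a, b, c, d = self.cells(drug, pt)
        return (a * d) / (b * c) if b * c else float("inf")


def _truncate_date(date: dt.date, mode: int) -> str:
    """mode 0: missing, 1: YYYYMM, 2: YYYY."""
    if mode == 0:
        return ""
    if mode == 1:
        return f"{date.year:04d}{date.month:02d}"
    return f"{date.year:04d}"


def simulate_reports(config: SimulationConfig) -> tuple[list[CaseReport], GroundTruth]:
    """Generate reports and their ground truth; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = [d for d, _ in config.drugs]
    drug_probs = np.array([p for _, p in config.drugs])
    pt_names = [p for p, _, _ in config.pts]
    pt_q = np.array([q for _, _, q in config.pts])
    target_drug = config.target_drug or drug_names[0]

    # -- drug assignment: independent marginals, first present drug is PS
    drug_mask = rng.random((n, len(drug_names))) < drug_probs
    has_drug = drug_mask.any(axis=1)
    ps_idx = np.where(has_drug, drug_mask.argmax(axis=1), -1)  # -1 -> filler

    # -- events: background rate q, tilted for the PS drug's injected signals
    probs = np.tile(pt_q, (n, 1))
    for drug, pt, theta in config.injected_signals:
        j = pt_names.index(pt)
        di = drug_names.index(drug)
        q = pt_q[j]
        probs[ps_idx == di, j] = q * theta / (1.0 - q + q * theta)
    event_mask = rng.random((n, len(pt_names))) < probs

    # -- demographics
    sex_missing = rng.random(n) < config.missing_sex_rate
    sex_male = rng.random(n) < config.sex_male_frac
    age = np.clip(rng.normal(72.0, 14.0, n), 18.0, 100.0).round(0)
    age_missing = rng.random(n) < config.missing_age_rate
    country = rng.choice(_COUNTRIES, n)
    reporter = rng.choice(_REPORTERS, n)

    # -- dates: start in 2018-2023, event = start + onset, FDA receipt later
    epoch = dt.date(2018, 1, 1).toordinal()
    start_ord = rng.integers(0, 6 * 365, n) + epoch
    is_target_ps = np.array(
        [ps_idx[i] >= 0 and drug_names[ps_idx[i]] == target_drug for i in range(n)]
    )
    onset = rng.integers(0, 361, n).astype(float)  # background: uniform 0-360 d
    first_pt = event_mask.argmax(axis=1)
    has_event = event_mask.any(axis=1)
    for i in np.nonzero(is_target_ps & has_event)[0]:
        med, sig = config.onset_overrides.get(
            pt_names[first_pt[i]], (config.onset_median_days, config.onset_sigma)
        )
        onset[i] = np.round(np.exp(rng.normal(np.log(med), sig)))
    event_ord = start_ord + onset.astype(int)
    fda_ord = event_ord + rng.integers(1, 91, n)

    # partial-date truncation, independently for start and event dates
    start_trunc = np.where(rng.random(n) < config.missing_date_rate,
                           rng.integers(0, 3, n), -1)
    event_trunc = np.where(rng.random(n) < config.missing_date_rate,
                           rng.integers(0, 3, n), -1)

    reports: list[CaseReport] = []
    for i in range(n):
        sd = dt.date.fromordinal(int(start_ord[i]))
        ed = dt.date.fromordinal(int(event_ord[i]))
        start_raw = (sd.strftime("%Y%m%d") if start_trunc[i] < 0
                     else _truncate_date(sd, int(start_trunc[i])))
        event_raw = (ed.strftime("%Y%m%d") if event_trunc[i] < 0
                     else _truncate_date(ed, int(event_trunc[i])))
        entries = []
        present = [drug_names[j] for j in np.nonzero(drug_mask[i])[0]]
        if not present:
            present = [FILLER_DRUG]
        for k, name in enumerate(present):
            entries.append(DrugEntry(name=name, role="PS" if k == 0 else "SS",
                                     start_date_raw=start_raw if k == 0 else ""))
        reports.append(
            CaseReport(
                primary_id=f"{100000 + i}01",
                case_id=f"C{100000 + i}",
                sex="unknown" if sex_missing[i]
                    else ("male" if sex_male[i] else "female"),
                age_years=None if age_missing[i] else float(age[i]),
                country=str(country[i]),
                reporter_type=str(reporter[i]),
                fda_date_raw=dt.date.fromordinal(int(fda_ord[i])).strftime("%Y%m%d"),
                event_date_raw=event_raw,
                drugs=entries,
                events=frozenset(pt_names[j] for j in np.nonzero(event_mask[i])[0]),
            )
        )

    truth = _tabulate_truth(config, ps_idx, event_mask, drug_names, pt_names)

    # -- verbatim duplicate submissions (same case id, same fields)
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        reports.extend(reports[int(i)] for i in dup_idx)

    return reports, truth


def _tabulate_truth(config, ps_idx, event_mask, drug_names, pt_names) -> GroundTruth:
    """Brute-force 2x2 counts per (drug, pt) over event-bearing reports."""
    has_event = event_mask.any(axis=1)
    ps = ps_idx[has_event]
    ev = event_mask[has_event]
    n_kept = int(has_event.sum())
    injected = {(d, p): t for d, p, t in config.injected_signals}
    rows = []
    for di, drug in enumerate(drug_names):
        in_drug = ps == di
        n_drug = int(in_drug.sum())
        for j, pt in enumerate(pt_names):
            a = int((in_drug & ev[:, j]).sum())
            c = int(ev[:, j].sum()) - a
            rows.append({
                "drug": drug, "pt": pt,
                "a": a, "b": n_drug - a,
                "c": c, "d": n_kept - n_drug - c,
                "target_or": injected.get((drug, pt), 1.0),
            })
    return GroundTruth(counts=pd.DataFrame(rows))


def write_faers_quarter(reports: list[CaseReport], directory: str | Path) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/THER files in the ``$``-delimited FAERS dialect.

    Round-trips through :func:`faerspv.ingest.read_quarter` without loss of
    any field used by downstream tabulation.
    """
    if not reports:
        raise ValueError("write_faers_quarter requires a non-empty report list")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    demo_rows, drug_rows, reac_rows, ther_rows = [], [], [], []
    for r in reports:
        demo_rows.append({
            "primaryid": r.primary_id, "caseid": r.case_id,
            "fda_dt": r.fda_date_raw, "event_dt": r.event_date_raw,
            "age": "" if r.age_years is None else f"{r.age_years:g}",
            "age_cod": "" if r.age_years is None else "YR",
            "sex": _SEX_BACK.get(r.sex, ""),
            "occp_cod": _REPORTER_BACK.get(r.reporter_type, ""),
            "occr_country": r.country or "",
        })
        for seq, d in enumerate(r.drugs, start=1):
            drug_rows.append({"primaryid": r.primary_id, "drug_seq": str(seq),
                              "role_cod": d.role, "drugname": d.name})
            if d.start_date_raw:
                ther_rows.append({"primaryid": r.primary_id,
                                  "dsg_drug_seq": str(seq),
                                  "start_dt": d.start_date_raw})
        for pt in sorted(r.events):
            reac_rows.append({"primaryid": r.primary_id, "pt": pt})

    paths = {}
    for name, rows, cols in (
        ("DEMO", demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt", "age",
                             "age_cod", "sex", "occp_cod", "occr_country"]),
        ("DRUG", drug_rows, ["primaryid", "drug_seq", "role_cod", "drugname"]),
        ("REAC", reac_rows, ["primaryid", "pt"]),
        ("THER", ther_rows, ["primaryid", "dsg_drug_seq", "start_dt"]),
    ):
        path = directory / f"{name}.txt"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="$", index=False)
        paths[name] = path
    return paths


def write_pt_soc_map(config: SimulationConfig, path: str | Path) -> Path:
    """Write the simulator's PT -> SOC table (tab-delimited)."""
    path = Path(path)
    pd.DataFrame(
        [(pt, soc) for pt, soc, _ in config.pts], columns=["pt", "soc"]
    ).to_csv(path, sep="\t", index=False)
    return path
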