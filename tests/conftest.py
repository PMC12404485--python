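import pytest

from faerspv.ingest import CaseReport, DrugEntry, clean_reports, flag_target
from faerspv.simulate import SimulationConfig, simulate_reports

TARGET = "SODIUM ZIRCONIUM CYCLOSILICATE"
TARGET_PATTERNS = ["sodium zirconium cyclosilicate", "lokelma"]


def make_report(pid="100001", case=None, sex="male", age=70.0, country="US",
                fda="20230601", event="20230101", drug=TARGET, role="PS",
                start="20221201", events=("Hypokalaemia",), extra_drugs=()):
    """Hand-built CaseReport for unit tests."""
    drugs = [DrugEntry(name=drug, role=role, start_date_raw=start)]
    drugs += [DrugEntry(name=n, role="SS") for n in extra_drugs]
    return CaseReport(
        primary_id=pid, case_id=case or f"C{pid}", sex=sex, age_years=age,
        country=country, fda_date_raw=fda, event_date_raw=event,
        drugs=drugs, events=frozenset(events),
    )


@pytest.fixture(scope="session")
def null_config():
    """No injected signals, no duplication, complete data — every
    drug-event pair has population odds ratio 1."""
    return SimulationConfig(
        n_reports=4000, seed=11, missing_sex_rate=0.0, missing_age_rate=0.0,
        missing_date_rate=0.0, duplicate_rate=0.0,
    )


@pytest.fixture(scope="session")
def null_reports(null_config):
    reports, truth = simulate_reports(null_config)
    reports = flag_target(clean_reports(reports), TARGET_PATTERNS)
    return reports, truth


@pytest.fixture(scope="session")
def injected_reports():
    """One strong injected association (target drug, Hypokalaemia, OR 10)."""
    cfg = SimulationConfig(
        n_reports=20_000, seed=7, duplicate_rate=0.0,
        injected_signals=[(TARGET, "Hypokalaemia", 10.0)],
    )
    reports, truth = simulate_reports(cfg)
    reports = flag_target(clean_reports(reports), TARGET_PATTERNS)
    return reports, truth
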