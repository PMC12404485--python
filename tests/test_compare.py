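import math

import pandas as pd
import pytest

from faerspv.compare import (comparative_analysis, delta_lnror, in_stratum,
                             partition_terms, se_from_ci, stratified_screen)
from faerspv.contingency import build_tables
from faerspv.ingest import clean_reports, flag_target
from faerspv.signals import compute_metrics
from faerspv.simulate import SimulationConfig, simulate_reports

from conftest import TARGET, TARGET_PATTERNS, make_report


class TestSeFromCi:
    def test_degenerate_interval(self):
        assert se_from_ci(2.0, 2.0) == 0.0

    @pytest.mark.parametrize("lo, hi, expected",
                             [(15.53, 28.37, 0.154), (5.12, 10.65, 0.187)])
    def test_published_intervals(self, lo, hi, expected):
        assert se_from_ci(lo, hi) == pytest.approx(expected, abs=0.001)

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(ValueError):
            se_from_ci(0.0, 2.0)

    def test_inverts_ror_ci_construction(self):
        """se_from_ci applied to a computed ROR CI recovers
        sqrt(1/a + 1/b + 1/c + 1/d)."""
        from faerspv.contingency import ContingencyTable
        t = ContingencyTable("x", "pt", 12, 88, 340, 9560)
        m = compute_metrics(t)
        s = math.sqrt(1 / 12 + 1 / 88 + 1 / 340 + 1 / 9560)
        assert se_from_ci(m.ror_lo, m.ror_hi) == pytest.approx(s, rel=1e-9)


class TestDeltaLnror:
    def test_congestive_heart_failure_rows(self):
        """Head-to-head CCF comparison from the two published rows:
        delta ~0.86-0.87, CI ~(0.46, 1.27), p < 0.001."""
        d = delta_lnror("CCF", 7.38, (5.12, 10.65), 3.11, (2.60, 3.71))
        assert d.delta_lnror == pytest.approx(0.87, abs=0.02)
        assert d.ci_lo == pytest.approx(0.46, abs=0.02)
        assert d.ci_hi == pytest.approx(1.27, abs=0.02)
        assert d.p < 0.001

    def test_faeces_hard_not_significant(self):
        d = delta_lnror("Faeces hard", 17.92, (5.77, 55.63), 45.02, (35.57, 56.98))
        assert d.delta_lnror == pytest.approx(-0.92, abs=0.03)
        assert d.ci_lo < 0 < d.ci_hi
        assert d.p > 0.05

    def test_identical_inputs_give_zero_delta_p_one(self):
        d = delta_lnror("x", 3.0, (2.0, 4.5), 3.0, (2.0, 4.5))
        assert d.delta_lnror == 0.0
        assert d.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        ab = delta_lnror("x", 7.38, (5.12, 10.65), 3.11, (2.60, 3.71))
        ba = delta_lnror("x", 3.11, (2.60, 3.71), 7.38, (5.12, 10.65))
        assert ab.delta_lnror == pytest.approx(-ba.delta_lnror)
        assert ab.p == pytest.approx(ba.p)
        assert ab.ci_lo == pytest.approx(-ba.ci_hi)

    def test_degenerate_se_rejected(self):
        with pytest.raises(ValueError):
            delta_lnror("x", 2.0, (2.0, 2.0), 3.0, (3.0, 3.0))


class TestPartition:
    def _frame(self, terms):
        return pd.DataFrame({"term": terms, "significant": [True] * len(terms)})

    def test_set_partition(self):
        a = self._frame(["Constipation", "Ileus", "Hypernatraemia"])
        b = self._frame(["Constipation", "Diarrhoea"])
        shared, only_a, only_b = partition_terms(a, b)
        assert shared == ["Constipation"]
        assert only_a == ["Hypernatraemia", "Ileus"]
        assert only_b == ["Diarrhoea"]

    def test_disjoint_and_identical(self):
        a, b = self._frame(["X"]), self._frame(["Y"])
        assert partition_terms(a, b) == ([], ["X"], ["Y"])
        assert partition_terms(a, a) == (["X"], [], [])

    def test_only_significant_rows_count(self):
        a = pd.DataFrame({"term": ["X", "Y"], "significant": [True, False]})
        b = self._frame(["X", "Y"])
        shared, only_a, only_b = partition_terms(a, b)
        assert shared == ["X"] and only_b == ["Y"]


class TestStratified:
    def test_age_bin_edges(self):
        r65 = make_report(age=65.0)
        r85 = make_report(age=85.0)
        r86 = make_report(age=86.0)
        r64 = make_report(age=64.9)
        missing = make_report(age=None)
        assert in_stratum(r65, "age", "65-85") and in_stratum(r85, "age", "65-85")
        assert in_stratum(r86, "age", ">85") and in_stratum(r64, "age", "<65")
        assert not any(in_stratum(missing, "age", lvl)
                       for lvl in ("<65", "65-85", ">85"))

    def test_sex_strata_sum_to_unstratified(self, null_reports):
        """Male + female + missing-sex tables reconstruct the full table
        cell-wise."""
        reports, _ = null_reports
        full = {t.term: t for t in build_tables(reports, min_a=1)}
        parts = [
            [r for r in reports if r.sex == "male"],
            [r for r in reports if r.sex == "female"],
            [r for r in reports if r.sex == "unknown"],
        ]
        for term in ("Drug ineffective", "Nausea"):
            cells = [0, 0, 0, 0]
            for sub in parts:
                tabs = {t.term: t for t in build_tables(sub, min_a=1)}
                if term in tabs:
                    t = tabs[term]
                    add = (t.a, t.b, t.c, t.d)
                else:  # term absent in this stratum's target reports
                    n_t = sum(r.is_target for r in sub)
                    c = sum((not r.is_target) and term in r.events for r in sub)
                    add = (0, n_t, c, len(sub) - n_t - c)
                cells = [x + y for x, y in zip(cells, add)]
            t = full[term]
            assert tuple(cells) == (t.a, t.b, t.c, t.d)

    def test_sex_specific_signal_localizes_to_stratum(self):
        """An association injected only in males yields a much larger
        male-stratum ROR than female-stratum ROR."""
        male_cfg = SimulationConfig(
            n_reports=15_000, seed=31, duplicate_rate=0.0, missing_sex_rate=0.0,
            sex_male_frac=1.0,
            injected_signals=[(TARGET, "Hypokalaemia", 10.0)],
        )
        female_cfg = SimulationConfig(
            n_reports=15_000, seed=32, duplicate_rate=0.0, missing_sex_rate=0.0,
            sex_male_frac=0.0,
        )
        reports = []
        for i, cfg in enumerate((male_cfg, female_cfg)):
            part, _ = simulate_reports(cfg)
            import dataclasses
            reports += [dataclasses.replace(r, primary_id=f"{i}{r.primary_id}",
                                            case_id=f"{i}{r.case_id}")
                        for r in part]
        reports = flag_target(clean_reports(reports), TARGET_PATTERNS)
        male = stratified_screen(reports, "sex", "male", min_a=1)
        female = stratified_screen(reports, "sex", "female", min_a=1)
        ror_m = male.set_index("term").loc["Hypokalaemia", "ror"]
        fem = female.set_index("term")
        ror_f = fem.loc["Hypokalaemia", "ror"] if "Hypokalaemia" in fem.index else 1.0
        assert ror_m > 3 * ror_f

    def test_empty_stratum_returns_empty(self):
        reports = flag_target([make_report(sex="male")], TARGET_PATTERNS)
        assert stratified_screen(reports, "sex", "female").empty


def test_comparative_analysis_shared_terms(null_config):
    """Two drugs injected on overlapping PT sets: the shared PT is
    detected for both and compared; unique PTs partition correctly."""
    import dataclasses
    cfg = dataclasses.replace(
        null_config, n_reports=40_000, seed=41,
        injected_signals=[
            (TARGET, "Hypokalaemia", 12.0),
            (TARGET, "Constipation", 8.0),
            ("PATIROMER", "Constipation", 8.0),
            ("PATIROMER", "Diarrhoea", 6.0),
        ],
    )
    reports, _ = simulate_reports(cfg)
    reports = clean_reports(reports)
    result = comparative_analysis(reports, TARGET_PATTERNS, ["patiromer"])
    assert "Constipation" in result["shared"]
    assert "Hypokalaemia" in result["only_a"]
    assert "Diarrhoea" in result["only_b"]
    deltas = result["deltas"].set_index("term")
    row = deltas.loc["Constipation"]
    assert row["ci_lo"] < row["delta_lnror"] < row["ci_hi"]
    # same injected strength for both drugs: no significant difference
    assert row["p"] > 0.01
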