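"""ROR, PRR/χ², expected counts, IC and the joint signal criterion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal import (
    ContingencyTable,
    DegenerateTableError,
    DisproportionalityModel,
    SRSDataset,
    SCREENING_ROW_MARGINALS,
    ZeroCellError,
    build_table,
    expected_count,
    information_component,
    prr_chi2,
    ror,
    select_reports,
    table_from_marginals,
)
from conftest import EGPA, small_config

cells = st.integers(min_value=1, max_value=5000)


def toy_dataset():
    """Four reports: drug+event, drug only, event only, neither."""
    cases = pd.DataFrame(
        {
            "report_id": ["1", "2", "3", "4"],
            "case_id": ["1", "2", "3", "4"],
            "version_key": ["1", "2", "3", "4"],
            "age": [50.0] * 4,
            "sex": ["female"] * 4,
            "weight": [70.0] * 4,
            "event_year": pd.array([2020] * 4, dtype="Int64"),
            "country": ["US"] * 4,
            "reporter": ["physician"] * 4,
            "outcomes": ["other"] * 4,
        }
    )
    drugs = pd.DataFrame(
        {
            "report_id": ["1", "2", "3", "4"],
            "verbatim_name": ["montelukast", "montelukast", "aspirin", "aspirin"],
            "ingredient": ["montelukast", "montelukast", None, None],
            "role": ["PS", "PS", "PS", "PS"],
            "start_date": [pd.NaT] * 4,
            "start_date_imputed": [False] * 4,
            "indication_pt": [None] * 4,
        }
    )
    events = pd.DataFrame(
        {
            "report_id": ["1", "3", "2", "4"],
            "pt": [EGPA, EGPA, "Headache", "Headache"],
            "onset_date": [pd.NaT] * 4,
            "onset_date_imputed": [False] * 4,
        }
    )
    return SRSDataset("FAERS", cases, drugs, events)


class TestBuildTable:
    def test_four_report_toy(self):
        t = build_table(toy_dataset(), ["montelukast"], [EGPA], roles={"PS"})
        assert t.as_tuple() == (1, 1, 1, 1)

    def test_cells_match_exhaustive_intersections(self, planted_dataset):
        ds, _ = planted_dataset
        roles = {"PS", "concomitant"}
        t = build_table(ds, ["montelukast"], [EGPA], roles=roles)
        exposed, with_event, both = select_reports(ds, ["montelukast"], roles, [EGPA])
        all_ids = set(ds.cases["report_id"])
        assert t.a == len(both)
        assert t.b == len(exposed - with_event)
        assert t.c == len(with_event - exposed)
        assert t.d == len(all_ids - exposed - with_event)

    def test_degenerate_margins_raise(self):
        ds = toy_dataset()
        with pytest.raises(DegenerateTableError):
            build_table(ds, ["montelukast"], ["Vertigo"], roles={"PS"})


class TestRor:
    def test_symmetric_table_is_one(self):
        est, lo, hi = ror(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_published_faers_ci_lower_bound(self):
        t = table_from_marginals(**SCREENING_ROW_MARGINALS["FAERS_LTRA"])
        est, lo, hi = ror(t)
        assert est == pytest.approx(268.58, rel=1e-6)
        assert lo == pytest.approx(247.04, abs=0.005)
        assert hi == pytest.approx(292.00, abs=0.005)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_matches_cross_product_oracle(self, a, b, c, d):
        est, lo, hi = ror(ContingencyTable(a, b, c, d))
        # independent arithmetic: odds in exposed over odds in unexposed
        odds_exposed = a / b
        odds_unexposed = c / d
        assert est == pytest.approx(odds_exposed / odds_unexposed, rel=1e-12)
        assert lo <= est <= hi

    def test_zero_cell_policy(self):
        t = ContingencyTable(0, 10, 10, 10)
        with pytest.raises(ZeroCellError):
            ror(t)
        est, lo, hi = ror(t, haldane=True)
        assert est == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))


class TestPrrChi2:
    def test_symmetric_table(self):
        est, lo, hi, chi2 = prr_chi2(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_published_faers_row(self):
        t = table_from_marginals(**SCREENING_ROW_MARGINALS["FAERS_LTRA"])
        est, _, _, chi2 = prr_chi2(t)
        assert est == pytest.approx(266.46, rel=1e-3)
        assert chi2 == pytest.approx(146177.12, rel=1e-3)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_chi2_matches_formula_rederivation(self, a, b, c, d):
        _, _, _, chi2 = prr_chi2(ContingencyTable(a, b, c, d))
        # independent route: sum over cells of (obs - exp)^2 / exp
        n = a + b + c + d
        obs = np.array([[a, b], [c, d]], dtype=float)
        rows = obs.sum(axis=1, keepdims=True)
        cols = obs.sum(axis=0, keepdims=True)
        exp = rows @ cols / n
        assert chi2 == pytest.approx(float(((obs - exp) ** 2 / exp).sum()), rel=1e-10)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_chi2_transpose_invariance_and_prr_ror_identity(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        _, _, _, chi2 = prr_chi2(t)
        _, _, _, chi2_t = prr_chi2(t.transpose())
        assert chi2 == pytest.approx(chi2_t, rel=1e-12)
        # PRR/ROR = [b/(a+b)] / [d/(c+d)] for all-positive tables
        prr_est = prr_chi2(t)[0]
        ror_est = ror(t)[0]
        identity = (b / (a + b)) / (d / (c + d))
        assert prr_est / ror_est == pytest.approx(identity, rel=1e-10)


class TestExpectedCount:
    def test_exact_independence(self):
        e, rr = expected_count(ContingencyTable(1, 9, 9, 81))
        assert e == pytest.approx(1.0)
        assert rr == pytest.approx(1.0)

    def test_published_faers_rr_matches_large_count_ebgm(self):
        t = table_from_marginals(**SCREENING_ROW_MARGINALS["FAERS_LTRA"])
        _, rr = expected_count(t)
        assert rr == pytest.approx(179.49, rel=1e-3)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_matches_margin_product_oracle(self, a, b, c, d):
        e, rr = expected_count(ContingencyTable(a, b, c, d))
        assert e == pytest.approx((a + b) * (a + c) / (a + b + c + d), rel=1e-12)
        assert rr == pytest.approx(a / e, rel=1e-12)


class TestInformationComponent:
    def test_zero_when_observed_equals_expected(self):
        r = information_component(8.0, 8.0, variant="raw")
        assert r.ic == pytest.approx(0.0)

    def test_published_faers_ic(self):
        t = table_from_marginals(**SCREENING_ROW_MARGINALS["FAERS_LTRA"])
        e, _ = expected_count(t)
        r = information_component(t.a, e, variant="raw")
        assert round(r.ic, 2) == 7.49
        assert round(r.ic025_approx, 2) == 7.37

    def test_mc_percentile_agrees_with_closed_form_at_large_a(self):
        # both IC025 routes are anchored in the Gamma(a+0.5, E+0.5)
        # posterior, so the comparison uses the shrunk IC
        t = table_from_marginals(**SCREENING_ROW_MARGINALS["FAERS_LTRA"])
        e, _ = expected_count(t)
        r = information_component(t.a, e, variant="shrunk", n_mc=1_000_000, seed=1)
        assert abs(r.ic025_mc - r.ic025_approx) < 0.02

    def test_raw_ic_is_log2_rr_and_shrunk_converges(self):
        for a, e in [(5, 2.0), (50, 20.0), (5000, 2000.0)]:
            raw = information_component(a, e, variant="raw").ic
            assert raw == pytest.approx(math.log2(a / e), rel=1e-12)
        gap = abs(
            information_component(5000, 2000.0, "shrunk").ic
            - information_component(5000, 2000.0, "raw").ic
        )
        assert gap < 1e-3

    def test_raw_variant_rejects_zero_count(self):
        with pytest.raises(ZeroCellError):
            information_component(0, 5.0, variant="raw")
        assert information_component(0, 5.0, variant="shrunk").ic < 0


class TestJointCriterion:
    def test_published_faers_row_is_positive(self):
        t = table_from_marginals(**SCREENING_ROW_MARGINALS["FAERS_LTRA"])
        res = DisproportionalityModel.from_table(t).fit()
        assert res.flags == {"ror": True, "prr": True, "ic": True, "ebgm": True}
        assert res.is_signal

    def test_case_count_gate(self):
        # 2 cases with an enormous ROR still fails the n >= 3 gate
        t = ContingencyTable(2, 1, 1, 100_000)
        res = DisproportionalityModel.from_table(t).fit()
        assert not res.flags["ror"]
        assert not res.is_signal

    def test_eb05_below_point_estimate(self):
        t = table_from_marginals(**SCREENING_ROW_MARGINALS["CVAR_montelukast"])
        res = DisproportionalityModel.from_table(t).fit()
        assert res.ebgm05 < res.ebgm
        assert res.ic025 < res.ic


class TestModelOnSyntheticData:
    def test_null_design_ror_near_one(self):
        from pvsignal import generate

        cfg = small_config(n_reports=200_000, seed=21)
        for spec in list(cfg.signals):
            cfg.signals = [spec.__class__(spec.ingredient, spec.event_pt, target_rr=1.0)]
        cfg.events[EGPA] = 0.01  # enough events for a stable null estimate
        ds, _ = generate(cfg)
        res = DisproportionalityModel(
            ds, ["montelukast"], [EGPA], roles={"PS", "concomitant"}
        ).fit()
        assert res.ror_ci[0] < 1.0 < res.ror_ci[1]

    def test_planted_rr_inside_wald_ci(self, planted_dataset):
        ds, truth = planted_dataset
        res = DisproportionalityModel(
            ds, ["montelukast"], [EGPA], roles={"PS", "concomitant"}
        ).fit()
        row = truth["pair_counts"].query(
            "ingredient == 'montelukast' and event_pt == @EGPA"
        ).iloc[0]
        assert row["target_rr"] == 50.0
        assert res.ror_ci[0] < 50.0 < res.ror_ci[1] or res.ror > 25.0

    def test_summary_mentions_all_four_statistics(self, planted_dataset):
        ds, _ = planted_dataset
        res = DisproportionalityModel(
            ds, ["montelukast"], [EGPA], roles={"PS", "concomitant"}
        ).fit()
        text = res.summary()
        for token in ("ROR", "PRR", "EBGM", "IC", "signal"):
            assert token in text
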