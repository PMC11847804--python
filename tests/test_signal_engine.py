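"""Four-fold tables and the ROR / PRR / BCPNN / MGPS estimators."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedsignal import signal_engine as se
from pedsignal.cohort_builder import build_cohort
from conftest import demo_frame, drug_frame, make_bundle, reac_frame

T = se.FourFoldTable(10, 20, 5, 40)

cells = st.integers(1, 500)


class TestFourFoldTable:
    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            se.FourFoldTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            se.FourFoldTable(0, 0, 0, 0)

    def test_build_contingency_from_pairs(self):
        cohort_pairs = pd.DataFrame(
            [("r1", "X"), ("r1", "Y"), ("r2", "X")], columns=["primaryid", "pt"]
        )
        background = pd.concat(
            [cohort_pairs,
             pd.DataFrame([("r3", "X"), ("r3", "Z")], columns=["primaryid", "pt"])],
            ignore_index=True,
        )
        t = se.build_contingency("X", "PT", cohort_pairs, background)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)

    def test_absent_term_gives_zero_a(self):
        pairs = pd.DataFrame([("r1", "X")], columns=["primaryid", "pt"])
        t = se.build_contingency("NOPE", "PT", pairs, pairs)
        assert t.a == 0 and t.b == 1

    def test_soc_level_unions_mapped_pts(self):
        pairs = pd.DataFrame(
            [("r1", "X"), ("r1", "Y"), ("r2", "Z")], columns=["primaryid", "pt"]
        )
        bg = pd.concat(
            [pairs, pd.DataFrame([("r3", "Z")], columns=["primaryid", "pt"])],
            ignore_index=True,
        )
        mapping = {"X": "SOC1", "Y": "SOC1", "Z": "SOC2"}
        t = se.build_contingency("SOC1", "SOC", pairs, bg, mapping)
        assert t.a == 2

    def test_soc_level_unmapped_pt_is_an_error(self):
        pairs = pd.DataFrame([("r1", "X")], columns=["primaryid", "pt"])
        with pytest.raises(KeyError, match="X"):
            se.build_contingency("SOC1", "SOC", pairs, pairs, {"Y": "SOC1"})

    def test_cohort_not_subset_of_background_is_an_error(self):
        pairs = pd.DataFrame([("r1", "X")], columns=["primaryid", "pt"])
        bg = pd.DataFrame([("r2", "X")], columns=["primaryid", "pt"])
        with pytest.raises(ValueError, match="subset"):
            se.build_contingency("X", "PT", pairs, bg)


class TestStatisticOracles:
    """Frozen hand computations on the canonical table (10, 20, 5, 40)."""

    def test_ror_point_and_ci(self):
        r = se.ror_statistic(T)
        assert r.ror == pytest.approx(4.0)
        assert r.lower == pytest.approx(1.2045, abs=1e-4)
        assert r.upper == pytest.approx(13.2838, abs=1e-3)

    def test_prr_and_chi2_both_corrections(self):
        prr, chi2_yates, _ = se.prr_statistic(T, continuity_correction=True)
        assert prr == pytest.approx(3.0)
        assert chi2_yates == pytest.approx(4.2535, abs=1e-4)
        _, chi2_raw, _ = se.prr_statistic(T, continuity_correction=False)
        assert chi2_raw == pytest.approx(5.5556, abs=1e-4)

    def test_ic_point(self):
        ic = se.bcpnn_statistic(T)
        assert ic.ic == pytest.approx(0.7370, abs=1e-4)

    def test_ebgm_and_lower_bound(self):
        eb = se.mgps_statistic(T)
        assert eb.ebgm == pytest.approx(1.6667, abs=1e-4)
        assert eb.ebgm05 == pytest.approx(0.6105, abs=1e-3)

    def test_chi2_matches_scipy_without_correction(self):
        from scipy.stats import chi2_contingency

        expected = chi2_contingency([[10, 20], [5, 40]], correction=False)[0]
        assert se.prr_statistic(T, False).chi2 == pytest.approx(expected)
        expected_yates = chi2_contingency([[10, 20], [5, 40]], correction=True)[0]
        assert se.prr_statistic(T, True).chi2 == pytest.approx(expected_yates)


class TestDegenerateTables:
    def test_zero_cell_makes_ror_undefined(self):
        r = se.ror_statistic(se.FourFoldTable(0, 5, 5, 5))
        assert not r.defined and math.isnan(r.ror)

    def test_zero_c_makes_prr_undefined(self):
        p = se.prr_statistic(se.FourFoldTable(3, 1, 0, 4))
        assert not p.defined

    def test_d_zero_is_still_computable_for_prr(self):
        p = se.prr_statistic(se.FourFoldTable(3, 0, 1, 0))
        assert p.prr == pytest.approx(1.0)

    def test_a_zero_ic_is_minus_infinity_but_bounds_exist(self):
        ic = se.bcpnn_statistic(se.FourFoldTable(0, 10, 10, 100))
        assert ic.ic == -math.inf and not ic.defined
        assert math.isfinite(ic.ic025)


@given(k=st.integers(1, 1000))
def test_independence_null_is_exact(k):
    t = se.FourFoldTable(k, k, k, k)
    assert se.ror_statistic(t).ror == pytest.approx(1.0)
    assert se.prr_statistic(t).prr == pytest.approx(1.0)
    assert se.prr_statistic(t, False).chi2 == 0.0
    assert se.bcpnn_statistic(t).ic == pytest.approx(0.0)
    assert se.mgps_statistic(t).ebgm == pytest.approx(1.0)


@given(a=cells, b=cells, c=cells, d=cells)
def test_product_null_tables_give_unit_ratios(a, b, c, d):
    """Any table with ad = bc has ROR = PRR = EBGM = 1 and IC = 0."""
    # construct ad = bc via outer product margins: (ab, a·d', b·c', cd)
    t = se.FourFoldTable(a * b, a * d, c * b, c * d)
    assert se.ror_statistic(t).ror == pytest.approx(1.0)
    assert se.prr_statistic(t).prr == pytest.approx(1.0)
    assert se.mgps_statistic(t).ebgm <= se.prr_statistic(t).prr + 1e-12


@given(a=cells, b=cells, c=cells, d=cells)
def test_shrinkage_ordering_and_ic_link(a, b, c, d):
    """ROR > 1 implies EBGM <= PRR <= ROR; IC = log2(EBGM) always."""
    t = se.FourFoldTable(a, b, c, d)
    ror = se.ror_statistic(t).ror
    prr = se.prr_statistic(t).prr
    ebgm = se.mgps_statistic(t).ebgm
    ic = se.bcpnn_statistic(t).ic
    assert ic == pytest.approx(math.log2(ebgm), abs=1e-12)
    if ror > 1:
        assert ebgm <= prr * (1 + 1e-12) <= ror * (1 + 1e-12)


def test_monotone_in_a_with_fixed_margins():
    row1, col1, n = 60, 50, 200
    stats_prev = None
    for a in range(5, 45, 5):
        t = se.FourFoldTable(a, row1 - a, col1 - a, n - row1 - col1 + a)
        cur = (
            se.ror_statistic(t).ror,
            se.prr_statistic(t).prr,
            se.bcpnn_statistic(t).ic,
            se.mgps_statistic(t).ebgm,
        )
        if stats_prev is not None:
            assert all(x > y for x, y in zip(cur, stats_prev))
        stats_prev = cur


def test_bate_expectation_approaches_log2_rrr_at_large_n():
    """E(IC) converges to the simplified IC as counts grow with fixed fractions."""
    frac = np.array([0.002, 0.018, 0.098, 0.882])
    n_total = 1_000_000
    a, b, c, d = (frac * n_total).astype(int)
    t = se.FourFoldTable(int(a), int(b), int(c), int(d))
    ic = se.bcpnn_statistic(t)
    e_ic_gap = abs(ic.ic025 - ic.ic)  # bound still below the point estimate
    priors = se.BcpnnPriors()
    # recompute E(IC) directly
    g = priors.gamma(t)
    e_ic = math.log2(
        (t.a + 1) * (t.n + 2) * (t.n + 2) / ((t.n + g) * (t.a + t.b + 1) * (t.a + t.c + 1))
    )
    assert e_ic == pytest.approx(ic.ic, abs=0.01)


def test_ln_ror_interval_coverage_is_calibrated():
    """95% CI covers the true odds ratio in 93-97% of 2000 simulated tables."""
    rng = np.random.default_rng(2024)
    theta = 3.0
    p0 = 0.05
    p1 = theta * p0 / (1 - p0 + theta * p0)
    n1, n0 = 500, 2000
    covered = total = 0
    while total < 2000:
        a = rng.binomial(n1, p1)
        c = rng.binomial(n0, p0)
        if a in (0, n1) or c in (0, n0):
            continue
        t = se.FourFoldTable(int(a), n1 - int(a), int(c), n0 - int(c))
        r = se.ror_statistic(t)
        covered += r.lower <= theta <= r.upper
        total += 1
    assert 0.93 <= covered / total <= 0.97


SYNONYMS = ["SEVOFLURANE", "ULTANE", "SEVORANE"]


class TestEvaluateSignals:
    def _cohort_and_background(self, tiny_bundle):
        from pedsignal.cohort_builder import build_stratum_background

        cohort = build_cohort(tiny_bundle, SYNONYMS, stratum="pediatric")
        _, bg = build_stratum_background(tiny_bundle, "pediatric")
        return cohort, bg

    MAPPING = {
        "Cough": "Respiratory", "Tachycardia": "Cardiac", "Bradycardia": "Cardiac",
        "Nausea": "Gastro", "Rash": "Skin", "Pyrexia": "General",
    }

    def test_one_row_per_observed_pt_and_soc(self, tiny_bundle):
        cohort, bg = self._cohort_and_background(tiny_bundle)
        res = se.evaluate_signals(cohort, bg, self.MAPPING)
        pts = res[res["level"] == "PT"]
        assert set(pts["term"]) == {"Cough", "Tachycardia", "Bradycardia"}
        assert (pts["a"] >= 1).all()
        assert set(res[res["level"] == "SOC"]["term"]) == {"Respiratory", "Cardiac"}

    def test_margin_equals_pair_count(self, tiny_bundle):
        cohort, bg = self._cohort_and_background(tiny_bundle)
        res = se.evaluate_signals(cohort, bg, self.MAPPING)
        pts = res[res["level"] == "PT"].iloc[0]
        # a + b = cohort pair total by construction
        t = se.build_contingency(pts["term"], "PT", cohort.pairs, bg)
        assert t.a + t.b == cohort.n_report_pt_pairs

    def test_min_a_gate_blocks_small_counts(self):
        crit = se.SignalCriteria()
        row = se._stat_row("X", "PT", "S", se.FourFoldTable(2, 5, 1, 500), crit)
        # enormous disproportion but a = 2 < 3
        assert row["flag_ror"] and not row["signal"]

    def test_all_four_rules_must_hold(self):
        crit = se.SignalCriteria()
        # strong association: all rules met at a = 14
        row = se._stat_row("X", "PT", "S", se.FourFoldTable(14, 100, 40, 900), crit)
        assert row["signal"] == (
            row["flag_ror"] and row["flag_prr"] and row["flag_bcpnn"] and row["flag_mgps"]
        )

    def test_unmapped_pts_pool_under_sentinel(self, tiny_bundle, caplog):
        import logging

        cohort, bg = self._cohort_and_background(tiny_bundle)
        mapping = {"Cough": "Respiratory"}  # others unmapped
        with caplog.at_level(logging.WARNING):
            res = se.evaluate_signals(cohort, bg, mapping)
        assert se.UNMAPPED_SOC in set(res[res["level"] == "SOC"]["term"])

    def test_empty_cohort_gives_empty_results(self):
        demo = demo_frame([("1", "a", "20200101", 30.0, "YR", "M")])
        drug = drug_frame([("1", "1", "PS", "SEVOFLURANE")])
        bundle = make_bundle(demo, drug, reac_frame([("1", "Cough")]))
        cohort = build_cohort(bundle, SYNONYMS, stratum="pediatric")
        res = se.evaluate_signals(cohort, pd.DataFrame(columns=["primaryid", "pt"]), {})
        assert res.empty

    def test_report_counting_switch(self, tiny_bundle):
        cohort, bg = self._cohort_and_background(tiny_bundle)
        res = se.evaluate_signals(cohort, bg, self.MAPPING, counting="reports")
        row = res[(res["level"] == "PT") & (res["term"] == "Cough")].iloc[0]
        # 3 pediatric sevoflurane reports, Cough in reports 1, 3, 4
        assert row["a"] == 3


def test_mapping_file_reader(tmp_path):
    p = tmp_path / "map.csv"
    p.write_text("pt,soc\nCough,Respiratory\nNausea,Gastro\n")
    assert se.read_pt_soc_mapping(p) == {"Cough": "Respiratory", "Nausea": "Gastro"}
    p2 = tmp_path / "map.tsv"
    p2.write_text("Cough\tRespiratory\n")
    assert se.read_pt_soc_mapping(p2) == {"Cough": "Respiratory"}
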