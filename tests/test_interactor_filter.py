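"""Filter cascade: predicates, normalization, accounting, oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest

from ipmsflow.interactor_filter import (FilterConfig, FilterLedger,
                                        combine_replicates, crapome_flag,
                                        enrichment_call, lineage_filter,
                                        normalize_against_control, run_cascade)
from ipmsflow.tables_io import CrapomeTable, QuantTable

from conftest import make_quant, random_toy_cascade_inputs


def make_crapome(records):
    """records: protein -> dict(n_experiments, max_spectral_count, avg_spectral_count)."""
    rows = [{"protein_id": p, **r} for p, r in records.items()]
    cols = ["protein_id", "n_experiments", "max_spectral_count", "avg_spectral_count"]
    return CrapomeTable(pd.DataFrame(rows, columns=cols))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_bait_scaled_to_control_total(self):
        t = make_quant([("P1", "G1", "e1", "bait", 1.5e6, 1),
                        ("P2", "G2", "e1", "bait", 0.5e6, 1),
                        ("P1", "G1", "e1", "control", 1e6, 1)])
        out = normalize_against_control(t)
        bait = out.df[out.df.channel == "bait"].set_index("protein_id")["lfq_intensity"]
        assert bait["P1"] == pytest.approx(0.75e6)
        assert bait["P2"] == pytest.approx(0.25e6)

    def test_equal_totals_leave_table_unchanged(self):
        t = make_quant([("P1", "G1", "e1", "bait", 100.0, 1),
                        ("P1", "G1", "e1", "control", 100.0, 1)])
        out = normalize_against_control(t)
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_zero_control_total_names_experiment(self):
        t = make_quant([("P1", "G1", "expA", "bait", 100.0, 1),
                        ("P1", "G1", "expA", "control", 0.0, 0)])
        with pytest.raises(ValueError, match="expA"):
            normalize_against_control(t)


# ---------------------------------------------------------------------------
# enrichment predicate
# ---------------------------------------------------------------------------

class TestEnrichmentCall:
    @pytest.mark.parametrize("bait,control,want_pass,want_enr", [
        (500.0, 0.0, True, None),                 # bait-only detection
        (4000.0, 1000.0, False, 2.0),             # ratio exactly 2: strict fail
        (4100.0, 1000.0, True, math.log2(4.1)),   # log2(4.1) ~ 2.036
        (0.0, 0.0, False, None),                  # undetected
        (0.0, 1000.0, False, math.log2(1 / 1000)),  # control-only, pseudo floor
    ])
    def test_cases(self, bait, control, want_pass, want_enr):
        passed, enr = enrichment_call(bait, control, FilterConfig())
        assert passed is want_pass
        if want_enr is None:
            assert enr is None
        else:
            assert enr == pytest.approx(want_enr)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            enrichment_call(-1.0, 0.0, FilterConfig())


class TestLineageFilter:
    def test_partition(self):
        kept, removed = lineage_filter({"A", "B", "C"}, {"A", "C", "D"})
        assert kept == {"A", "C"} and removed == {"B"}

    def test_subset_removes_nothing(self):
        kept, removed = lineage_filter({"A"}, {"A", "B"})
        assert removed == set()

    def test_empty_expressed_raises(self):
        with pytest.raises(ValueError, match="transcriptome"):
            lineage_filter({"A"}, set())


class TestCrapomeFlag:
    def _rec(self, n_exp, max_sc):
        return pd.Series({"n_experiments": n_exp, "max_spectral_count": max_sc,
                          "avg_spectral_count": min(max_sc, 10)})

    @pytest.mark.parametrize("max_sc,n_ip,flag", [
        (201, 1, True),    # max rule, strict
        (60, 2, True),     # 120 > 100 product rule
        (40, 2, False),    # 80 <= 100 and 40 <= 200
        (50, 2, False),    # boundary product 100 kept
        (101, 1, True),    # product rule at a single experiment
    ])
    def test_rules(self, max_sc, n_ip, flag):
        assert crapome_flag(self._rec(5, max_sc), n_ip, FilterConfig()) is flag

    def test_max_rule_boundary_is_strict(self):
        # isolate the max rule by relaxing the product threshold
        cfg = FilterConfig(crapome_product_threshold=100_000)
        assert crapome_flag(self._rec(5, 200), 1, cfg) is False
        assert crapome_flag(self._rec(5, 201), 1, cfg) is True

    def test_absent_record_is_not_contaminant(self):
        assert crapome_flag(None, 2, FilterConfig()) is False

    def test_repository_count_reading(self):
        cfg = FilterConfig(crapome_n_source="repository")
        # 60 * 2 > 100 under the study reading, but repository n=1 -> 60 <= 100
        assert crapome_flag(self._rec(1, 60), 2, cfg) is False
        assert crapome_flag(self._rec(3, 60), 2, cfg) is True


class TestCombineReplicates:
    def _reps(self):
        a = make_quant([("A", "A", "e1", "bait", 10.0, 1),
                        ("A", "A", "e1", "control", 1.0, 1),
                        ("B", "B", "e1", "bait", 10.0, 2),
                        ("B", "B", "e1", "control", 1.0, 1)])
        b = make_quant([("B", "B", "e2", "bait", 30.0, 1),
                        ("B", "B", "e2", "control", 2.0, 1),
                        ("C", "C", "e2", "bait", 5.0, 1),
                        ("C", "C", "e2", "control", 1.0, 1)])
        return [a, b]

    def test_union_and_intersection(self):
        union = combine_replicates(self._reps(), FilterConfig())
        assert union.proteins() == {"A", "B", "C"}
        inter = combine_replicates(
            self._reps(), FilterConfig(replicate_combination="intersection"))
        assert inter.proteins() == {"B"}

    def test_max_intensity_and_count_retained(self):
        out = combine_replicates(self._reps(), FilterConfig()).to_wide()
        b = out[out.protein_id == "B"].iloc[0]
        assert b.bait_lfq == 30.0 and b.bait_sc == 2

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            combine_replicates([], FilterConfig())


# ---------------------------------------------------------------------------
# ledger
# ---------------------------------------------------------------------------

class TestFilterLedger:
    def test_derived_counts(self):
        led = FilterLedger.from_stage_counts(10, 2, 6, 1)
        assert led.n_after_lineage == 8 and led.n_final == 5

    @pytest.mark.parametrize("kwargs", [
        dict(n_identified=5, n_lineage_removed=1, n_after_lineage=3,
             n_enrichment_pass=2, n_contaminants=0, n_final=2),
        dict(n_identified=5, n_lineage_removed=0, n_after_lineage=5,
             n_enrichment_pass=3, n_contaminants=1, n_final=3),
        dict(n_identified=5, n_lineage_removed=0, n_after_lineage=5,
             n_enrichment_pass=6, n_contaminants=0, n_final=6),
    ])
    def test_inconsistent_counts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterLedger(**kwargs)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def _tables_from_rows(quant_rows):
    return {stage: [make_quant(rows) for rows in reps]
            for stage, reps in quant_rows.items()}


def brute_force_final_set(quant_rows, crapome, expressed, config):
    """Independent per-protein evaluation of the three predicates.

    Pure-dict reimplementation: per experiment equal-total scaling of the
    bait channel, union/intersection replicate combination with max values,
    then specificity, reliability and contamination rules per protein.
    Returns the pooled set of protein ids passing in at least one stage.
    """
    final = set()
    for stage, reps in quant_rows.items():
        per_rep = []
        for rows in reps:
            by_exp = {}
            for p, g, e, ch, lfq, sc in rows:
                by_exp.setdefault(e, []).append((p, g, ch, lfq, sc))
            rep_vals = {}
            for e, entries in by_exp.items():
                bait_total = sum(l for _p, _g, ch, l, _s in entries if ch == "bait")
                ctl_total = sum(l for _p, _g, ch, l, _s in entries if ch == "control")
                scale = ctl_total / bait_total
                for p, g, ch, lfq, sc in entries:
                    v = lfq * scale if ch == "bait" else lfq
                    cur = rep_vals.setdefault(p, {"gene": g, "bait": 0.0,
                                                  "control": 0.0})
                    cur[ch] += v
            per_rep.append(rep_vals)
        if config.replicate_combination == "union":
            proteins = set().union(*[set(r) for r in per_rep])
        else:
            proteins = set.intersection(*[set(r) for r in per_rep])
        for p in proteins:
            vals = [r[p] for r in per_rep if p in r]
            gene = vals[0]["gene"]
            bait = max(v["bait"] for v in vals)
            control = max(v["control"] for v in vals)
            if bait <= 0:
                continue
            if gene not in expressed[stage]:
                continue
            if control == 0:
                enr_pass = bait > 0
            else:
                enr_pass = math.log2(bait / control) > config.log2_ratio_threshold
            if not enr_pass:
                continue
            rec = crapome.get(p)
            if rec is not None:
                n = (rec["n_experiments"] if config.crapome_n_source == "repository"
                     else config.n_ip_experiments)
                if (rec["max_spectral_count"] > config.crapome_max_count_threshold
                        or n * rec["max_spectral_count"] > config.crapome_product_threshold):
                    continue
            final.add(p)
    return final


class TestRunCascade:
    def _toy_inputs(self):
        """10-protein single-stage toy with every failure mode.

        Channel totals are equal so normalization is the identity:
        p1..p4 pass; p5, p6 not expressed; p7 ratio exactly 2 (strict fail),
        p8 ratio < 2, p9 undetected in bait (dropped); p10 contaminant.
        """
        rows = [
            ("p1", "P1", "e1", "bait", 800.0, 5), ("p1", "P1", "e1", "control", 100.0, 1),
            ("p2", "P2", "e1", "bait", 500.0, 5), ("p2", "P2", "e1", "control", 0.0, 0),
            ("p3", "P3", "e1", "bait", 900.0, 5), ("p3", "P3", "e1", "control", 100.0, 1),
            ("p4", "P4", "e1", "bait", 450.0, 5), ("p4", "P4", "e1", "control", 100.0, 1),
            ("p5", "P5", "e1", "bait", 500.0, 5), ("p5", "P5", "e1", "control", 100.0, 1),
            ("p6", "P6", "e1", "bait", 500.0, 5), ("p6", "P6", "e1", "control", 0.0, 0),
            ("p7", "P7", "e1", "bait", 400.0, 5), ("p7", "P7", "e1", "control", 100.0, 1),
            ("p8", "P8", "e1", "bait", 150.0, 5), ("p8", "P8", "e1", "control", 100.0, 1),
            ("p9", "P9", "e1", "bait", 0.0, 0), ("p9", "P9", "e1", "control", 100.0, 1),
            ("p10", "P10", "e1", "bait", 900.0, 5), ("p10", "P10", "e1", "control", 100.0, 1),
        ]
        bait_total = sum(r[4] for r in rows if r[3] == "bait")
        ctl_total = sum(r[4] for r in rows if r[3] == "control")
        rows.append(("anchor", "ANCHOR", "e1", "control",
                     float(bait_total - ctl_total), 1))
        quant_rows = {"OPC": [rows]}
        crapome = {"p10": {"n_experiments": 5, "max_spectral_count": 300,
                           "avg_spectral_count": 40.0}}
        expressed = {"OPC": {"P1", "P2", "P3", "P4", "P7", "P8", "P9", "P10"}}
        return quant_rows, crapome, expressed

    def test_hand_evaluated_toy(self):
        quant_rows, crapome, expressed = self._toy_inputs()
        calls, ledger = run_cascade(_tables_from_rows(quant_rows),
                                    make_crapome(crapome), expressed,
                                    FilterConfig())
        final = {c.protein_id for c in calls if c.final_pass}
        assert final == {"p1", "p2", "p3", "p4"}
        # p9 dropped (control-only); anchor is control-only too
        assert ledger.n_identified == 9
        assert ledger.n_lineage_removed == 2
        assert ledger.n_enrichment_pass == 5  # p1-p4 + contaminant p10
        assert ledger.n_contaminants == 1
        assert ledger.n_final == 4

    def test_matches_brute_force_on_random_toys(self, rng):
        config = FilterConfig()
        for _ in range(15):
            quant_rows, crapome, expressed = random_toy_cascade_inputs(rng)
            calls, ledger = run_cascade(_tables_from_rows(quant_rows),
                                        make_crapome(crapome), expressed, config)
            got = {c.protein_id for c in calls if c.final_pass}
            want = brute_force_final_set(quant_rows, crapome, expressed, config)
            assert got == want
            assert len(want) == ledger.n_final

    def test_ledger_conservation_on_random_toys(self, rng):
        for _ in range(10):
            quant_rows, crapome, expressed = random_toy_cascade_inputs(rng)
            _, led = run_cascade(_tables_from_rows(quant_rows),
                                 make_crapome(crapome), expressed, FilterConfig())
            assert led.n_identified == (led.n_lineage_removed
                                        + (led.n_after_lineage - led.n_enrichment_pass)
                                        + led.n_contaminants + led.n_final)

    def test_threshold_monotonicity(self, rng):
        quant_rows, crapome, expressed = random_toy_cascade_inputs(rng, n_proteins=40)
        tables = _tables_from_rows(quant_rows)
        crap = make_crapome(crapome)

        def final_at(**kw):
            calls, _ = run_cascade(tables, crap, expressed, FilterConfig(**kw))
            return {c.protein_id for c in calls if c.final_pass}

        base = final_at()
        assert final_at(log2_ratio_threshold=3.0) <= base
        assert base <= final_at(crapome_max_count_threshold=10_000,
                                crapome_product_threshold=10_000)

    def test_intersection_mode_is_subset_of_union(self, rng):
        quant_rows, crapome, expressed = random_toy_cascade_inputs(rng, n_proteins=30)
        tables = _tables_from_rows(quant_rows)
        crap = make_crapome(crapome)
        calls_u, _ = run_cascade(tables, crap, expressed, FilterConfig())
        cfg_i = FilterConfig(replicate_combination="intersection")
        calls_i, _ = run_cascade(tables, crap, expressed, cfg_i)
        got_i = {c.protein_id for c in calls_i if c.final_pass}
        want_i = brute_force_final_set(quant_rows, crapome, expressed, cfg_i)
        assert got_i == want_i

    def test_empty_final_set_is_valid(self):
        quant_rows = {"OPC": [[("p1", "P1", "e1", "bait", 100.0, 1),
                               ("p1", "P1", "e1", "control", 100.0, 1)]]}
        calls, led = run_cascade(_tables_from_rows(quant_rows),
                                 make_crapome({}), {"OPC": {"P1"}},
                                 FilterConfig())
        assert led.n_final == 0
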