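"""Instrument selection: significance, clumping, restriction, exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabmr.instruments import (InstrumentSet, apply_exclusion_list,
                                 filter_iv_count, ld_clump,
                                 restrict_cross_exposure, select_by_pvalue,
                                 select_instruments)
from metabmr.io import EXPOSURE, LDPanel, SummaryTable


def exposure_table(snps, trait_id="E1"):
    """snps: list of (snp_id, chrom, pos, pval)."""
    df = pd.DataFrame(snps, columns=["snp_id", "chrom", "pos", "pval"])
    df["effect_allele"], df["other_allele"] = "A", "G"
    df["eaf"], df["beta"], df["se"], df["n"] = 0.3, 0.1, 0.02, 1000
    return SummaryTable(trait_id, EXPOSURE, df)


def brute_force_clump(snps, r2, r2_cutoff, window_bp):
    """Direct transcription of the greedy rule with explicit loops.

    snps: list of (snp_id, chrom, pos, pval); r2: dict of frozenset -> value.
    """
    remaining = sorted(snps, key=lambda s: (s[3], s[1], s[2], s[0]))
    removed, kept = set(), []
    for idx in remaining:
        if idx[0] in removed:
            continue
        kept.append(idx[0])
        for other in remaining:
            if other[0] == idx[0] or other[0] in removed:
                continue
            same_chrom = other[1] == idx[1]
            close = abs(other[2] - idx[2]) <= window_bp
            linked = r2.get(frozenset((idx[0], other[0])), 0.0) > r2_cutoff
            if same_chrom and close and linked:
                removed.add(other[0])
    return set(kept)


class TestSelectByPvalue:
    def test_strict_threshold_boundary(self):
        t = exposure_table([("rs1", "1", 100, 2e-6), ("rs2", "1", 200, 1e-5),
                            ("rs3", "1", 300, 0.3)])
        assert select_by_pvalue(t, 1e-5).snp_ids == ["rs1"]

    def test_threshold_one_keeps_all(self):
        t = exposure_table([("rs1", "1", 100, 2e-6), ("rs2", "1", 200, 0.99)])
        assert len(select_by_pvalue(t, 1.0)) == 2

    def test_uniform_pvalues_rarely_pass(self, rng):
        pvals = rng.uniform(size=200)
        t = exposure_table([(f"rs{i}", "1", i * 1000, p)
                            for i, p in enumerate(pvals)])
        # binomial expectation 200 * 1e-5 = 0.002
        assert len(select_by_pvalue(t, 1e-5)) <= 1


class TestLDClump:
    def test_worked_example_keeps_index_snp(self):
        t = exposure_table([("s1", "1", 100_000, 1e-8),
                            ("s2", "1", 200_000, 1e-7),
                            ("s3", "2", 100_000, 1e-6)])
        panel = LDPanel(["s1", "s2", "s3"])
        panel.set_r2("s1", "s2", 0.5)
        out = ld_clump(select_by_pvalue(t, 1e-5), t, panel,
                       r2_cutoff=0.001, window_kb=10_000)
        assert set(out.snp_ids) == {"s1", "s3"}
        assert out.provenance["s2"].startswith("removed_clump")

    def test_no_ld_no_removal(self):
        t = exposure_table([("s1", "1", 100, 1e-8), ("s2", "1", 200, 1e-7)])
        panel = LDPanel(["s1", "s2"])
        cand = select_by_pvalue(t, 1e-5)
        assert ld_clump(cand, t, panel).snp_ids == cand.snp_ids

    def test_outside_window_both_kept(self):
        t = exposure_table([("s1", "1", 1_000_000, 1e-8),
                            ("s2", "1", 21_000_000, 1e-7)])
        panel = LDPanel(["s1", "s2"])
        panel.set_r2("s1", "s2", 0.5)
        out = ld_clump(select_by_pvalue(t, 1e-5), t, panel,
                       window_kb=10_000)
        assert set(out.snp_ids) == {"s1", "s2"}

    def test_missing_panel_snp_kept_or_dropped_by_policy(self):
        t = exposure_table([("s1", "1", 100, 1e-8), ("s2", "1", 200, 1e-7)])
        panel = LDPanel(["s1"])
        cand = select_by_pvalue(t, 1e-5)
        assert "s2" in ld_clump(cand, t, panel).snp_ids
        assert "s2" not in ld_clump(cand, t, panel,
                                    missing_snp_policy="drop").snp_ids

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(2, 11))
        snps = [(f"s{i}", str(rng.integers(1, 3)),
                 int(rng.integers(1, 3)) * 500_000,
                 float(rng.uniform(1e-10, 1e-6))) for i in range(J)]
        r2 = {}
        panel = LDPanel([s[0] for s in snps])
        for i in range(J):
            for j in range(i + 1, J):
                if rng.random() < 0.4:
                    v = float(rng.uniform())
                    r2[frozenset((snps[i][0], snps[j][0]))] = v
                    panel.set_r2(snps[i][0], snps[j][0], v)
        t = exposure_table(snps)
        expected = brute_force_clump(snps, r2, 0.1, 600_000)
        got = ld_clump(select_by_pvalue(t, 1.0), t, panel,
                       r2_cutoff=0.1, window_kb=600)
        assert set(got.snp_ids) == expected
        # invariance to candidate input order
        shuffled = InstrumentSet("E1", list(rng.permutation(
            [s[0] for s in snps])))
        got2 = ld_clump(shuffled, t, panel, r2_cutoff=0.1, window_kb=600)
        assert set(got2.snp_ids) == expected
        # retained pairs satisfy the cutoff within the window
        for a in got.snp_ids:
            for b in got.snp_ids:
                if a < b:
                    pa = next(s for s in snps if s[0] == a)
                    pb = next(s for s in snps if s[0] == b)
                    if pa[1] == pb[1] and abs(pa[2] - pb[2]) <= 600_000:
                        assert panel.r2(a, b) <= 0.1


class TestCrossExposureRestriction:
    def make(self, pvals_by_exposure):
        tables, sets = [], {}
        for eid, pvals in pvals_by_exposure.items():
            t = exposure_table([(s, "1", i * 1000, p)
                                for i, (s, p) in enumerate(pvals.items())],
                               trait_id=eid)
            tables.append(t)
            sets[eid] = select_by_pvalue(t, 1e-5)
        return tables, sets

    def test_shared_snp_removed_from_both(self):
        tables, sets = self.make({
            "E1": {"rs1": 1e-8, "rs2": 1e-9},
            "E2": {"rs1": 1e-7, "rs3": 1e-9},
        })
        out = restrict_cross_exposure(sets, tables)
        assert "rs1" not in out["E1"].snp_ids
        assert "rs1" not in out["E2"].snp_ids
        assert out["E1"].provenance["rs1"] == "removed_cross_exposure"

    def test_private_snp_retained(self):
        tables, sets = self.make({
            "E1": {"rs1": 1e-8}, "E2": {"rs3": 1e-9},
        })
        out = restrict_cross_exposure(sets, tables)
        assert "rs1" in out["E1"].snp_ids


class TestExclusionAndCount:
    def test_exclusion_list_set_difference(self):
        iset = InstrumentSet("E1", ["rs1", "rs2", "rs3"])
        assert apply_exclusion_list(iset, []).snp_ids == ["rs1", "rs2", "rs3"]
        assert apply_exclusion_list(iset, ["rs2"]).snp_ids == ["rs1", "rs3"]
        assert apply_exclusion_list(iset, ["rs9"]).snp_ids == \
            ["rs1", "rs2", "rs3"]

    @pytest.mark.parametrize("n, kept", [(2, False), (3, True), (100, True),
                                         (101, False)])
    def test_iv_count_boundaries(self, n, kept):
        sets = {"E1": InstrumentSet("E1", [f"rs{i}" for i in range(n)])}
        assert ("E1" in filter_iv_count(sets)) is kept


def test_filter_trace_monotonic_and_composition(rng):
    tables = []
    for e in range(3):
        pvals = rng.uniform(size=30)
        pvals[:6] = 1e-8  # six instruments each; rs0..rs5 shared across all
        tables.append(exposure_table(
            [(f"rs{i}", "1", i * 20_000_000, p) for i, p in enumerate(pvals)],
            trait_id=f"E{e}"))
    kept, traces, removed = select_instruments(
        tables, panel=None, exclusion=["rs5"])
    for eid, trace in traces.items():
        assert trace.monotonic
    # shared instruments removed everywhere -> everyone fails the IV count
    assert kept == {} and len(removed) == 3
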