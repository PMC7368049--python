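"""Promoter windows, motif scanning, occupancy calls and rank tests."""

from itertools import combinations as _combos

import numpy as np
import pytest

from hetinsul.genome_io import Interval, Peak, PeakSet, SequenceSet
from hetinsul.occupancy import (
    BEAF32_MOTIF,
    DREF_MOTIF,
    MotifSpec,
    OccupancyRecord,
    call_occupancy,
    classify_binding,
    compare_groups,
    occupancy_combinations,
    promoter_window,
    scan_motif,
)
from hetinsul.stats import fisher_exact_2x2, mann_whitney

from conftest import make_gene


class TestPromoterWindow:
    def test_plus_strand(self):
        g = make_gene("g", start=1000, end=3000, strand="+")
        assert promoter_window(g, 200).interval == Interval("chr2L", 800, 1000, "+")

    def test_minus_strand_symmetry(self):
        g = make_gene("g", start=0, end=2000, strand="-")  # tss = 1999
        assert promoter_window(g, 200).interval == Interval("chr2L", 2000, 2200, "-")

    def test_clipped_at_chromosome_start(self):
        g = make_gene("g", start=50, end=2050, strand="+")
        assert promoter_window(g, 200).interval == Interval("chr2L", 0, 50, "+")


class TestScanMotif:
    def test_cgata_inside_dref_consensus(self):
        # the BEAF-32 recognition motif is contained in the Dref site
        hits = scan_motif("TATCGATA", BEAF32_MOTIF)
        assert (3, "+") in hits

    def test_reverse_complement_hit(self):
        # revcomp(CGATA) = TATCG
        assert scan_motif("TATCG", BEAF32_MOTIF) == [(0, "-")]

    def test_empty_sequence(self):
        assert scan_motif("", BEAF32_MOTIF) == []

    def test_overlapping_matches_all_reported(self):
        hits = scan_motif("GAGAGAG", MotifSpec("GAF", "GAGAG"))
        assert [(0, "+"), (2, "+")] == [h for h in hits if h[1] == "+"]

    def test_iupac_codes(self):
        m = MotifSpec("amb", "CRATA", scan_both_strands=False)
        assert scan_motif("CGATA", m) == [(0, "+")]
        assert scan_motif("CAATA", m) == [(0, "+")]
        assert scan_motif("CCATA", m) == []

    def test_single_strand_scan(self):
        m = MotifSpec("b", "CGATA", scan_both_strands=False)
        assert scan_motif("TATCG", m) == []


class TestCallOccupancy:
    def make(self, peaks, extended=False):
        g = make_gene("g", start=1000, end=3000, strand="+")
        win = promoter_window(g, 200)
        ps = PeakSet("BEAF-32", peaks)
        return call_occupancy(g, ps, win, extended=extended)

    def test_overlapping_peak_occupies(self):
        rec, peak = self.make([Peak(Interval("chr2L", 850, 950), signal_value=3.0)])
        assert rec.occupied and rec.peak_signal == 3.0
        assert peak.interval.start == 850

    def test_distant_peak_not_occupied_even_extended(self):
        rec, _ = self.make(
            [Peak(Interval("chr2L", 13_200, 13_400), signal_value=3.0)],
            extended=True,  # 10 kb upstream cutoff; peak is 12 kb upstream
        )
        assert not rec.occupied and rec.peak_signal is None

    def test_extended_mode_reaches_upstream(self):
        rec, _ = self.make(
            [Peak(Interval("chr2L", 0, 100), signal_value=3.0)], extended=True
        )
        assert rec.occupied

    def test_max_signal_peak_wins(self):
        rec, peak = self.make([
            Peak(Interval("chr2L", 850, 950), signal_value=5.0),
            Peak(Interval("chr2L", 900, 980), signal_value=9.0, summit_offset=40),
        ])
        assert rec.peak_signal == 9.0
        assert rec.distance_to_tss == abs(940 - 1000)  # summit of the winner


class TestClassifyBinding:
    genome = SequenceSet({"chr2L": "A" * 500 + "TATCGATA" + "A" * 500})

    def occupied(self):
        return OccupancyRecord("g", "BEAF-32", occupied=True, peak_signal=1.0)

    def test_motif_in_peak_is_direct(self):
        peak = Peak(Interval("chr2L", 450, 560), signal_value=1.0)
        assert classify_binding(self.occupied(), peak, self.genome,
                                BEAF32_MOTIF).binding == "direct"

    def test_no_motif_is_indirect(self):
        peak = Peak(Interval("chr2L", 0, 100), signal_value=1.0)
        assert classify_binding(self.occupied(), peak, self.genome,
                                BEAF32_MOTIF).binding == "indirect"

    def test_minus_strand_motif_is_direct(self):
        genome = SequenceSet({"chr2L": "AAAA" + "TATCG" + "AAAA"})  # revcomp(CGATA)
        peak = Peak(Interval("chr2L", 0, 13), signal_value=1.0)
        assert classify_binding(self.occupied(), peak, genome,
                                BEAF32_MOTIF).binding == "direct"

    def test_unoccupied_record_rejected(self):
        with pytest.raises(ValueError):
            classify_binding(
                OccupancyRecord("g", "BEAF-32", occupied=False),
                Peak(Interval("chr2L", 0, 10), signal_value=1.0),
                self.genome, BEAF32_MOTIF,
            )


class TestOccupancyCombinations:
    factors = ("BEAF-32", "GAF", "dCTCF")

    @staticmethod
    def recs(gene, present):
        return [
            OccupancyRecord(gene, f, occupied=f in present,
                            peak_signal=1.0 if f in present else None)
            for f in ("BEAF-32", "GAF", "dCTCF")
        ]

    def test_example_counts(self):
        records = {
            "a": self.recs("a", {"BEAF-32"}),
            "b": self.recs("b", {"BEAF-32", "GAF", "dCTCF"}),
            "c": self.recs("c", set()),
        }
        counts = occupancy_combinations(records, self.factors)
        assert counts[frozenset({"BEAF-32"})] == 1
        assert counts[frozenset(self.factors)] == 1
        assert counts[frozenset()] == 1
        assert sum(counts.values()) == 3

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        records = {}
        for i in range(60):
            present = {f for f in self.factors if rng.random() < 0.5}
            records[f"g{i}"] = self.recs(f"g{i}", present)
        counts = occupancy_combinations(records, self.factors)
        assert len(counts) == 8
        assert sum(counts.values()) == 60


def enumeration_oracle_mw(x, y):
    """Independent exact two-sided P: count U over all C(n, n1) labelings
    by direct pairwise comparison (no rank arithmetic)."""
    from itertools import combinations
    from math import comb

    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)

    def u_of(ix):
        xs = [pooled[i] for i in ix]
        ys = [pooled[i] for i in range(n) if i not in set(ix)]
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    mu = n1 * (n - n1) / 2
    obs = abs(u_of(tuple(range(n1))) - mu)
    hits = sum(1 for ix in combinations(range(n), n1)
               if abs(u_of(ix) - mu) >= obs - 1e-12)
    return hits / comb(n, n1)


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme

    def test_identical_multisets_p_one(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3], mode="exact")
        assert res.p_value == 1.0

    def test_normal_approx_close_to_permutation_at_n30(self):
        # Monte-Carlo permutation oracle for n1 = n2 = 30, where full
        # enumeration is infeasible
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        pooled = np.concatenate([x, y])
        mu = 30 * 30 / 2
        def u_stat(a, b):
            return float((a[:, None] > b[None, :]).sum()
                         + 0.5 * (a[:, None] == b[None, :]).sum())

        obs = abs(u_stat(x, y) - mu)
        hits = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            hits += abs(u_stat(perm[:30], perm[30:]) - mu) >= obs - 1e-12
        mc_p = hits / n_perm
        approx = mann_whitney(x, y, mode="normal_approx").p_value
        assert abs(mc_p - approx) < 0.05

    def test_auto_mode_switches_on_size_and_ties(self):
        small = mann_whitney([1, 2, 3], [4, 5, 6], mode="auto")
        assert small.method == "mann_whitney_exact"
        tied = mann_whitney([1, 1, 2], [2, 3, 4], mode="auto")
        assert tied.method == "mann_whitney_normal_approx"

    def test_medians_reported(self):
        res = mann_whitney([8, 8, 9], [9, 9.5, 10], mode="exact")
        assert res.medians == (8.0, 9.5)


class TestCompareGroups:
    @staticmethod
    def rec(gene, binding, signal):
        return OccupancyRecord(gene, "BEAF-32", occupied=True,
                               peak_signal=signal, binding=binding)

    def test_single_group_no_tests(self):
        recs = [self.rec(f"g{i}", "direct", 5.0 + i) for i in range(4)]
        summary, tests = compare_groups(recs, lambda r: r.binding)
        assert len(summary) == 1 and not tests

    def test_identical_groups_p_one(self):
        recs = [self.rec(f"a{i}", "direct", v) for i, v in enumerate([3, 4, 5])]
        recs += [self.rec(f"b{i}", "indirect", v) for i, v in enumerate([3, 4, 5])]
        summary, tests = compare_groups(recs, lambda r: r.binding, mode="exact")
        med = {s["group"]: s["median_signal"] for s in summary}
        assert med["direct"] == med["indirect"]
        assert tests[("direct", "indirect")].p_value == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        recs = [self.rec(f"d{i}", "direct", float(v))
                for i, v in enumerate(rng.lognormal(np.log(11), 0.4, 40))]
        recs += [self.rec(f"i{i}", "indirect", float(v))
                 for i, v in enumerate(rng.lognormal(np.log(5), 0.4, 40))]
        summary, tests = compare_groups(recs, lambda r: r.binding)
        med = {s["group"]: s["median_signal"] for s in summary}
        assert med["direct"] > med["indirect"]
        assert tests[("direct", "indirect")].p_value < 0.01
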