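"""Context annotation, conversion QC, window filters, and DMR calling."""

import numpy as np
import pandas as pd
import pytest

from poetools import methylome as me, simulate as sim
from poetools.io import GenomeSequence


def calls_frame(rows):
    df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "context",
                                     "n_meth", "n_total", "allele"])
    return df


class TestPileupContexts:
    genome = GenomeSequence({"chr1": "ACGTCATCCG"})
    #                         0123456789

    def test_plus_strand_contexts(self):
        calls = calls_frame([("chr1", 1, "+", "", 0, 5, "ambiguous"),   # CGT -> CG
                             ("chr1", 4, "+", "", 0, 5, "ambiguous"),   # CAT -> CHH
                             ("chr1", 7, "+", "", 0, 5, "ambiguous")])  # CCG -> CHG
        out = me.pileup_contexts(calls, self.genome)
        assert dict(zip(out["pos"], out["context"])) == \
            {1: "CG", 4: "CHH", 7: "CHG"}

    def test_minus_strand_context_read_on_reverse_complement(self):
        # G at 9: minus-strand triplet is revcomp of seq[7:10]="CCG" -> CGG
        # -> CG; G at 2: revcomp of seq[0:3]="ACG" -> CGT -> CG
        calls = calls_frame([("chr1", 9, "-", "", 0, 5, "ambiguous"),
                             ("chr1", 2, "-", "", 0, 5, "ambiguous")])
        out = me.pileup_contexts(calls, self.genome)
        assert list(out["context"]) == {9: ["CG"], 2: ["CG"]}[9] + ["CG"]

    def test_non_cytosine_position_raises(self):
        calls = calls_frame([("chr1", 0, "+", "", 0, 5, "ambiguous")])
        with pytest.raises(ValueError, match="not a reference C"):
            me.pileup_contexts(calls, self.genome)

    def test_simulator_contexts_match_pileup(self, sim_truth):
        meth = sim.simulate_methylome(sim_truth, "WT", 0, contigs=["chrC"])
        sample = meth.sample(500, random_state=0).drop(columns=["context"])
        out = me.pileup_contexts(sample.copy(), sim_truth.genome)
        merged = out.merge(meth, on=["contig", "pos", "strand", "allele"],
                           suffixes=("_derived", "_truth"))
        assert (merged["context_derived"] == merged["context_truth"]).all()


class TestConversionQc:
    def test_rate_arithmetic(self):
        calls = calls_frame([("chrC", i, "+", "CHH", m, t, "ambiguous")
                             for i, (m, t) in enumerate([(10, 1000)])])
        rate, ok = me.conversion_qc(calls, "chrC")
        assert rate == pytest.approx(99.0)
        assert ok

    def test_low_depth_cytosines_excluded(self):
        calls = calls_frame([
            ("chrC", 0, "+", "CHH", 9, 9, "ambiguous"),    # depth 9: dropped
            ("chrC", 1, "+", "CHH", 1, 100, "ambiguous"),
        ])
        rate, ok = me.conversion_qc(calls, "chrC", min_depth=10)
        assert rate == pytest.approx(99.0)

    def test_no_qualifying_cytosine_raises(self):
        calls = calls_frame([("chrC", 0, "+", "CHH", 0, 5, "ambiguous")])
        with pytest.raises(ValueError, match="depth"):
            me.conversion_qc(calls, "chrC", min_depth=10)

    def test_simulated_conversion_recovered(self, sim_truth):
        meth = sim.simulate_methylome(sim_truth, "WT", 0, contigs=["chrC"])
        rate, ok = me.conversion_qc(meth, "chrC")
        # truth conversion success is 0.99 -> apparent methylation ~1%
        assert rate == pytest.approx(99.0, abs=0.2)
        assert ok


def two_condition_calls(c_pattern, depth=10):
    """Helper: same cytosines in A and B with given per-C (m_a, m_b)."""
    rows_a, rows_b = [], []
    for pos, (ma, mb) in c_pattern.items():
        rows_a.append(("chr1", pos, "+", "CHH", ma, depth, "ambiguous"))
        rows_b.append(("chr1", pos, "+", "CHH", mb, depth, "ambiguous"))
    return calls_frame(rows_a), calls_frame(rows_b)


class TestWindowMethylation:
    lengths = {"chr1": 600}

    def test_weighted_percent_arithmetic(self):
        a, b = two_condition_calls({10: (2, 2), 20: (0, 0), 30: (5, 5),
                                    40: (3, 3)})
        win = me.window_methylation(a, b, {"chr1": 300}, min_depth=6)
        first = win.iloc[0]
        assert first["pct_a"] == pytest.approx(25.0)
        assert first["delta"] == pytest.approx(0.0)

    def test_min_common_c_filter(self):
        a, b = two_condition_calls({10: (2, 2), 20: (1, 1)})
        win = me.window_methylation(a, b, {"chr1": 300}, min_common_c=3)
        assert win.empty

    def test_uncommon_cytosines_do_not_count(self):
        a, b = two_condition_calls({10: (2, 2), 20: (0, 0), 30: (5, 5)})
        # B loses coverage at pos 30 -> only 2 common Cs remain
        b.loc[b["pos"] == 30, "n_total"] = 0
        b.loc[b["pos"] == 30, "n_meth"] = 0
        win = me.window_methylation(a, b, {"chr1": 300}, min_common_c=3)
        assert win.empty

    def test_mean_depth_filter(self):
        a, b = two_condition_calls({10: (0, 0), 20: (0, 0), 30: (0, 0)},
                                   depth=5)
        assert me.window_methylation(a, b, {"chr1": 300},
                                     min_depth=6).empty
        assert not me.window_methylation(a, b, {"chr1": 300},
                                         min_depth=5).empty


class TestDosageFilter:
    def make_windows(self):
        return pd.DataFrame({
            "contig": ["chr1"] * 3, "start": [0, 100, 200],
            "end": [300, 400, 500], "context": ["CHH"] * 3,
            "delta": [15.0, 15.0, 15.0]})

    @pytest.mark.parametrize("pct,kept", [
        (67.0, True), (52.0, True), (82.0, True),  # inclusive bounds
        (90.0, False), (51.9, False),
    ])
    def test_boundaries(self, pct, kept):
        win = self.make_windows().iloc[:1]
        frac = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [300],
                             "percent_maternal": [pct],
                             "n_allelic_reads": [50.0]})
        out = me.dosage_filter(win, frac)
        assert (len(out) == 1) is kept

    def test_windows_without_allelic_reads_dropped(self):
        win = self.make_windows()
        frac = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [300],
                             "percent_maternal": [67.0],
                             "n_allelic_reads": [50.0]})
        out = me.dosage_filter(win, frac)
        assert list(out["start"]) == [0]

    def test_simulated_dna_dosage_passes_filter(self, sim_truth):
        meth = sim.simulate_methylome(sim_truth, "WT", 0, contigs=["chr1"])
        frac = me.window_maternal_fraction(meth, {"chr1": 200_000})
        inside = frac["percent_maternal"].between(52, 82).mean()
        assert inside > 0.99


class TestReplicateMaskAndDmrs:
    def test_replicate_mask_collects_variable_windows(self):
        win = pd.DataFrame({
            "contig": ["chr1", "chr1"], "start": [0, 300],
            "end": [300, 600], "context": ["CHH", "CHH"],
            "delta": [25.0, 2.0]})
        mask = me.replicate_mask(win)
        assert mask == [("chr1", 0, 300, "CHH")]
        assert me.apply_mask(win, mask)["start"].tolist() == [300]

    def test_identical_replicates_empty_mask(self):
        win = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [300],
                            "context": ["CG"], "delta": [0.0]})
        assert me.replicate_mask(win) == []

    def window_row(self, start, context, pct_a, pct_b, contig="chr1"):
        t = 1000.0
        return {"contig": contig, "start": start, "end": start + 300,
                "context": context, "n_common": 10,
                "pct_a": pct_a, "pct_b": pct_b, "delta": pct_b - pct_a,
                "depth_a": 10, "depth_b": 10,
                "m_a": pct_a * 10, "t_a": t, "m_b": pct_b * 10, "t_b": t}

    def test_context_thresholds(self):
        win = pd.DataFrame([
            self.window_row(0, "CHH", 20.0, 5.0),    # delta 15 >= 10: DMR
            self.window_row(600, "CG", 60.0, 35.0),  # delta 25 < 30: no
            self.window_row(1200, "CHG", 50.0, 25.0),  # delta 25 >= 20: DMR
        ])
        dmrs = me.call_dmrs(win)
        assert {(d.context, d.direction) for d in dmrs} == \
            {("CHH", "hypo"), ("CHG", "hypo")}

    def test_overlapping_windows_merge_and_recompute(self):
        win = pd.DataFrame([self.window_row(0, "CHH", 30.0, 10.0),
                            self.window_row(100, "CHH", 20.0, 5.0)])
        (dmr,) = me.call_dmrs(win)
        assert (dmr.start, dmr.end, dmr.n_windows) == (0, 400, 2)
        assert dmr.pct_a == pytest.approx(25.0)  # pooled over both windows

    def test_mixed_directions_never_merge(self):
        win = pd.DataFrame([self.window_row(0, "CHH", 30.0, 10.0),
                            self.window_row(100, "CHH", 5.0, 25.0)])
        dmrs = me.call_dmrs(win)
        assert {d.direction for d in dmrs} == {"hypo", "hyper"}
        assert len(dmrs) == 2

    def test_direction_flips_under_condition_swap(self):
        win = pd.DataFrame([self.window_row(0, "CHH", 30.0, 10.0)])
        swapped = win.rename(columns={"pct_a": "pct_b", "pct_b": "pct_a",
                                      "m_a": "m_b", "m_b": "m_a",
                                      "t_a": "t_b", "t_b": "t_a",
                                      "depth_a": "depth_b",
                                      "depth_b": "depth_a"})
        swapped["delta"] = -win["delta"]
        (fwd,) = me.call_dmrs(win)
        (rev,) = me.call_dmrs(swapped)
        assert (fwd.direction, rev.direction) == ("hypo", "hyper")
        assert (fwd.start, fwd.end) == (rev.start, rev.end)

    def test_output_invariant_to_window_order(self):
        win = pd.DataFrame([self.window_row(s, "CHH", 25.0, 5.0)
                            for s in (400, 0, 100, 800)])
        shuffled = win.sample(frac=1.0, random_state=1)
        a = me.call_dmrs(win)
        b = me.call_dmrs(shuffled)
        assert [(d.contig, d.start, d.end) for d in a] == \
            [(d.contig, d.start, d.end) for d in b]
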