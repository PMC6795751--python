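"""Seed-and-verify alignment, unit assignment, NMJ filtering, RMRJs."""

import numpy as np
import pytest

from ribocirc import junctionmap as jm
from ribocirc.pseudoref import CircRNA, build_virtual_genome
from ribocirc.readprep import Read


def brute_force_alignments(ref, seq, max_mismatch, read_id=""):
    """Independent oracle: Hamming scan over every offset, both strands."""
    out = []
    for strand, oriented in (("+", seq), ("-", jm.revcomp(seq))):
        for s in range(len(ref) - len(seq) + 1):
            window = ref[s:s + len(seq)]
            if "N" in window:
                continue
            mm = sum(1 for a, b in zip(window, oriented) if a != b or b == "N")
            if mm <= max_mismatch:
                out.append(jm.Alignment(s, strand, s + len(seq), mm, read_id))
    return sorted(set(out))


def mk_read(seq, rid="r"):
    return Read(rid, seq, (35,) * len(seq))


class TestIndex:
    def test_kmer_positions(self):
        idx = jm.build_index("ACGTACGT", k=4)
        assert idx.positions("ACGT") == (0, 4)
        assert idx.positions("CGTA") == (1,)
        assert idx.positions("AAAA") == ()

    def test_n_kmers_excluded(self):
        assert jm.build_index("NNNN", k=2).table == {}

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            jm.build_index("", k=4)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            jm.build_index("ACGT", k=0)
        with pytest.raises(ValueError):
            jm.build_index("ACGT", k=5)


class TestAlignRead:
    def test_exact_substring_occurrences(self):
        idx = jm.build_index("ACGTACGTACGT", k=4)
        hits = jm.align_read(mk_read("GTAC"), idx, max_mismatch=0)
        plus = [a.start for a in hits if a.strand == "+"]
        assert plus == [2, 6]

    def test_one_mismatch_matches_brute_force(self):
        ref = "ACGTACGTACGT"
        idx = jm.build_index(ref, k=2)
        hits = jm.align_read(mk_read("GTAT"), idx, max_mismatch=1)
        assert hits == brute_force_alignments(ref, "GTAT", 1, "r")

    def test_no_hit_returns_empty(self):
        idx = jm.build_index("A" * 40, k=4)
        assert jm.align_read(mk_read("GGGG"), idx, max_mismatch=1) == []

    def test_alignments_never_overlap_spacer_n(self):
        ref = "ACGTACGT" + "N" * 10 + "ACGTACGT"
        idx = jm.build_index(ref, k=4)
        for a in jm.align_read(mk_read("GTACGT"), idx, max_mismatch=2):
            assert "N" not in ref[a.start:a.end]

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_pigeonhole_equals_brute_force_on_random_instances(self, rng, max_mismatch):
        for _ in range(30):
            ref = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 400))))
            idx = jm.build_index(ref, k=6)
            read_len = int(rng.integers(20, 41))
            if rng.random() < 0.5:  # planted, then mutated
                s = int(rng.integers(0, len(ref) - read_len))
                seq = list(ref[s:s + read_len])
                for _ in range(int(rng.integers(0, max_mismatch + 1))):
                    p = int(rng.integers(0, read_len))
                    seq[p] = "ACGT"[int(rng.integers(0, 4))]
                seq = "".join(seq)
            else:
                seq = "".join(rng.choice(list("ACGT"), size=read_len))
            got = jm.align_read(mk_read(seq), idx, max_mismatch)
            assert got == brute_force_alignments(ref, seq, max_mismatch, "r")

    def test_read_shorter_than_seed_skipped_with_warning(self, caplog):
        idx = jm.build_index("ACGTACGTACGT", k=8)
        with caplog.at_level("WARNING"):
            assert jm.align_read(mk_read("ACG"), idx, 0) == []
        assert "shorter than seed" in caplog.text


class TestSpansJunction:
    @pytest.mark.parametrize("interval,overhang,expected", [
        ((4, 10), 1, True),
        ((6, 12), 1, False),   # starts at the junction: no 5' base
        ((4, 10), 5, False),
    ])
    def test_overhang_rule(self, interval, overhang, expected):
        aln = jm.Alignment(interval[0], "+", interval[1], 0, "r")
        assert jm.spans_junction(aln, junction=6, min_overhang=overhang) is expected


class TestAssignToUnits:
    def test_tandem_shadow_collapsed_to_leftmost_when_not_spanning(self):
        vg = build_virtual_genome([CircRNA("A", "ACGTTC")], spacer=10)
        # read matching monomer [1,5): placements at s=1 and shadow s=7
        alns = jm.align_read(mk_read("CGTT"), jm.build_index(vg.layout, 4), 0)
        placements = jm.assign_to_units({"r": alns}, vg)
        assert len(placements) == 1
        assert placements[0].alignment.start == 1
        assert placements[0].spanning is False

    def test_junction_spanning_placement_preferred(self):
        vg = build_virtual_genome([CircRNA("A", "ACGTTC")], spacer=10)
        # "TCAC" = monomer[4:6] + monomer[0:2]: spans J=6 at s=4
        alns = jm.align_read(mk_read("TCAC"), jm.build_index(vg.layout, 4), 0)
        placements = jm.assign_to_units({"r": alns}, vg)
        assert len(placements) == 1
        assert placements[0].spanning is True
        assert placements[0].alignment.start == 4

    def test_read_hitting_two_units_discarded(self):
        vg = build_virtual_genome(
            [CircRNA("A", "ACGTACGTAA"), CircRNA("B", "TTACGTACGG")], spacer=20)
        alns = jm.align_read(mk_read("ACGTACG"), jm.build_index(vg.layout, 3), 0)
        units = {vg.unit_of(a.start).circ_id for a in alns}
        assert units == {"A", "B"}
        assert jm.assign_to_units({"r": alns}, vg) == []


class TestComputeRmrjs:
    @staticmethod
    def _placements(vg, intervals, spanning_all=True):
        unit = vg.units[0]
        out = []
        for i, (s, e) in enumerate(intervals):
            aln = jm.Alignment(s, "+", e, 0, f"r{i}")
            out.append(jm.Placement(f"r{i}", unit, aln,
                                    jm.spans_junction(aln, unit.junction)))
        return out

    @pytest.fixture
    def vg(self):
        return build_virtual_genome([CircRNA("A", "ACGTTCGATCGG")], spacer=10)

    def test_four_spanning_reads_pass_three_fail(self, vg):
        # junction at 12; nmj_min=3: strictly more than 3 reads required
        four = self._placements(vg, [(8, 16)] * 4)
        three = self._placements(vg, [(8, 16)] * 3)
        assert jm.compute_rmrjs(four, vg)[0].nmj == 4
        assert jm.compute_rmrjs(three, vg) == []

    def test_interval_is_union_of_spanning_reads(self, vg):
        # J = 12; intervals [8,16) and [10,18) -> RMRJ [8,18)
        pl = self._placements(vg, [(8, 16), (10, 18), (8, 16), (10, 18), (9, 17)])
        rmrj = jm.compute_rmrjs(pl, vg)[0]
        assert (rmrj.start, rmrj.end) == (8, 18)
        assert rmrj.seq == vg.layout[8:18]
        assert rmrj.junction_offset == 4
        assert "N" not in rmrj.seq

    def test_nmj_monotone_in_depth(self, vg):
        pl = self._placements(vg, [(8, 16)] * 4)
        more = self._placements(vg, [(8, 16)] * 4 + [(9, 17)] * 2)
        assert jm.compute_rmrjs(more, vg)[0].nmj > jm.compute_rmrjs(pl, vg)[0].nmj
        assert len(jm.compute_rmrjs(more, vg)) >= len(jm.compute_rmrjs(pl, vg))

    def test_deduplication_collapses_identical_intervals(self, vg):
        pl = self._placements(vg, [(8, 16)] * 5)
        assert jm.compute_rmrjs(pl, vg, deduplicate=True) == []  # 1 distinct


class TestSamRoundtrip:
    def test_external_sam_reproduces_placements(self, tmp_path):
        vg = build_virtual_genome(
            [CircRNA("A", "ACGTTCGATCGGACGTAAGGCCTT")], spacer=100)
        reads = [mk_read(vg.layout[20:44], "span1"),
                 mk_read(vg.layout[2:26], "span2")]
        _, placements = jm.map_reads(reads, vg, max_mismatch=0)
        sam = tmp_path / "aln.sam"
        with open(sam, "w") as fh:
            jm.write_sam(placements, vg, fh, {r.id: r for r in reads})
        back = jm.placements_from_sam(sam, vg)
        assert {(p.read_id, p.alignment.start, p.spanning) for p in back} == \
            {(p.read_id, p.alignment.start, p.spanning) for p in placements}
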