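"""Synthetic-data generator: determinism, truth-table consistency, the
Markov null model, and planted-signal geometry."""

import itertools

import numpy as np
import pytest

from ribocirc import peptides, simdata
from ribocirc.simdata import SimConfig, markov_emulate, simulate_dataset


class TestDeterminism:
    def test_same_seed_same_bundle(self):
        cfg = SimConfig(seed=5, n_circ_translated=2, n_circ_untranslated=2,
                        n_train_coding=10, n_train_noncoding=10)
        b1, b2 = simulate_dataset(cfg), simulate_dataset(cfg)
        assert [c.seq for c in b1.circs] == [c.seq for c in b2.circs]
        assert [(r.id, r.seq, r.qual) for r in b1.reads] == \
            [(r.id, r.seq, r.qual) for r in b2.reads]
        assert b1.train_coding == b2.train_coding
        assert b1.train_noncoding == b2.train_noncoding
        assert b1.truth == b2.truth

    def test_written_bundle_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=5, n_circ_translated=2, n_circ_untranslated=1,
                        n_train_coding=5, n_train_noncoding=5)
        p1 = simdata.write_bundle(simulate_dataset(cfg), tmp_path / "a")
        p2 = simdata.write_bundle(simulate_dataset(cfg), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name


class TestTruthTable:
    def test_planted_orfs_verifiable_against_sequences(self, default_bundle):
        circs = {c.id: c.seq for c in default_bundle.circs}
        for row in default_bundle.truth:
            if not row.translated:
                assert row.orf_start == -1
                continue
            mono = circs[row.circ_id]
            L = len(mono)
            doubled = mono * 2
            assert row.orf_start < L < row.orf_end  # junction-crossing
            orf = doubled[row.orf_start:row.orf_end]
            aa = peptides.translate(orf, 0)
            assert "*" not in aa and aa == row.aa_seq
            # flanking in-frame stops
            assert peptides.translate(doubled[row.orf_start - 3:row.orf_start], 0) == "*"
            assert peptides.translate(doubled[row.orf_end:row.orf_end + 3], 0) == "*"

    def test_read_counts_match_fastq(self, default_bundle):
        cfg = default_bundle.config
        by_circ = {row.circ_id: 0 for row in default_bundle.truth}
        for read in default_bundle.reads:
            if "_span" in read.id:
                by_circ[read.id.rsplit("_span", 1)[0]] += 1
        for row in default_bundle.truth:
            assert by_circ[row.circ_id] == row.n_spanning_reads

    def test_recoverable_flag_tracks_nmj_cut(self):
        cfg = SimConfig(seed=1, n_circ_translated=3,
                        reads_per_translated_junction=3,
                        n_train_coding=5, n_train_noncoding=5)
        bundle = simulate_dataset(cfg, nmj_min=3)
        # 3 junction reads never beat the "greater than 3" cut
        assert all(not row.recoverable for row in bundle.truth)

    def test_spanning_reads_cross_junction_with_overhang(self, default_bundle):
        circs = {c.id: c.seq for c in default_bundle.circs}
        checked = 0
        for read in default_bundle.reads:
            if "_span" not in read.id or not read.id.startswith("circ_t"):
                continue
            cid = read.id.rsplit("_span", 1)[0]
            mono = circs[cid]
            doubled = mono * 2
            core = read.seq
            if core not in doubled:  # adapter- or error-carrying read
                continue
            s = doubled.index(core)
            if s <= len(mono) - 1 and s + len(core) >= len(mono) + 1:
                checked += 1
        assert checked >= default_bundle.config.n_circ_translated * 4

    def test_infeasible_orf_geometry_rejected(self, rng):
        with pytest.raises(ValueError):
            simdata.plant_translated_circ(rng, circ_len=60, orf_len=60)
        with pytest.raises(ValueError):
            SimConfig(orf_len_range=(900, 1000))


class TestGuardCycles:
    def test_shifted_frames_stop_every_period(self):
        for cycle in simdata.GUARD_CYCLES:
            period = "".join(cycle) * 2
            for shift in (1, 2):
                aa = peptides.translate(period, shift)
                assert "*" in aa[:len(cycle) + 1]
            assert "*" not in peptides.translate(period, 0)

    def test_junction_combos_unique_across_circs(self, default_bundle):
        # no two planted circRNAs share cycles and phases at the junction
        circs = {c.id: c.seq for c in default_bundle.circs}
        jregions = []
        for row in default_bundle.truth:
            if row.translated:
                mono = circs[row.circ_id]
                L = len(mono)
                jregions.append((mono * 2)[L - 12:L + 12])
        assert len(set(jregions)) == len(jregions)


class TestMarkovEmulate:
    def test_degenerate_order0_emits_training_base(self):
        out = markov_emulate(["A" * 10_000], order=0, n=3,
                             length_model=[30], seed=4)
        assert all(set(s) == {"A"} for s in out)

    def test_deterministic_per_seed(self):
        train = ["ACGTACGTAGGCCTTAAGCT" * 5] * 3
        a = markov_emulate(train, order=1, n=5, seed=9)
        b = markov_emulate(train, order=1, n=5, seed=9)
        assert a == b

    def test_lengths_follow_training_distribution(self):
        train = ["A" * 17, "C" * 23, "G" * 31]
        out = markov_emulate(train, order=1, n=50, seed=2)
        assert set(map(len, out)) <= {17, 23, 31}

    def test_dinucleotide_frequencies_converge(self, rng):
        # order-1 fit: emitted dinucleotide frequencies approach the
        # training frequencies (L1 distance within 2% at ~1e6 emitted nt)
        train = [simdata.coding_sequence(rng, 200_000)]
        out = markov_emulate(train, order=1, n=5, seed=3)

        def dinuc(seqs):
            counts = {}
            for s in seqs:
                for a, b in itertools.pairwise(s):
                    counts[a + b] = counts.get(a + b, 0) + 1
            total = sum(counts.values())
            return {k: v / total for k, v in counts.items()}

        p, q = dinuc(train), dinuc(out)
        l1 = sum(abs(p.get(k, 0) - q.get(k, 0))
                 for k in set(p) | set(q))
        assert l1 <= 0.02

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            markov_emulate([], order=1, n=1, seed=0)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(rrna_read_fraction=1.2)
        with pytest.raises(ValueError):
            SimConfig(rrna_read_fraction=0.6, linear_read_fraction=0.6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_circ_translated=-1)
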