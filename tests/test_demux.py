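"""Barcode matching and read classification against independent oracles."""

import numpy as np
import pytest

import otsp
from otsp.demux import (
    MergedRead,
    classify_read,
    demux_sample,
    match_barcode,
    revcomp,
    validate_library,
)
from otsp.simulate import SimConfig, emit_reads, st_template_sequences

from .conftest import (
    oracle_leftmost_start,
    oracle_min_window_distance,
    random_dna,
)

BARCODE = "ACGTACGTA"


class TestMatchBarcode:
    @pytest.mark.parametrize(
        "window,expect_match",
        [
            ("ACGTACGTA", True),   # exact
            ("ACGTACCTA", True),   # one substitution
            ("ACGTAATTA", False),  # two substitutions
        ],
    )
    def test_embedded_window(self, window, expect_match):
        seq = "TTTTTTTTTT" + window + "GGGGGGGGGG"
        m = match_barcode(seq, BARCODE, max_edits=1)
        if expect_match:
            # leftmost qualifying window; with indels allowed this can start
            # one base before the embedded window (leading insertion)
            assert m is not None
            assert m.start == oracle_leftmost_start(seq, BARCODE, 1)
        else:
            # confirm there really is no closer window anywhere
            assert oracle_min_window_distance(seq, BARCODE) > 1
            assert m is None

    def test_leftmost_window_beats_exact_hit_downstream(self):
        # a distance-1 window precedes an exact one; leftmost wins
        seq = "TT" + "ACGTACCTA" + "GG" + "ACGTACGTA"
        m = match_barcode(seq, BARCODE, max_edits=1)
        assert m.start == 2 and m.distance == 1
        assert oracle_leftmost_start(seq, BARCODE, 1) == 2

    def test_indel_match(self):
        seq = "CCCC" + "ACGTCGTA" + "CCCC"  # one deletion
        m = match_barcode(seq, BARCODE, max_edits=1)
        assert m is not None and m.distance == 1

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            match_barcode("", BARCODE)
        with pytest.raises(ValueError):
            match_barcode("ACGT", "")

    def test_oracle_agreement_random_sequences(self):
        """Match decision and leftmost position agree with exhaustive DP."""
        rng = np.random.default_rng(7)
        n_checked = 0
        for _ in range(300):
            seq = random_dna(rng, 60)
            m = match_barcode(seq, BARCODE, max_edits=1)
            oracle_d = oracle_min_window_distance(seq, BARCODE)
            if m is None:
                assert oracle_d > 1
            else:
                assert oracle_d <= 1
                assert m.start == oracle_leftmost_start(seq, BARCODE, 1)
                n_checked += 1
        assert n_checked > 0  # a few random 60-mers do contain near-matches


class TestLibrary:
    def test_design_invariants(self, library):
        assert len(library.entries) == 260
        assert len(set(library.barcodes())) == 260
        pairs = {(v, j) for v, j, _ in library.entries}
        assert pairs == {(v, j) for v in range(1, 21) for j in range(1, 14)}
        # spot-check the pairwise-distance floor with the independent DP
        from .conftest import levenshtein

        rng = np.random.default_rng(3)
        bcs = library.barcodes()
        for _ in range(300):
            a, b = rng.choice(260, size=2, replace=False)
            assert levenshtein(bcs[a], bcs[b]) >= 3

    def test_validation_rejects_close_barcodes(self, small_library):
        entries = list(small_library.entries)
        v, j, bc = entries[1]
        other = entries[0][2]
        # make entry 1's barcode one edit from entry 0's
        entries[1] = (v, j, other[:-1] + ("A" if other[-1] != "A" else "C"))
        with pytest.raises(ValueError, match="edit distance"):
            otsp.STBarcodeLibrary(
                small_library.universal_barcode, tuple(entries), n_v=4, n_j=3
            )


class TestClassify:
    def test_simulator_read_roundtrip(self, small_library):
        templates = st_template_sequences(small_library)
        for idx in [0, 5, 11]:
            read = MergedRead(f"r{idx}", templates[idx])
            cls = classify_read(read, small_library)
            assert cls.kind == "st"
            assert cls.template_index == idx
            assert cls.pair == small_library.pair_of(idx)

    def test_reverse_complement_orientation(self, small_library):
        templates = st_template_sequences(small_library)
        cls = classify_read(MergedRead("r", revcomp(templates[3])), small_library)
        assert cls.kind == "st" and cls.template_index == 3 and cls.strand == "-"

    def test_random_read_is_clonotype(self, small_library):
        rng = np.random.default_rng(11)
        n = 0
        while n < 20:
            seq = random_dna(rng, 150)
            fwd = oracle_min_window_distance(seq, small_library.universal_barcode)
            rc = oracle_min_window_distance(revcomp(seq), small_library.universal_barcode)
            if min(fwd, rc) <= 1:
                continue  # oracle says this one does contain a near-match
            assert classify_read(MergedRead("r", seq), small_library).kind == "clonotype"
            n += 1

    def test_universal_without_unique_is_ambiguous(self, small_library):
        junk = "A" * 16  # >= 2 edits from every (random) unique barcode
        for bc in small_library.barcodes():
            assert oracle_min_window_distance(junk, bc) >= 2
        seq = random_dna(np.random.default_rng(5), 40) + \
            small_library.universal_barcode + junk + "CCCCCCCC"
        cls = classify_read(MergedRead("r", seq), small_library)
        assert cls.kind == "ambiguous"


class TestDemux:
    def _clean_random_read(self, rng, library, length=120):
        while True:
            seq = random_dna(rng, length)
            if oracle_min_window_distance(seq, library.universal_barcode) > 1 and \
               oracle_min_window_distance(revcomp(seq), library.universal_barcode) > 1:
                return seq

    def test_hand_fixture_counts(self, small_library):
        templates = st_template_sequences(small_library)
        rng = np.random.default_rng(23)
        i11 = small_library.index_of(1, 1)
        i22 = small_library.index_of(2, 2)
        reads = (
            [MergedRead(f"a{k}", templates[i11]) for k in range(3)]
            + [MergedRead(f"b{k}", templates[i22]) for k in range(2)]
            + [MergedRead(f"c{k}", self._clean_random_read(rng, small_library))
               for k in range(4)]
        )
        vec, clono, summary = demux_sample(reads, small_library)
        assert vec[(1, 1)] == 3 and vec[(2, 2)] == 2
        assert vec.sum() == 5
        assert len(clono) == 4
        assert summary.n_st + summary.n_clonotype + summary.n_ambiguous == 9

    def test_empty_input(self, small_library):
        vec, clono, summary = demux_sample([], small_library)
        assert vec.sum() == 0 and clono == [] and summary.n_reads == 0

    def test_errorfree_roundtrip_exact(self, library):
        rng = np.random.default_rng(31)
        counts = otsp.demux.template_multiindex().to_frame(index=False)
        st = rng.integers(0, 6, 260)
        import pandas as pd

        st_counts = pd.Series(st, index=otsp.template_multiindex())
        cfg = SimConfig(seed=42, error_rate=0.0)
        reads = emit_reads(st_counts, None, library, cfg)
        vec, clono, summary = demux_sample(reads, library)
        assert (vec == st_counts).all()
        assert summary.n_ambiguous == 0 and len(clono) == 0

    def test_noisy_reads_conservation_and_recovery(self, library):
        import pandas as pd

        rng = np.random.default_rng(53)
        st_counts = pd.Series(rng.poisson(4, 260), index=otsp.template_multiindex())
        cfg = SimConfig(seed=77, error_rate=0.001)
        reads = emit_reads(st_counts, None, library, cfg)
        vec, clono, summary = demux_sample(reads, library)
        assert summary.n_st + summary.n_clonotype + summary.n_ambiguous == len(reads)
        # substitution errors at 1e-3 leave almost every read assignable
        assert vec.sum() >= 0.99 * st_counts.sum()
        assert (vec - st_counts).abs().sum() <= 0.02 * st_counts.sum()
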