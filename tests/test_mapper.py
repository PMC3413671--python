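import numpy as np
import pytest

from oracles import full_sw_glocal
from sap._codec import encode, revcomp
from sap.align import banded_align
from sap.index import build_index
from sap.io_formats import Read, write_sam
from sap.mapper import (
    accept_alignment,
    banded_sw,
    direct_compare,
    extract_pieces,
    final_score,
    map_read,
    map_reads,
    piece_starts,
    seed_candidates,
)
from sap.simulator import random_reference


def _read(bases: str, q: int = 30, rid: str = "r") -> Read:
    return Read(rid, bases, np.full(len(bases), q, dtype=np.int16))


class TestPieces:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (105, [0, 15, 30, 45, 60, 75, 90]),
            (75, [0, 10, 20, 30, 40, 50, 60]),
            (15, [0, 0, 0, 0, 0, 0, 0]),
        ],
    )
    def test_piece_starts(self, n, expected):
        assert piece_starts(n, 15, 7) == expected

    def test_pieces_cover_read_ends(self):
        r = _read("ACGT" * 30)
        pieces = extract_pieces(r, 15)
        assert pieces[0].start == 0
        assert pieces[-1].start == len(r) - 15
        assert all(p.bases == r.bases[p.start : p.start + 15] for p in pieces)

    def test_short_read_yields_no_pieces(self):
        assert extract_pieces(_read("ACGTACGT"), 15) == []


class TestSeeding:
    def test_perfect_read_single_locus_full_support(self, small_ref, small_index):
        p = 500
        r = _read(small_ref.sequence[p : p + 75])
        loci = seed_candidates(r, small_index)
        assert loci[0].support == 7
        assert loci[0].l_min == loci[0].l_max == p

    def test_deletion_splits_implied_starts_by_its_length(self, small_ref, small_index):
        # read spans a 5 bp deletion: left part from p, right part from p+40+5
        p = 1000
        bases = small_ref.sequence[p : p + 40] + small_ref.sequence[p + 45 : p + 80]
        loci = seed_candidates(_read(bases), small_index)
        assert loci[0].support >= 2
        assert loci[0].l_max - loci[0].l_min == 5

    def test_foreign_read_has_no_candidates(self, small_index):
        rng = np.random.default_rng(3)
        bases = "".join(rng.choice(list("ACGT"), 75))
        assert seed_candidates(_read(bases), small_index) == []

    def test_reverse_strand_locus(self, small_ref, small_index):
        p = 700
        r = _read(revcomp(small_ref.sequence[p : p + 75]))
        loci = seed_candidates(r, small_index)
        assert loci[0].strand == "-"
        assert loci[0].l_min == p


class TestExtension:
    def test_identity_and_mismatch_scoring(self, small_ref, small_index):
        from sap.mapper import CandidateLocus

        p = 50
        r = _read(small_ref.sequence[p : p + 20])
        locus = CandidateLocus(0, "+", p, p, 7)
        a = direct_compare(r, small_index, locus)
        assert a.l_map == 20 and a.s_map == 1.0

        bases = list(r.bases)
        bases[10] = "A" if bases[10] != "A" else "C"
        a = direct_compare(_read("".join(bases)), small_index, locus)
        assert a.s_map == pytest.approx(0.95)

    def test_acceptance_threshold_is_strict(self):
        a = type("A", (), {})()
        a.s_map = 0.95
        assert accept_alignment(a)
        a.s_map = 0.9
        assert not accept_alignment(a)
        a.s_map = 0.0
        assert not accept_alignment(a)

    def test_banded_recovers_internal_deletion(self, small_ref, small_index):
        from sap.mapper import CandidateLocus

        p = 200
        bases = small_ref.sequence[p : p + 30] + small_ref.sequence[p + 34 : p + 64]
        locus = CandidateLocus(0, "+", p, p + 4, 4)
        a = banded_sw(_read(bases), small_index, locus)
        assert ("D", 4) in a.cigar
        assert a.s_map == 1.0
        # score equals the unrestricted oracle
        oracle = full_sw_glocal(encode(bases), encode(small_ref.sequence[p - 10 : p + 80]))
        got = banded_align(encode(bases), encode(small_ref.sequence), p - 5, p + 9)
        assert got.score == oracle

    def test_final_score_reduces_to_identity_on_uniform_quals(self, small_ref, small_index):
        from sap.mapper import CandidateLocus

        p = 400
        bases = list(small_ref.sequence[p : p + 40])
        bases[5] = "A" if bases[5] != "A" else "C"
        bases[17] = "G" if bases[17] != "G" else "T"
        r = _read("".join(bases))
        a = direct_compare(r, small_index, CandidateLocus(0, "+", p, p, 7))
        assert final_score(a) == pytest.approx(a.s_map)

    def test_low_quality_mismatches_score_higher(self, small_ref, small_index):
        from sap.mapper import CandidateLocus

        p = 400
        bases = list(small_ref.sequence[p : p + 40])
        bases[5] = "A" if bases[5] != "A" else "C"
        locus = CandidateLocus(0, "+", p, p, 7)
        quals_hi = np.full(40, 30, dtype=np.int16)
        quals_lo = quals_hi.copy()
        quals_lo[5] = 3  # mismatch sits on an unreliable base
        a_hi = direct_compare(Read("h", "".join(bases), quals_hi), small_index, locus)
        a_lo = direct_compare(Read("l", "".join(bases), quals_lo), small_index, locus)
        assert final_score(a_lo) > final_score(a_hi)


class TestBandedOracle:
    def test_score_never_exceeds_and_matches_covering_band(self):
        """Randomized read/window pairs with small InDels vs the full DP."""
        rng = np.random.default_rng(1234)
        n_equal = 0
        for _ in range(100):
            m = int(rng.integers(60, 200))
            ref = rng.integers(0, 4, m).astype(np.uint8)
            start = int(rng.integers(0, m // 4))
            rlen = int(rng.integers(40, m - start))
            read = ref[start : start + rlen].copy()
            shift = 0
            if rng.random() < 0.7:  # inject one InDel of <= 10 bp
                g = int(rng.integers(1, 11))
                cut = int(rng.integers(5, max(6, len(read) - 5)))
                if rng.random() < 0.5 and len(read) > cut + g + 5:
                    read = np.concatenate([read[:cut], read[cut + g :]])
                    shift = g
                else:
                    ins = rng.integers(0, 4, g).astype(np.uint8)
                    read = np.concatenate([read[:cut], ins, read[cut:]])
                    shift = -g
            for pos in rng.choice(len(read), size=min(3, len(read)), replace=False):
                read[pos] = (read[pos] + rng.integers(1, 4)) % 4
            oracle = full_sw_glocal(read, ref)
            lo = min(start, start + shift) - 3
            hi = max(start, start + shift) + 3
            res = banded_align(read, ref, lo, hi)
            assert res is not None
            assert res.score <= oracle
            if res.score == oracle:
                n_equal += 1
            # band covering the whole matrix always reproduces the oracle
            full = banded_align(read, ref, -len(read), m)
            assert full.score == oracle
        assert n_equal >= 90  # band covers the true offset by construction

    def test_cell_count_within_band_bound(self):
        rng = np.random.default_rng(9)
        ref = rng.integers(0, 4, 500).astype(np.uint8)
        read = ref[100:300].copy()
        res = banded_align(read, ref, 95, 110)
        width = 110 - 95 + 1
        assert res.cells <= (len(read) + 1) * width


class TestMapRead:
    def test_error_free_reads_map_to_exact_origin(self):
        ref = random_reference(50_000, seed=21)
        idx = build_index([ref], k=15)
        rng = np.random.default_rng(2)
        n_ok = 0
        n = 300
        for i in range(n):
            p = int(rng.integers(0, ref.length - 75))
            bases = ref.sequence[p : p + 75]
            if rng.random() < 0.5:
                bases = revcomp(bases)
            a = map_read(_read(bases, rid=f"r{i}"), idx)
            if a.mapped and a.ref_start == p:
                n_ok += 1
        assert n_ok / n >= 0.99

    def test_foreign_read_unmapped(self, small_index):
        rng = np.random.default_rng(8)
        a = map_read(_read("".join(rng.choice(list("ACGT"), 80))), small_index)
        assert not a.mapped

    def test_short_read_reported_unmapped(self, small_index):
        a = map_read(_read("ACGTACGT"), small_index)
        assert not a.mapped

    def test_slow_mode_rescues_mismatched_seeds(self, small_ref, small_index):
        # every piece carries one error: exact seeding fails, one-mismatch works
        p = 1200
        bases = list(small_ref.sequence[p : p + 75])
        for s in (2, 18, 32, 48, 62, 71):
            bases[s] = "A" if bases[s] != "A" else "C"
        r = _read("".join(bases))
        assert not map_read(r, small_index, "fast").mapped
        a = map_read(r, small_index, "slow")
        assert a.mapped and a.ref_start == p

    def test_mapping_is_deterministic_byte_identical(self, tmp_path):
        ref = random_reference(20_000, seed=33)
        idx = build_index([ref], k=15)
        from sap.simulator import SimulationConfig, simulate_dataset

        ds = simulate_dataset(ref, SimulationConfig(read_len=75, coverage=3, seed=4))
        outs = []
        for trial in range(2):
            alns = map_reads(ds.reads, idx)
            path = tmp_path / f"t{trial}.sam"
            write_sam(alns, [ref], path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]
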